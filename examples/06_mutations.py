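"""Apply the experimentally assayed sequence mutations to a hairpin.

Substitutions rebuild the base moiety from an ideal template on the
glycosidic attachment frame; deletions remove the residue without
renumbering. The mutated structures remain classifiable.
"""

from hairpin7sk import (apply_mutation, assign_family, build_hairpin,
                        detect_triplets, xi_angle)

wild_type, _ = build_hairpin(template="M2", seed=1)
panel = ["U40C", "U41C", "U40C+U41C", "delU63", "A39G", "A39U",
         "A39U+U68A", "A39G+U68C"]

print(f"{'mutant':12s} {'residues':>8s} {'xi (deg)':>9s} {'family':>7s}")
for spec in panel:
    mutant = apply_mutation(wild_type, spec)
    xi = xi_angle(mutant)
    family = assign_family(xi, detect_triplets(mutant))
    print(f"{spec:12s} {len(mutant):8d} {xi:9.1f} {family:>7s}")
print()
print("Mutations change base identity (and hence contact patterns and")
print("pairing compatibility) while leaving the backbone untouched; the")
print("starting geometry here is the M2 template in every case.")
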