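"""Recover planted family fractions from a noisy synthetic ensemble.

A 500-frame mixture is generated with known per-family counts and
0.3 A atomic noise, classified frame by frame via the xi angle and
triplet detection, and the recovered composition is compared with the
planted truth.
"""

from hairpin7sk import classify_ensemble, composition, make_mixture

n = 500
ens, truth = make_mixture(["M1", "M2", "E"], [0.06, 0.68, 0.26],
                          n=n, sigma=0.3, seed=7)
frames = classify_ensemble(ens)
recovered = composition(frames).folded()

print(f"{'family':8s} {'planted':>8s} {'recovered':>10s}")
for family, count in truth.payload["family_counts"].items():
    print(f"{family:8s} {count / n:8.1%} {recovered.get(family, 0.0):10.1%}")
print()
print("Fractions are exact up to classification errors; at this noise")
print("level the xi-based family bands are essentially never crossed.")
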