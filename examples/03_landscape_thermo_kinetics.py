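"""Thermodynamics and kinetics of a planted three-funnel landscape.

The network emulates the hairpin's energy landscape: an E funnel lowest,
an M2 funnel a few kcal/mol above it, and a much higher M1 funnel, with
funnel crossings around 25 kcal/mol. The script computes free-energy
gaps between funnels, basin content under a 15 kcal/mol cutoff, and
two-state inter-funnel rates from the master equation.
"""

from hairpin7sk import (RateParams, basin_content, free_energy_gap,
                        interfunnel_rate, occupation, planted_network)

params = RateParams(temperature=298.0)
net, truth = planted_network(
    [(12, 0.0, 1.0), (12, 5.0, 1.0), (12, 19.0, 0.5)],
    inter_barrier=25.0, seed=2, families=["E", "M2", "M1"])
membership = truth.payload["membership"]
sets = {fam: [int(k) for k, v in membership.items() if v == i]
        for i, fam in enumerate(["E", "M2", "M1"])}

gap_e = free_energy_gap(net, sets["E"], sets["M2"], params)
gap_m1 = free_energy_gap(net, sets["M1"], sets["M2"], params)
print(f"F(E) - F(M2)  = {gap_e:7.2f} kcal/mol   (negative: E more stable)")
print(f"F(M1) - F(M2) = {gap_m1:7.2f} kcal/mol")

k_ab, k_ba = interfunnel_rate(net, sets["M2"], sets["E"], params)
print(f"k(M2 -> E) = {k_ab:.2e} 1/s, k(E -> M2) = {k_ba:.2e} 1/s")
k1, k2 = interfunnel_rate(net, sets["M1"], sets["M2"], params)
print(f"k(M1 -> M2) / k(M2 -> M1) = {k1 / k2:.2e}"
      " (detailed balance: equals the population ratio)")

bc = basin_content(net, sets["E"][0], 15.0)
print(f"basin of the E bottom at 15 kcal/mol: {len(bc.subset)} minima,",
      {k: round(v, 3) for k, v in bc.uniform.fractions.items()})
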