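# Methods

This note documents the models and numerical choices behind the
package: how hairpin conformations are classified into the M1 / M2 /
M2\* / E families, how minima–transition-state networks are turned
into thermodynamics and kinetics, how peptide–RNA interfaces are
profiled, and what the synthetic fixture generator does and does not
emulate.

## The system

The 5′ hairpin (HP1) of human 7SK RNA carries the 7SK motif: a
GAUC/GAUC four-base-pair helix (nucleotides 42–45 paired with 64–67)
framed by three unpaired uridines, U40, U41 and U63. The package works
on the apical window, nucleotides 37–70, closed by the stable pairs
C37–G70, C38–G69 and A39–U68. Experimentally observed conformations
fall into families distinguished by which uridine joins which pair as a
base triplet:

| family | triplets | character |
|---|---|---|
| M1 | T1 = U40·C45–G64 and T3 = U41·A43–U66 | compact, groove blocked |
| M2 | T2 = U40·A43–U66 | open major groove, binding-competent |
| M2\* | T2 plus U63·U44–A65 | subset of M2 with U63 engaged |
| E | none | extended, bent |

## Classification

The classification coordinate ξ is the angle at the midpoint of the
A43–U66 base centroids, between the U40 base centroid and the midpoint
of the C45–G64 centroids. Base centroids are unweighted means of the
ring heavy atoms; this choice is rotation-robust and insensitive to
missing hydrogens. (The original definition's reference atoms are not
published; the angle-spec object accepts alternative residue numbers,
and the bands below tolerate reasonable reference-point conventions.)

Band rule, with boundaries resolved downward for determinism:
ξ ∈ [0, 60] → M1, (60, 100] → M2, (100, 180] → E. An M2 assignment is
refined to M2\* when the U63·U44–A65 triplet is detected; the triplet
criterion alone (no energy criterion) marks the subset. The
U44–A65–U63 angle reports the gatekeeper state of U63; `u63_state`
calls it "out" at or above 100° (configurable — the published
projection is unthresholded).

## Contacts

Hydrogen bonds are geometric: donor–acceptor heavy-atom distance
≤ 3.5 Å, plus a D–H…A angle ≥ 120° when an explicit donor hydrogen is
present. Crystal-style inputs without hydrogens therefore use the
distance criterion alone. Donor/acceptor tables cover A/C/G/U (base
and backbone) and the twenty amino acids.

Base pairs require at least two inter-base hydrogen bonds, base-centroid
distance ≤ 7 Å, inter-plane angle ≤ 35° (admitting propellered pairs),
and a centroid offset ≤ 2 Å along the mean base normal. The last
criterion is not part of the usual textbook rule but is necessary under
hydrogen-free criteria: stacked neighbours sit ~3.4 Å apart vertically
and otherwise pass the distance and plane-angle tests. A pair is
flagged Watson–Crick when all supporting bonds use WC-edge atoms.

A canonical triplet is present when its pair is detected and the third
base forms at least two base–base hydrogen bonds with the pair members
(U·A–U and U·C–G triplets canonically form two). Non-canonical bases
joining a detected pair at the same support level are reported as
OTHER.

## Kinetic transition networks

Minima and transition states carry potential energies in kcal/mol;
k_B = 0.0019872 kcal/(mol·K), default temperature 298 K. All Boltzmann
arithmetic is done in the log domain (log-sum-exp), so 14 kcal/mol
free-energy gaps (equilibrium ratios ~10^10) do not underflow.

* **Occupation**: p_i ∝ exp(−E_i/kT), or the harmonic-superposition
  form exp(−E_i/kT − log∏ν_i − ln σ_i) when vibrational data are
  present for every minimum (mixing is an error).
* **Rates**: Arrhenius with a uniform 10^13 s⁻¹ prefactor when no
  frequency data are available, harmonic-TST frequency-ratio prefactors
  otherwise. Absolute rates therefore depend on an assumed prefactor;
  ratios and detailed balance do not. Negative barriers are clamped to
  zero with a warning.
* **Basin content**: minima connected to a designated bottom through
  transition states at or below E(bottom) + cutoff (default
  15 kcal/mol), restricted to minima below the same threshold. Both
  uniform and Boltzmann-weighted family compositions are returned,
  since published basin percentages do not state their weighting.
* **Two-state rates**: the `master` method takes the slowest nonzero
  relaxation eigenvalue λ₁ of the full generator (symmetrized with the
  exact equilibrium distribution) and splits it as k_ab = λ₁·P_b,
  k_ba = λ₁·P_a with populations restricted to a ∪ b. The `gt` method
  eliminates intervening minima by a Schur complement with a
  self-consistent eigenvalue shift; its fixed point is exactly an
  eigenvalue of the full generator, so the two methods agree to solver
  tolerance whenever the slow mode is spectrally separated. This
  two-state extraction assumes local equilibration within each set.
  Note the numerical regime: for barriers ≳ 18 kcal/mol the slowest
  rate is below ~10⁻¹⁵ of the rate-matrix norm and *no* dense
  eigensolver resolves it; oracle comparisons are therefore made on
  networks with moderate barriers, while graph transformation remains
  the method of choice for deep landscapes.
* **Free-energy gaps**: ΔF = −kT ln(P_a/P_b), restricted and
  renormalized to a ∪ b; negative means the first set is more stable.

## Disconnectivity graphs

At each threshold energy (descending from the highest transition state
plus one level spacing, default 1 kcal/mol), minima below the threshold
are grouped by union–find over transition states below the threshold;
the tree records where superbasins merge, and leaves sit at the minima
energies. Funnels are defined operationally by minimax-path
attraction: each minimum belongs to the designated bottom reachable
over the lowest highest-energy barrier, ties going to the lower-energy
bottom. Rendering is plain SVG with a vertical energy axis, subtree
ordering by member count (deterministic, reproducible byte-for-byte)
and leaves coloured M1 blue, M2 green, M2\* dark green, E red.

## Interface profiling

* **Fingerprints**: per peptide residue, the minimum CA–phosphate and
  CA–(base C4) distances; the 5′-terminal nucleotide without a
  phosphate is excluded from the P pool.
* **SASA**: Shrake–Rupley with 960 golden-spiral points, probe 1.4 Å,
  bundled van der Waals radii, heavy atoms only.
* **Gap index**: gap volume divided by interface area. Gap cells (grid
  0.8 Å) lie outside both van der Waals surfaces, within 4 Å of both
  chains' surfaces, and are sandwiched between the chains (directions
  to the nearest atom of each chain oppose each other). The sandwich
  criterion keeps the volume stable under grid refinement (~0.1%
  change from 0.8 to 0.4 Å in practice). The area is the mean
  per-chain buried SASA, (SASA_A + SASA_B − SASA_AB)/2. Zero buried
  area raises "not in contact". Absolute values depend on these
  conventions; the package's claims are comparative (groove vs
  surface poses).
* **Coulomb energy**: 332.06·Σ q_i q_j / (ε r_ij) kcal/mol over
  cross-chain heavy-atom pairs, uniform dielectric 78.5. Partial
  charges come from a bundled nominal table and are shifted per residue
  so each residue carries its formal charge at pH 7 (RNA −1 per
  phosphate-bearing nucleotide; Arg/Lys +1; Asp/Glu −1). This is not a
  force field: only relative comparisons between poses are meaningful.

## Synthetic fixtures

The generator exists to give every pipeline stage inputs with known
ground truth; fixtures are geometrically plausible but **not**
energy-minimized, and no thermodynamic claim attaches to them.

* **Hairpins**: paired regions are stacked with A-form-like parameters
  (twist 32.7°, rise 2.81 Å, base-pair displacement −4.4 Å from the
  axis, which opens a deep major groove). Base geometries are CCD
  ideal coordinates; partner bases are placed by least squares against
  target hydrogen-bond distances (~2.8–2.9 Å), coplanarity, sterics
  and a cis-glycosidic side constraint. The bulged uridines realize
  the family templates: triplet-forming bases are superposed to give
  the planted donor–acceptor contacts and steer ξ to the family target
  (M1 ≈ 30°, M2 ≈ 90°, E ≳ 120°; ±4° seeded spread). The backbone is
  threaded through sugar anchor points with circular-arc chains whose
  bond lengths come out within ~10% of standard values; the apical
  loop 49–59 is an arc above the stem with outward-pointing bases and
  stands in for the native loop (which the underlying experiments also
  replace). The reduced atom set per nucleotide is P, OP1, OP2, O5′,
  C5′, C4′, C3′, O3′, C1′ plus the base; C2′/O2′/O4′ are omitted, so
  C1′–C4′ is not a covalent bond and may stretch where a bulged base
  sits far from its strand.
* **Noise**: `jitter_ensemble` adds isotropic Gaussian displacement
  with RMS magnitude sigma per atom (default study condition 0.3 Å);
  at that level the planted triplet patterns survive in ≥ 95% of
  frames and ξ-based classification is essentially unaffected.
* **Mixtures**: largest-remainder rounding of n·fractions, shuffled,
  with exact planted counts recorded in the truth payload.
* **Networks**: each funnel is a random tree with Exp-distributed
  energy increments; funnel bottoms are chained by single transition
  states at the inter-funnel barrier (default 20 kcal/mol, above every
  intra-funnel barrier by construction).
* **Peptide poses**: the ARM peptide (GKKKHRRRPSKKKRHWK, numbered
  149–165) is a compact helical rod with pseudo side-chain tips. The
  groove pose follows the local tangent of the helical major-groove
  channel, slim backbone face inward, advanced until a 2.2 Å clash
  rule stops it; the surface pose lies tangentially across the
  backbone with side chains pointing away; the distant pose sits 50 Å
  out. The groove pose has smaller CA–C4 distances, a smaller gap
  index, larger buried area and a more negative Coulomb energy than
  the surface pose — the orderings the analysis relies on — but no
  pose is docked or optimized.

What passing tests on these fixtures shows: the descriptors, detectors
and network machinery compute what they claim on structures with known
answers. What it does not show: anything about force-field energetics,
real conformational propensities, or binding thermodynamics.

## Problem sizes

The test suite and the reproduction script use fixture sizes chosen to
exercise the estimators well inside their asymptotic regime while
staying light: 500-frame mixtures over 10–20 seeds for composition
recovery, 12–24-minimum planted networks (100 replicates for
rate-method equivalence, exhaustive path oracles on ≤ 12 minima), and
single complexes per pose for the interface profile.

## Known limitations

* ξ reference points (base centroids) are a convention; other
  realizations shift ξ by a few degrees, which the band tolerances
  absorb.
* Hydrogen-bond counts on hydrogen-free inputs use distance-only
  criteria and can differ from counts under angle-aware criteria.
* Absolute rates carry the 10^13 s⁻¹ prefactor assumption; only
  ratios, gaps and detailed-balance relations are quantitative.
* The gap index and Coulomb energy are convention-bound; compare
  poses, not publications.
* The M1 fixture's groove pose is only mildly worse than M2's; the
  dramatic experimental contrast between blocked and open grooves is
  under-represented by rigid fixtures.
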