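"""The fixture generators: determinism, planted truths, validity."""

import numpy as np
import pytest

from hairpin7sk import (build_arm_peptide, build_hairpin, jitter_ensemble,
                        largest_remainder_counts, make_mixture, place_peptide,
                        planted_network, wild_type_sequence, xi_angle)
from hairpin7sk.structure import StructureError, validate_nucleotide
from hairpin7sk.synthetic import PAIR_SCHEME, TEMPLATES

BACKBONE_BONDS = [("C4'", "C3'", 1.52), ("C3'", "O3'", 1.42)]


class TestBuildHairpin:
    def test_same_seed_bit_identical(self):
        a, _ = build_hairpin(template="M2", seed=4)
        b, _ = build_hairpin(template="M2", seed=4)
        assert np.abs(a.coords() - b.coords()).max() == 0.0

    def test_different_seed_differs(self):
        a, _ = build_hairpin(template="M2", seed=4)
        b, _ = build_hairpin(template="M2", seed=5)
        assert np.abs(a.coords() - b.coords()).max() > 0.0

    def test_wild_type_sequence_layout(self):
        seq = wild_type_sequence()
        assert len(seq) == 34
        assert seq[40 - 37] == "U" and seq[41 - 37] == "U" and seq[63 - 37] == "U"
        assert seq[42 - 37:46 - 37] == "GAUC"

    def test_residues_pass_module_validators(self, all_templates):
        for conf, _ in all_templates.values():
            for res in conf:
                validate_nucleotide(res)

    def test_incompatible_sequence_rejected(self):
        seq = dict(zip(range(37, 71), wild_type_sequence()))
        seq[70] = "A"  # breaks the C37-G70 closing pair
        with pytest.raises(StructureError, match="pairing"):
            build_hairpin(sequence=seq, template="M2", seed=0)

    def test_truth_records_template(self):
        conf, truth = build_hairpin(template="E", seed=2)
        assert truth.kind == "family"
        assert truth.payload["family"] == "E"
        assert truth.seed == 2

    def test_backbone_bonds_near_ideal(self, all_templates):
        for name, (conf, _) in all_templates.items():
            for k in range(38, 71):
                prev, cur = conf.residue(k - 1), conf.residue(k)
                chain = [(prev, "C4'"), (prev, "C3'"), (prev, "O3'"),
                         (cur, "P"), (cur, "O5'"), (cur, "C5'"), (cur, "C4'")]
                targets = [1.52, 1.42, 1.60, 1.59, 1.44, 1.51]
                for (ra, na), (rb, nb), t in zip(chain, chain[1:], targets):
                    d = np.linalg.norm(ra.atom(na).position
                                       - rb.atom(nb).position)
                    assert abs(d - t) / t <= 0.10, (name, k, na, nb)

    def test_five_prime_terminus_lacks_phosphate(self, m2_conf):
        conf, _ = m2_conf
        assert not conf.residue(37).has_atom("P")
        assert conf.residue(38).has_atom("P")

    def test_target_xi_inside_family_band(self):
        bands = {"M1": (0, 60), "M2": (60, 100), "M2STAR": (60, 100),
                 "E": (100, 180)}
        for name, tpl in TEMPLATES.items():
            lo, hi = bands[name]
            assert lo < tpl.target_xi <= hi


class TestJitterEnsemble:
    def test_sigma_zero_identical(self, m2_conf):
        conf, _ = m2_conf
        ens, _ = jitter_ensemble(conf, 3, 0.0, seed=1)
        for f in ens:
            assert np.abs(f.coords() - conf.coords()).max() == 0.0

    def test_same_seed_identical(self, m2_conf):
        conf, _ = m2_conf
        a, _ = jitter_ensemble(conf, 4, 0.4, seed=9)
        b, _ = jitter_ensemble(conf, 4, 0.4, seed=9)
        for fa, fb in zip(a, b):
            assert np.abs(fa.coords() - fb.coords()).max() == 0.0

    def test_mean_structure_clt_bound(self, m2_conf):
        # with n frames the mean structure deviates by ~sigma/sqrt(n)
        conf, _ = m2_conf
        sigma, n = 0.5, 2000
        ens, _ = jitter_ensemble(conf, n, sigma, seed=2)
        mean = np.mean([f.coords() for f in ens], axis=0)
        dev = np.linalg.norm(mean - conf.coords(), axis=1)
        bound = 3.0 * sigma / np.sqrt(n)
        assert np.mean(dev <= bound) >= 0.99

    def test_rms_displacement_matches_sigma(self, m2_conf):
        conf, _ = m2_conf
        sigma = 0.5
        ens, _ = jitter_ensemble(conf, 200, sigma, seed=3)
        disp = np.concatenate([
            np.linalg.norm(f.coords() - conf.coords(), axis=1) for f in ens])
        assert np.sqrt(np.mean(disp ** 2)) == pytest.approx(sigma, rel=0.05)


class TestMakeMixture:
    def test_half_half_counts(self):
        ens, truth = make_mixture(["M2", "E"], [0.5, 0.5], n=10,
                                  sigma=0.1, seed=0)
        assert len(ens) == 10
        assert truth.payload["counts"] == {"M2": 5, "E": 5}

    def test_largest_remainder_rule(self):
        assert largest_remainder_counts([0.06, 0.68, 0.26], 100) == [6, 68, 26]
        assert largest_remainder_counts([0.06, 0.68, 0.26], 500) == [30, 340, 130]
        counts = largest_remainder_counts([1 / 3, 1 / 3, 1 / 3], 100)
        assert sum(counts) == 100

    def test_truth_labels_match_frames(self):
        ens, truth = make_mixture(["M1", "M2", "E"], [0.2, 0.5, 0.3],
                                  n=10, sigma=0.0, seed=5)
        labels = truth.payload["labels"]
        assert len(labels) == 10
        for frame, label in zip(ens, labels):
            xi = xi_angle(frame)
            band = "M1" if xi <= 60 else ("M2" if xi <= 100 else "E")
            assert band == label

    def test_n_below_populated_templates_rejected(self):
        with pytest.raises(ValueError):
            make_mixture(["M1", "M2", "E"], [0.3, 0.3, 0.4], n=2,
                         sigma=0.1, seed=0)


class TestPlantedNetwork:
    def test_single_minimum_trivial(self):
        net, truth = planted_network([(1, 0.0, 1.0)], seed=0)
        assert len(net.minima) == 1
        assert not net.transition_states

    def test_membership_and_bottoms_recorded(self, two_funnel_network):
        net, truth = two_funnel_network
        membership = truth.payload["membership"]
        assert len(membership) == len(net.minima)
        for b, funnel in zip(truth.payload["bottoms"], range(2)):
            assert membership[str(b)] == funnel
            # a bottom is the lowest minimum of its funnel
            funnel_ids = [int(k) for k, v in membership.items() if v == funnel]
            assert net.minima[b].energy == min(
                net.minima[i].energy for i in funnel_ids)

    def test_inter_barrier_above_intra(self, two_funnel_network):
        net, truth = two_funnel_network
        membership = truth.payload["membership"]
        intra = [ts.energy for ts in net.transition_states
                 if membership[str(ts.min1)] == membership[str(ts.min2)]]
        assert max(intra) < truth.payload["inter_barrier"]

    def test_barrier_too_low_rejected(self):
        with pytest.raises(ValueError):
            planted_network([(6, 0.0, 5.0), (6, 0.0, 5.0)],
                            inter_barrier=1.0, seed=0)

    def test_deterministic(self):
        a, _ = planted_network([(5, 0.0, 1.0), (5, 2.0, 1.0)], seed=8)
        b, _ = planted_network([(5, 0.0, 1.0), (5, 2.0, 1.0)], seed=8)
        assert [m.energy for m in a.minima.values()] == \
            [m.energy for m in b.minima.values()]


class TestPlacePeptide:
    def test_distant_mode_offset(self, m2_conf):
        rna, _ = m2_conf
        cpx, truth = place_peptide(rna, mode="distant", seed=0)
        from scipy.spatial import cKDTree
        rxyz = np.vstack([a.position for r in cpx.residues
                          if r.chain == "A" for a in r.atoms])
        pxyz = np.vstack([a.position for r in cpx.residues
                          if r.chain == "B" for a in r.atoms])
        dmin = cKDTree(rxyz).query(pxyz)[0].min()
        assert 25.0 <= dmin <= 55.0

    def test_same_seed_identical_pose(self, m2_conf):
        rna, _ = m2_conf
        a, _ = place_peptide(rna, mode="groove", seed=6)
        b, _ = place_peptide(rna, mode="groove", seed=6)
        assert np.abs(a.coords() - b.coords()).max() == 0.0

    def test_no_steric_overlap(self, groove_complex, surface_complex):
        from scipy.spatial import cKDTree
        for cpx, _ in (groove_complex, surface_complex):
            rxyz = np.vstack([a.position for r in cpx.residues
                              if r.chain == "A" for a in r.atoms])
            pxyz = np.vstack([a.position for r in cpx.residues
                              if r.chain == "B" for a in r.atoms])
            assert cKDTree(rxyz).query(pxyz)[0].min() >= 2.2

    def test_arm_peptide_layout(self):
        pep = build_arm_peptide()
        assert len(pep) == 17
        one = "".join(
            {"GLY": "G", "LYS": "K", "HIS": "H", "ARG": "R", "PRO": "P",
             "SER": "S", "TRP": "W"}[r.name] for r in pep)
        assert one == "GKKKHRRRPSKKKRHWK"
        assert all(r.has_atom("CA") for r in pep)
        assert pep.residues[0].number == 149

    def test_pair_scheme_is_the_hairpin_topology(self):
        numbers = {n for pair in PAIR_SCHEME for n in pair}
        assert numbers.isdisjoint({40, 41, 63})
        assert (37, 70) in PAIR_SCHEME and (45, 64) in PAIR_SCHEME
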