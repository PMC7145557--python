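"""Interface profiling: fingerprints, SASA, gap index, Coulomb energy."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hairpin7sk import (buried_area, coulomb_energy, distance_fingerprint,
                        gap_index, interface_report, jitter_ensemble,
                        place_peptide, sasa, total_sasa)
from hairpin7sk.interface import COULOMB_CONSTANT, assign_charges
from hairpin7sk.structure import (Atom, Conformation, Ensemble, Residue,
                                  StructureError)


def atom_grid(chain, name_prefix, origin, nx=4, ny=4, spacing=2.0, z=0.0,
              res_name="GLY"):
    """A rigid slab of carbon atoms as one residue."""
    atoms = []
    k = 0
    for i in range(nx):
        for j in range(ny):
            k += 1
            pos = np.array(origin) + [i * spacing, j * spacing, z]
            atoms.append(Atom("C", "C", pos, k))
    return Residue(chain, 1, res_name, atoms)


class TestDistanceFingerprint:
    def test_translation_contract_distant_pose(self, m2_conf):
        rna, _ = m2_conf
        cpx, _ = place_peptide(rna, mode="distant", seed=1)
        fp = distance_fingerprint(cpx, "B", "A")
        assert (fp.ca_p > 25.0).all()
        assert (fp.ca_p < 80.0).all()

    def test_exact_distance_single_pair(self):
        pep = Residue("B", 149, "GLY", [Atom("CA", "C", np.zeros(3), 1)])
        rna = Residue("A", 40, "U", [Atom("P", "P", np.array([4.0, 0, 0]), 2),
                                     Atom("C4", "C", np.array([0, 3.0, 0]), 3),
                                     *[Atom(n, n[0], np.array([0, 3.0, 0]), 4)
                                       for n in ()]])
        fp = distance_fingerprint(Conformation([pep, rna]), "B", "A")
        assert fp.ca_p.iloc[0] == pytest.approx(4.0)
        assert fp.ca_c4.iloc[0] == pytest.approx(3.0)

    def test_groove_closer_to_bases_than_surface(self, groove_complex,
                                                 surface_complex):
        groove, _ = groove_complex
        surface, _ = surface_complex
        fg = distance_fingerprint(groove, "B", "A")
        fs = distance_fingerprint(surface, "B", "A")
        assert fg.ca_c4.mean() < fs.ca_c4.mean()

    def test_missing_ca_errors(self):
        pep = Residue("B", 149, "GLY", [Atom("N", "N", np.zeros(3), 1)])
        rna = Residue("A", 40, "U", [Atom("P", "P", np.ones(3), 2),
                                     Atom("C4", "C", np.ones(3), 3)])
        with pytest.raises(StructureError):
            distance_fingerprint(Conformation([pep, rna]), "B", "A")

    def test_rigid_motion_invariance(self, groove_complex):
        cpx, _ = groove_complex
        rng = np.random.default_rng(4)
        moved = cpx.transform(Rotation.random(random_state=rng).as_matrix(),
                              rng.uniform(-10, 10, 3))
        a = distance_fingerprint(cpx, "B", "A")
        b = distance_fingerprint(moved, "B", "A")
        assert np.abs(a.ca_p.values - b.ca_p.values).max() <= 1e-9


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        conf = Conformation([Residue("A", 1, "GLY",
                                     [Atom("C", "C", np.zeros(3), 1)])])
        area = total_sasa(conf)
        assert area == pytest.approx(4 * math.pi * (1.7 + 1.4) ** 2, rel=0.01)

    def test_far_separated_atoms_additive(self):
        one = Conformation([Residue("A", 1, "GLY",
                                    [Atom("C", "C", np.zeros(3), 1)])])
        two = Conformation([Residue("A", 1, "GLY",
                                    [Atom("C", "C", np.zeros(3), 1),
                                     Atom("C", "C", np.array([50.0, 0, 0]), 2)])])
        assert total_sasa(two) == pytest.approx(2 * total_sasa(one), rel=1e-6)

    def test_caged_atom_buried(self):
        # a central atom enclosed by a dense icosahedral-ish shell
        pts = []
        golden = math.pi * (3 - math.sqrt(5))
        for k in range(60):
            z = 1 - 2 * (k + 0.5) / 60
            r = math.sqrt(1 - z * z)
            pts.append(3.0 * np.array([r * math.cos(golden * k),
                                       r * math.sin(golden * k), z]))
        atoms = [Atom("C", "C", np.zeros(3), 1)] + [
            Atom("C", "C", p, i + 2) for i, p in enumerate(pts)]
        conf = Conformation([Residue("A", 1, "GLY", atoms)])
        table = sasa(conf)
        assert table.area.iloc[0] == pytest.approx(0.0, abs=1.0)

    def test_agrees_with_independent_implementation(self, m2_conf):
        biotite_sasa = pytest.importorskip("biotite.structure").sasa
        from hairpin7sk.io import _conformation_to_array
        from hairpin7sk.chemdata import VDW_RADII
        conf, _ = m2_conf
        small = Conformation([r.copy() for r in conf.residues[:6]])
        ours = sasa(small)["area"].sum()
        arr = _conformation_to_array(small)
        radii = np.array([VDW_RADII[e.capitalize()] for e in arr.element])
        theirs = float(np.nansum(biotite_sasa(arr, vdw_radii=radii,
                                              point_number=1000)))
        assert ours == pytest.approx(theirs, rel=0.03)


class TestGapIndex:
    def test_monotone_in_slab_separation(self):
        gaps = []
        for d in (3.8, 4.6, 5.4):
            a = atom_grid("A", "C", (0.0, 0.0, 0.0))
            b = atom_grid("B", "C", (0.0, 0.0, d), z=0.0)
            b = Residue("B", 1, "GLY",
                        [Atom("C", "C", at.position + [0, 0, d], at.serial)
                         for at in atom_grid("B", "C", (0, 0, 0)).atoms])
            conf = Conformation([a, b])
            gaps.append(gap_index(conf, "B", "A"))
        assert gaps[0] < gaps[1] < gaps[2]

    def test_grid_refinement_stability(self, groove_complex):
        cpx, _ = groove_complex
        g_coarse = gap_index(cpx, "B", "A", grid=0.8)
        g_fine = gap_index(cpx, "B", "A", grid=0.4)
        assert g_fine == pytest.approx(g_coarse, rel=0.15)

    def test_distant_chains_error(self, m2_conf):
        rna, _ = m2_conf
        cpx, _ = place_peptide(rna, mode="distant", seed=1)
        with pytest.raises(StructureError, match="contact"):
            gap_index(cpx, "B", "A")

    def test_groove_snugger_than_surface(self, groove_complex, surface_complex):
        groove, _ = groove_complex
        surface, _ = surface_complex
        assert gap_index(groove, "B", "A") < gap_index(surface, "B", "A")

    def test_symmetric_in_chain_order(self, groove_complex):
        cpx, _ = groove_complex
        assert gap_index(cpx, "B", "A") == pytest.approx(
            gap_index(cpx, "A", "B"), rel=1e-9)
        assert buried_area(cpx, "A", "B") == pytest.approx(
            buried_area(cpx, "B", "A"), rel=1e-9)


class TestCoulomb:
    def test_two_unit_charges_closed_form(self):
        # +1 e and -1 e at 3.32 A in vacuum: about -100 kcal/mol
        a = Residue("B", 1, "ARG", [Atom("NH1", "N", np.zeros(3), 1)])
        b = Residue("A", 2, "GLU", [Atom("OE1", "O", np.array([3.32, 0, 0]), 2)])
        conf = Conformation([a, b])
        qa = assign_charges(a)["NH1"]
        qb = assign_charges(b)["OE1"]
        e = coulomb_energy(conf, "B", "A", dielectric=1.0)
        assert e == pytest.approx(COULOMB_CONSTANT * qa * qb / 3.32, rel=1e-9)
        # formal charges concentrate on the lone atom: the printed anchor
        assert e == pytest.approx(-100.0, rel=0.01)

    def test_scaling_law(self, groove_complex):
        cpx, _ = groove_complex
        doubled = cpx.copy()
        doubled.set_coords(cpx.coords() * 2.0)
        assert coulomb_energy(doubled, "B", "A") == pytest.approx(
            coulomb_energy(cpx, "B", "A") / 2.0, rel=1e-9)

    def test_matches_naive_double_loop(self):
        a = Residue("B", 1, "LYS", [Atom("NZ", "N", np.array([0.0, 0, 0]), 1),
                                    Atom("CA", "C", np.array([1.5, 0, 0]), 2)])
        b = Residue("A", 2, "U", [Atom("OP1", "O", np.array([4.0, 1, 0]), 3),
                                  Atom("P", "P", np.array([5.5, 0, 0]), 4)])
        conf = Conformation([a, b])
        qa = assign_charges(a)
        qb = assign_charges(b)
        expected = 0.0
        for at_a in a.atoms:
            for at_b in b.atoms:
                r = np.linalg.norm(at_a.position - at_b.position)
                expected += 332.06 / 78.5 * qa[at_a.name] * qb[at_b.name] / r
        assert coulomb_energy(conf, "B", "A") == pytest.approx(expected, rel=1e-9)

    def test_groove_pose_more_favorable_than_retracted(self, m2_conf):
        rna, _ = m2_conf
        groove, _ = place_peptide(rna, mode="groove", seed=3)
        surface, _ = place_peptide(rna, mode="surface", seed=3)
        assert coulomb_energy(groove, "B", "A") < coulomb_energy(
            surface, "B", "A")

    def test_residue_charges_sum_to_formal(self, m2_conf, groove_complex):
        rna, _ = m2_conf
        for res in rna:
            total = sum(assign_charges(res).values())
            expected = 0.0 if not res.has_atom("P") else -1.0
            assert total == pytest.approx(expected, abs=1e-9)


class TestInterfaceReport:
    def test_single_frame_std_zero(self, groove_complex):
        cpx, _ = groove_complex
        rep = interface_report(Ensemble([cpx]), "B", "A")
        assert rep.gap_index_std == 0.0
        assert rep.coulomb_std == 0.0

    def test_self_concatenation_keeps_means(self, groove_complex):
        cpx, _ = groove_complex
        one = interface_report(Ensemble([cpx]), "B", "A")
        two = interface_report(Ensemble([cpx.copy(), cpx.copy()]), "B", "A")
        assert two.gap_index_mean == pytest.approx(one.gap_index_mean)
        assert two.coulomb_mean == pytest.approx(one.coulomb_mean)

    def test_groove_report_smaller_gap_than_surface(self, groove_complex,
                                                    surface_complex):
        groove, _ = groove_complex
        surface, _ = surface_complex
        rg = interface_report(Ensemble([groove]), "B", "A")
        rs = interface_report(Ensemble([surface]), "B", "A")
        assert rg.gap_index_mean < rs.gap_index_mean
        assert len(rg.hbond_persistence) >= 0
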