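"""Kinetic transition network thermodynamics and kinetics.

Oracles: closed-form two-state Boltzmann ratios, an independent
breadth-first-search threshold oracle for basin content, a log-domain
free-energy oracle, and the master-equation eigen-decomposition as the
reference for graph-transformation rates.
"""

import io
import math

import numpy as np
import pytest

from hairpin7sk import (KB, Minimum, RateParams, TransitionNetwork,
                        TransitionStateRec, basin_content, basin_subset,
                        free_energy_gap, interfunnel_rate, load_network,
                        occupation, planted_network, rate_matrix,
                        save_network, ts_rate)
from hairpin7sk.ktn import NetworkError

from conftest import random_small_network


def chain_network(energies, ts_energies):
    minima = {i + 1: Minimum(i + 1, e) for i, e in enumerate(energies)}
    tss = [TransitionStateRec(i + 1, e, i + 1, i + 2)
           for i, e in enumerate(ts_energies)]
    return TransitionNetwork(minima, tss)


class TestLoadSave:
    def test_minimal_dialect(self):
        net = load_network("0.0\n1.0\n", "5.0 1 2\n")
        assert len(net.minima) == 2
        assert len(net.transition_states) == 1
        assert net.minima[2].energy == 1.0

    def test_missing_minimum_reference_names_line(self):
        with pytest.raises(NetworkError, match="line 1"):
            load_network("0.0\n1.0\n", "5.0 1 3\n")

    def test_non_numeric_field_errors(self):
        with pytest.raises(NetworkError, match="non-numeric"):
            load_network("0.0\nxyz\n", "5.0 1 2\n")

    def test_full_dialect_roundtrip(self):
        net = TransitionNetwork(
            {1: Minimum(1, 0.0, 12.5, 2), 2: Minimum(2, 1.5, 11.0, 1)},
            [TransitionStateRec(1, 6.0, 1, 2, 10.0, 1)])
        min_buf, ts_buf = io.StringIO(), io.StringIO()
        save_network(net, min_buf, ts_buf, dialect="full")
        back = load_network(min_buf.getvalue(), ts_buf.getvalue(),
                            dialect="full")
        assert back.minima[1].log_prod_freq == 12.5
        assert back.minima[1].symmetry == 2
        assert back.transition_states[0].energy == 6.0

    def test_ts_below_minima_warns_not_errors(self):
        with pytest.warns(UserWarning, match="below"):
            load_network("0.0\n5.0\n", "2.0 1 2\n")


class TestOccupation:
    def test_equal_energies_split_evenly(self):
        net = chain_network([2.0, 2.0], [5.0])
        occ = occupation(net)
        assert occ[1] == pytest.approx(0.5, abs=1e-12)

    def test_kt_ln2_gives_two_thirds(self):
        params = RateParams(298.0)
        de = params.kt * math.log(2.0)
        net = chain_network([0.0, de], [5.0])
        occ = occupation(net, params)
        assert occ[1] == pytest.approx(2.0 / 3.0, abs=1e-9)
        assert occ[2] == pytest.approx(1.0 / 3.0, abs=1e-9)

    def test_five_kcal_minority_closed_form(self):
        # independent closed form exp(-dE/kT) / (1 + exp(-dE/kT))
        net = chain_network([0.0, 5.0], [8.0])
        occ = occupation(net)
        x = math.exp(-5.0 / (KB * 298.0))
        assert occ[2] == pytest.approx(x / (1.0 + x), rel=1e-9)
        assert occ[2] == pytest.approx(2.1e-4, rel=0.05)

    def test_sums_to_one_and_gauge_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            net, _ = random_small_network(rng)
            occ = occupation(net)
            assert sum(occ.values()) == pytest.approx(1.0, abs=1e-9)
            shifted = TransitionNetwork(
                {i: Minimum(i, m.energy + 123.4)
                 for i, m in net.minima.items()},
                [TransitionStateRec(t.id, t.energy + 123.4, t.min1, t.min2)
                 for t in net.transition_states])
            occ2 = occupation(shifted)
            for i in occ:
                assert occ2[i] == pytest.approx(occ[i], abs=1e-9)

    def test_mixed_frequency_data_rejected(self):
        net = TransitionNetwork({1: Minimum(1, 0.0, 10.0), 2: Minimum(2, 1.0)},
                                [TransitionStateRec(1, 5.0, 1, 2)])
        with pytest.raises(NetworkError):
            occupation(net)

    def test_deep_gap_survives_in_log_domain(self):
        net = chain_network([0.0, 140.0], [150.0])
        occ = occupation(net)
        assert occ[1] == pytest.approx(1.0, abs=1e-12)
        assert occ[2] > 0.0


def bfs_threshold_oracle(net, bottom, cutoff):
    """Exhaustive threshold-connectivity search, separate from the
    implementation's adjacency construction."""
    threshold = net.minima[bottom].energy + cutoff
    reached = {bottom}
    changed = True
    while changed:
        changed = False
        for ts in net.transition_states:
            if ts.energy > threshold:
                continue
            for a, b in ((ts.min1, ts.min2), (ts.min2, ts.min1)):
                if (a in reached and b not in reached
                        and net.minima[b].energy <= threshold):
                    reached.add(b)
                    changed = True
    return sorted(reached)


class TestBasinContent:
    def test_cutoff_above_all_barriers_includes_everything(self):
        net = chain_network([0.0, 1.0, 2.0], [3.0, 4.0])
        assert basin_subset(net, 1, 100.0) == [1, 2, 3]

    def test_zero_cutoff_is_bottom_only(self):
        net = chain_network([0.0, 1.0], [5.0])
        assert basin_subset(net, 1, 0.0) == [1]

    def test_cross_barrier_excludes_other_funnel(self, two_funnel_network):
        net, truth = two_funnel_network
        bottoms = truth.payload["bottoms"]
        subset = basin_subset(net, bottoms[0], 15.0)
        other = {int(k) for k, v in truth.payload["membership"].items()
                 if v == 1}
        assert not (set(subset) & other)

    def test_matches_bfs_oracle_on_random_networks(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            net, truth = random_small_network(rng)
            bottom = truth.payload["bottoms"][0]
            cutoff = float(rng.uniform(0.0, 30.0))
            assert basin_subset(net, bottom, cutoff) == \
                bfs_threshold_oracle(net, bottom, cutoff)

    def test_unlabeled_minimum_named_in_error(self, two_funnel_network):
        net, _ = two_funnel_network
        stripped = TransitionNetwork(
            {i: Minimum(i, m.energy) for i, m in net.minima.items()},
            list(net.transition_states))
        with pytest.raises(NetworkError, match=r"minimum \d+"):
            basin_content(stripped, 1, 15.0)

    def test_uniform_and_boltzmann_views(self, two_funnel_network):
        net, _ = two_funnel_network
        bc = basin_content(net, 1, 15.0)
        assert sum(bc.uniform.fractions.values()) == pytest.approx(1.0)
        assert sum(bc.boltzmann.fractions.values()) == pytest.approx(1.0)
        assert bc.uniform.weighting == "uniform"
        assert bc.boltzmann.weighting == "boltzmann"


class TestTsRate:
    def test_zero_barrier_gives_prefactor(self):
        net = chain_network([0.0, 0.0], [0.0])
        k = ts_rate(net, net.transition_states[0], "forward")
        assert k == pytest.approx(1e13)

    def test_ten_kcal_barrier_closed_form(self):
        net = chain_network([0.0, 1.0], [10.0])
        k = ts_rate(net, net.transition_states[0], "forward")
        oracle = 1e13 * math.exp(-10.0 / (0.0019872 * 298.0))
        assert k == pytest.approx(oracle, rel=1e-12)
        assert k == pytest.approx(4.6e5, rel=0.05)

    def test_forward_backward_ratio_is_detailed_balance(self):
        net = chain_network([0.0, 2.5], [7.0])
        ts = net.transition_states[0]
        params = RateParams()
        ratio = ts_rate(net, ts, "forward", params) / ts_rate(
            net, ts, "backward", params)
        assert ratio == pytest.approx(math.exp(-2.5 / params.kt), rel=1e-12)

    def test_negative_barrier_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            net = chain_network([0.0, 5.0], [2.0])
        ts = net.transition_states[0]
        with pytest.warns(UserWarning, match="clamped"):
            k = ts_rate(net, ts, "backward")
        assert k == pytest.approx(1e13)

    def test_harmonic_prefactor_used_when_frequencies_present(self):
        net = TransitionNetwork(
            {1: Minimum(1, 0.0, 30.0, 1), 2: Minimum(2, 1.0, 30.0, 1)},
            [TransitionStateRec(1, 4.0, 1, 2, 28.0, 1)])
        k = ts_rate(net, net.transition_states[0], "forward")
        oracle = math.exp(30.0 - 28.0) * math.exp(-4.0 / (KB * 298.0))
        assert k == pytest.approx(oracle, rel=1e-12)


class TestRateMatrix:
    def test_global_balance(self):
        rng = np.random.default_rng(7)
        net, _ = random_small_network(rng)
        K, ids = rate_matrix(net)
        assert np.abs(K.sum(axis=0)).max() <= 1e-8 * np.abs(K).max()
        occ = occupation(net)
        pi = np.array([occ[i] for i in ids])
        residual = K @ pi
        assert np.abs(residual).max() <= 1e-8 * np.abs(K).max()


class TestInterfunnelRate:
    def test_symmetric_double_well_equal_rates(self):
        net = chain_network([0.0, 0.0], [6.0])
        kab, kba = interfunnel_rate(net, [1], [2])
        assert kab == pytest.approx(kba, rel=1e-12)

    def test_three_state_chain_gt_matches_master(self):
        net = chain_network([0.0, 6.0, 1.0], [8.0, 8.5])
        m = interfunnel_rate(net, [1], [3], method="master")
        g = interfunnel_rate(net, [1], [3], method="gt")
        assert g[0] == pytest.approx(m[0], rel=1e-6)
        assert g[1] == pytest.approx(m[1], rel=1e-6)

    def test_gt_matches_master_on_planted_networks(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            net, truth = random_small_network(rng)
            membership = truth.payload["membership"]
            set_a = [int(k) for k, v in membership.items() if v == 0]
            set_b = [int(k) for k, v in membership.items() if v == 1]
            m = interfunnel_rate(net, set_a, set_b, method="master")
            g = interfunnel_rate(net, set_a, set_b, method="gt")
            assert g[0] == pytest.approx(m[0], rel=1e-6)
            assert g[1] == pytest.approx(m[1], rel=1e-6)

    def test_detailed_balance_between_sets(self, two_funnel_network):
        net, truth = two_funnel_network
        membership = truth.payload["membership"]
        set_a = [int(k) for k, v in membership.items() if v == 0]
        set_b = [int(k) for k, v in membership.items() if v == 1]
        kab, kba = interfunnel_rate(net, set_a, set_b)
        occ = occupation(net)
        pa = sum(occ[i] for i in set_a)
        pb = sum(occ[i] for i in set_b)
        assert kab / kba == pytest.approx(pb / pa, rel=1e-6)

    def test_deep_to_shallow_much_slower(self):
        net = chain_network([0.0, 8.0], [12.0])
        k_deep_to_shallow, k_back = interfunnel_rate(net, [1], [2])
        assert k_deep_to_shallow < k_back * 1e-4

    def test_disconnected_sets_error(self):
        net = TransitionNetwork({1: Minimum(1, 0.0), 2: Minimum(2, 1.0)}, [])
        with pytest.raises(NetworkError):
            interfunnel_rate(net, [1], [2])


class TestFreeEnergyGap:
    def test_identical_sets_of_energies_zero(self):
        net = chain_network([1.0, 1.0], [5.0])
        assert free_energy_gap(net, [1], [2]) == pytest.approx(0.0, abs=1e-12)

    def test_singleton_closed_form(self):
        net = chain_network([0.0, 5.0], [8.0])
        gap = free_energy_gap(net, [1], [2])
        assert gap == pytest.approx(-5.0, abs=1e-9)

    def test_sign_antisymmetry(self, two_funnel_network):
        net, truth = two_funnel_network
        membership = truth.payload["membership"]
        a = [int(k) for k, v in membership.items() if v == 0]
        b = [int(k) for k, v in membership.items() if v == 1]
        assert free_energy_gap(net, a, b) == pytest.approx(
            -free_energy_gap(net, b, a), abs=1e-12)

    def test_matches_logsumexp_oracle(self):
        rng = np.random.default_rng(5)
        ea = rng.uniform(0, 10, 10)
        eb = rng.uniform(0, 10, 10)
        minima = {i + 1: Minimum(i + 1, float(e))
                  for i, e in enumerate(np.concatenate([ea, eb]))}
        tss = [TransitionStateRec(i, 30.0, i, i + 1) for i in range(1, 20)]
        net = TransitionNetwork(minima, tss)
        gap = free_energy_gap(net, list(range(1, 11)), list(range(11, 21)))
        kt = KB * 298.0
        # independent log-domain evaluation
        la = np.log(np.sum(np.exp(-ea / kt)))
        lb = np.log(np.sum(np.exp(-eb / kt)))
        assert gap == pytest.approx(-kt * (la - lb), abs=1e-9)
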