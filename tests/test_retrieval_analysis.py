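"""Correlation statistics, distance profile, retrieval range, Q and R."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import assocmem as am
from assocmem.memory_graphs import CommunityLabels
from assocmem.retrieval_analysis import (AssemblyTraces, CorrelationMatrix,
                                         DistanceProfile,
                                         population_correlation_matrix)
from conftest import random_correlation_like


def textbook_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Two-pass reference implementation."""
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def brute_force_q(c: np.ndarray, labels: np.ndarray) -> float:
    p = c.shape[0]
    tot = 0.0
    for mu in range(p):
        for nu in range(p):
            if mu != nu:
                s = 1.0 if labels[mu] == labels[nu] else -1.0
                tot += s * c[mu, nu]
    return tot / (p * p - p)


def brute_force_r(c: np.ndarray, dist: np.ndarray, d: int) -> float:
    p = c.shape[0]
    tot = 0.0
    for v in range(p):
        for mu in range(p):
            if mu != v:
                la = 1.0 if dist[mu, v] <= d else -1.0
                tot += la * c[mu, v]
    return tot / (p * p - p)


def brute_force_retrieval_range(c_d, epsilon, y):
    """Independent re-implementation of the plateau-detection rule."""
    p2 = len(c_d) - 1
    diffs = {d: abs(c_d[d - 1] - c_d[d]) for d in range(2, p2 + 1)}
    onsets = [d for d in sorted(diffs) if diffs[d] >= epsilon]
    if not onsets:
        return 2
    for d in range(onsets[0], p2 + 1):
        win = [diffs.get(dd) for dd in range(d, d + y)]
        if None in win or len(win) < y:
            break
        if all(w < epsilon for w in win):
            return d
    return p2


class TestSelectiveMask:
    def _trial_with_peaks(self, peaks):
        from assocmem.rate_dynamics import TrialRecord
        cfg = am.SimulationConfig(n_e=len(peaks), n_g=1, n_l=1, f=0.5)
        return TrialRecord(config=cfg, stimulated_pattern=0, seed=0,
                           assembly_traces=np.zeros((1, 10)),
                           window_v_e=np.zeros((10, len(peaks)), np.float32),
                           window_t0=0.0, peak_v_e=np.asarray(peaks),
                           mean_v_g=np.zeros(10), mean_v_l=np.zeros(10),
                           f_norm=0.015)

    def test_all_quiet_gives_empty_mask(self):
        trial = self._trial_with_peaks([0.01, 0.019, 0.0])
        assert not am.selective_mask(trial).any()

    def test_zero_threshold_selects_everyone(self):
        trial = self._trial_with_peaks([0.0, 0.5])
        assert am.selective_mask(trial, threshold=0.0).all()

    def test_saturated_assembly_members_selected(self, tiny_ring, tiny_config,
                                                 tiny_network):
        trial = am.run_trial(tiny_config, tiny_network, graph=tiny_ring,
                             stimulated_pattern=0, seed=2)
        members = tiny_network.patterns.members(0)
        mask = am.selective_mask(trial)
        assert mask[members].mean() > 0.9


class TestAssemblyTraces:
    def test_zero_rates_give_zero_traces(self, tiny_ring, tiny_config,
                                         tiny_network):
        cfg = tiny_config.with_(h_ext=0.0, noise_sd=0.0)
        trial = am.run_trial(cfg, tiny_network, graph=tiny_ring,
                             stimulated_pattern=0, seed=0)
        traces = am.assembly_traces(trial, tiny_network.patterns)
        assert np.all(traces.a == 0.0)

    def test_shared_neuron_contributes_to_both(self):
        import scipy.sparse as sp
        from assocmem.network_construction import PatternMatrix
        from assocmem.rate_dynamics import TrialRecord
        xi = sp.csr_matrix(np.array([[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]]))
        pm = PatternMatrix(xi=xi, li_members=[], f=0.5)
        cfg = am.SimulationConfig(n_e=3, n_g=1, n_l=1, f=0.5, t_end=0.3,
                                  t_stim=0.1)
        rates = np.array([[0.1, 0.2, 0.4],
                          [0.0, 0.1, 0.1],
                          [0.3, 0.0, 0.2]], dtype=np.float32)
        trial = TrialRecord(config=cfg, stimulated_pattern=0, seed=0,
                            assembly_traces=xi @ rates.T,
                            window_v_e=rates, window_t0=0.0,
                            peak_v_e=rates.max(axis=0),
                            mean_v_g=np.zeros(3), mean_v_l=np.zeros(3),
                            f_norm=0.015)
        traces = am.assembly_traces(trial, pm, window=(0.0, 0.3))
        assert np.allclose(traces.a[0], [0.3, 0.1, 0.3])
        assert np.allclose(traces.a[1], [0.6, 0.2, 0.2])

    def test_window_outside_record_rejected(self, tiny_ring, tiny_config,
                                            tiny_network):
        trial = am.run_trial(tiny_config, tiny_network, graph=tiny_ring,
                             stimulated_pattern=0, seed=0)
        with pytest.raises(ValueError):
            am.assembly_traces(trial, tiny_network.patterns,
                               window=(0.0, 50.0))


class TestCorrelationMatrix:
    def test_affine_invariance(self):
        t = np.linspace(0, 1, 50)
        a = np.vstack([t, 2 * t + 1, -t])
        c = am.correlation_matrix(AssemblyTraces(a=a, window=(0, 5)))
        assert c.c[0, 1] == pytest.approx(1.0)
        assert c.c[0, 2] == pytest.approx(-1.0)

    def test_known_pearson_value(self):
        a = np.array([[1.0, 2, 3, 4], [1.0, 3, 2, 4]])
        c = am.correlation_matrix(AssemblyTraces(a=a, window=(0, 0.4)))
        assert c.c[0, 1] == pytest.approx(0.8)

    def test_matches_textbook_two_pass(self):
        rng = np.random.default_rng(5)
        a = rng.random((6, 40))
        c = am.correlation_matrix(AssemblyTraces(a=a, window=(0, 4)))
        for i in range(6):
            for j in range(6):
                if i != j:
                    assert c.c[i, j] == pytest.approx(
                        textbook_pearson(a[i], a[j]), abs=1e-12)

    def test_zero_variance_flagged_and_zeroed(self):
        a = np.vstack([np.ones(20), np.linspace(0, 1, 20)])
        c = am.correlation_matrix(AssemblyTraces(a=a, window=(0, 2)))
        assert c.zero_variance[0] and not c.zero_variance[1]
        assert c.c[0, 1] == 0.0 and c.c[0, 0] == 1.0

    def test_population_mode_matches_numpy(self):
        rng = np.random.default_rng(8)
        states = {i: rng.random(200) for i in range(5)}
        c = population_correlation_matrix(states, 5)
        ref = np.corrcoef(np.vstack([states[i] for i in range(5)]))
        assert np.allclose(c.c, ref, atol=1e-12)

    def test_population_mode_partial_battery_has_nans(self):
        rng = np.random.default_rng(8)
        states = {0: rng.random(50), 3: rng.random(50)}
        c = population_correlation_matrix(states, 5)
        assert np.isnan(c.c[1, 2])
        assert not np.isnan(c.c[0, 3])


class TestDistanceProfile:
    def test_distance_zero_is_unity(self, ring100):
        rng = np.random.default_rng(0)
        c = CorrelationMatrix(c=random_correlation_like(rng, 100),
                              zero_variance=np.zeros(100, bool))
        prof = am.distance_profile(c, ring100)
        assert prof.c_d[0] == pytest.approx(1.0)

    def test_all_ones_matrix_gives_flat_unity(self, ring100):
        c = CorrelationMatrix(c=np.ones((100, 100)),
                              zero_variance=np.zeros(100, bool))
        prof = am.distance_profile(c, ring100)
        assert np.allclose(prof.c_d, 1.0)

    def test_four_pattern_toy_hand_computed(self):
        ring4 = am.build_ring_chain(4)
        c = np.array([
            [1.0, 0.8, 0.2, 0.6],
            [0.8, 1.0, 0.4, 0.0],
            [0.2, 0.4, 1.0, 0.5],
            [0.6, 0.0, 0.5, 1.0],
        ])
        cm = CorrelationMatrix(c=c, zero_variance=np.zeros(4, bool))
        prof = am.distance_profile(cm, ring4)
        # Eq over all rows: C_1 = mean of both ring neighbors per row
        c1 = np.mean([(0.8 + 0.6) / 2, (0.4 + 0.8) / 2,
                      (0.5 + 0.4) / 2, (0.6 + 0.5) / 2])
        c2 = np.mean([0.2, 0.0, 0.2, 0.0])
        assert prof.c_d[1] == pytest.approx(c1)
        assert prof.c_d[2] == pytest.approx(c2)

    def test_non_ring_graph_rejected(self, karate):
        c = CorrelationMatrix(c=np.eye(34), zero_variance=np.zeros(34, bool))
        with pytest.raises(ValueError):
            am.distance_profile(c, karate)

    def test_per_trial_row_profile(self, ring100):
        rng = np.random.default_rng(3)
        c = CorrelationMatrix(c=random_correlation_like(rng, 100),
                              zero_variance=np.zeros(100, bool))
        prof = am.distance_profile(c, ring100, stimulated=10)
        expected_d3 = (c.c[10, 13] + c.c[10, 7]) / 2
        assert prof.c_d[3] == pytest.approx(expected_d3)


class TestRetrievalRange:
    def _profile(self, values):
        return DistanceProfile(c_d=np.asarray(values, float),
                               p=2 * (len(values) - 1))

    def test_flat_profile_gives_minimum_range(self):
        prof = self._profile(np.ones(51))
        assert am.retrieval_range(prof).d == 2

    def test_everywhere_steep_profile_falls_back_to_half_ring(self):
        vals = [1.0 - 0.06 * k for k in range(51)]
        assert am.retrieval_range(self._profile(vals)).d == 50

    def test_step_profile_detects_end_of_decay(self):
        vals = [1.0] * 21 + [0.8, 0.6, 0.4, 0.2] + [0.0] * 26
        assert am.retrieval_range(self._profile(vals)).d == 26

    def test_short_profile_rejected(self):
        prof = DistanceProfile(c_d=np.ones(10), p=100)
        with pytest.raises(ValueError):
            am.retrieval_range(prof)

    @given(seed=st.integers(0, 100_000))
    @settings(deadline=None, max_examples=50)
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        # random piecewise profiles: plateaus and ramps
        vals = np.clip(np.cumsum(rng.choice(
            [0.0, 0.0, -0.02, -0.08, 0.06], size=51)) + 1.0, -1, 1)
        vals[0] = 1.0
        prof = self._profile(vals)
        got = am.retrieval_range(prof).d
        want = brute_force_retrieval_range(vals, 0.05, 5)
        assert got == want
        assert 2 <= got <= 50


class TestIndices:
    def test_single_community_reduces_to_mean(self):
        c = np.full((6, 6), 0.3)
        np.fill_diagonal(c, 1.0)
        cm = CorrelationMatrix(c=c, zero_variance=np.zeros(6, bool))
        labels = CommunityLabels(labels=np.zeros(6, int), seed=0)
        assert am.clustering_index(cm, labels) == pytest.approx(0.3)

    def test_balanced_split_cancels(self):
        # communities of equal size: half the ordered pairs within
        c = np.full((4, 4), 0.5)
        np.fill_diagonal(c, 1.0)
        cm = CorrelationMatrix(c=c, zero_variance=np.zeros(4, bool))
        # sizes 2+2: within-pairs = 4, between = 8 -> not balanced; build
        # an exact cancellation with community sizes 1,1,... all singleton
        # vs pairs: use labels (0,0,1,1): within=4 ordered, between=8
        labels = CommunityLabels(labels=np.array([0, 0, 1, 1]), seed=0)
        q = am.clustering_index(cm, labels)
        assert q == pytest.approx(0.5 * (4 - 8) / 12)

    def test_four_vertex_toy_brute_force(self):
        rng = np.random.default_rng(2)
        c = random_correlation_like(rng, 4)
        cm = CorrelationMatrix(c=c, zero_variance=np.zeros(4, bool))
        labels = CommunityLabels(labels=np.array([0, 0, 1, 1]), seed=0)
        assert am.clustering_index(cm, labels) == pytest.approx(
            brute_force_q(c, labels.labels), abs=1e-12)

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=15)
    def test_q_and_r_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(4, 31))
        ring = am.build_ring_chain(p)
        c = random_correlation_like(rng, p)
        cm = CorrelationMatrix(c=c, zero_variance=np.zeros(p, bool))
        labels = CommunityLabels(
            labels=rng.integers(0, 3, size=p), seed=0)
        dist = am.shortest_path_matrix(ring)
        assert am.clustering_index(cm, labels) == pytest.approx(
            brute_force_q(c, labels.labels), abs=1e-12)
        for d in range(1, dist.max() + 1):
            assert am.geometric_index(cm, ring, d) == pytest.approx(
                brute_force_r(c, dist, d), abs=1e-12)

    def test_r_at_diameter_equals_mean_offdiagonal(self, karate):
        rng = np.random.default_rng(9)
        c = random_correlation_like(rng, 34)
        cm = CorrelationMatrix(c=c, zero_variance=np.zeros(34, bool))
        r = am.geometric_index(cm, karate, am.diameter(karate))
        assert r == pytest.approx(cm.mean_offdiag(), abs=1e-12)

    def test_radius_out_of_range_rejected(self, karate):
        cm = CorrelationMatrix(c=np.eye(34), zero_variance=np.zeros(34, bool))
        with pytest.raises(ValueError):
            am.geometric_index(cm, karate, 0)
        with pytest.raises(ValueError):
            am.geometric_index(cm, karate, 6)

    def test_scan_reports_best_radius(self, karate):
        rng = np.random.default_rng(4)
        c = random_correlation_like(rng, 34)
        cm = CorrelationMatrix(c=c, zero_variance=np.zeros(34, bool))
        labels = am.label_propagation(karate, seed=1)
        res = am.geometric_index_scan(cm, karate, labels=labels)
        assert set(res.r_by_d) == set(range(1, 6))
        d_best, r_best = res.best
        assert r_best == max(res.r_by_d.values())
        assert res.r_by_d[d_best] == r_best
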