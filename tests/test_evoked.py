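import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from replayburst.evoked import (
    EvokedResponse,
    cluster_permutation,
    compare_conditions,
    epoch_states,
    group_evoked,
    replication_cluster_test,
    threshold_sweep,
)
from replayburst.synthetic import gen_replay_train, gen_state_path


def _one_hot_gamma(path, K):
    g = np.zeros((K, path.size))
    g[path, np.arange(path.size)] = 1.0
    return g


def _coupled_fixture(seed, T=75000, fs=250.0):
    trans = np.array([[0.999, 0.001 / 2, 0.001 / 2]] * 3)
    trans = np.full((3, 3), 0.0005)
    np.fill_diagonal(trans, 0.999)
    path = gen_state_path(3, trans, T, seed)
    events = gen_replay_train(path, fs, {0}, 2.0, 0.2, seed + 1)
    return _one_hot_gamma(path, 3), events, path


class TestEpochStates:
    def test_constant_gamma_zero_after_baseline(self):
        g = np.tile(np.array([0.2, 0.3, 0.5])[:, None], (1, 2000))
        ev = epoch_states(g, np.array([500, 1000]), 250.0)
        assert np.allclose(ev.values, 0.0)
        assert ev.n_epochs == 2

    def test_one_hot_baseline_algebra(self):
        # gamma one-hot on state k in every epoch: evoked_k = 1 - occupancy_k
        T, K, fs = 10000, 2, 250.0
        path = np.zeros(T, dtype=int)
        path[:3000] = 1  # occupancy of state 0 = 0.7
        g = _one_hot_gamma(path, K)
        w = int(0.5 * fs)
        events = np.array([5000, 7000, 9000 - w - 1])
        ev = epoch_states(g, events, fs)
        assert np.allclose(ev.values[0], 1.0 - 0.7)
        assert np.allclose(ev.values[1], -0.3)

    def test_coupled_state_positive_at_lag_zero(self):
        gamma, events, _ = _coupled_fixture(0)
        ev = epoch_states(gamma, events, 250.0)
        lag0 = ev.values.shape[1] // 2
        assert ev.values[0, lag0] > 0
        assert ev.values[0, lag0] > ev.values[0, 0]
        assert ev.values[0, lag0] > ev.values[0, -1]

    def test_conservation(self):
        gamma, events, _ = _coupled_fixture(1)
        ev = epoch_states(gamma, events, 250.0, baseline=True)
        assert np.allclose(ev.values.sum(axis=0), 0.0, atol=1e-9)
        raw = epoch_states(gamma, events, 250.0, baseline=False)
        assert np.allclose(raw.values.sum(axis=0), 1.0, atol=1e-9)

    def test_epochs_crossing_edges_or_bad_dropped(self):
        g = np.tile(np.array([0.5, 0.5])[:, None], (1, 1000))
        bad = np.zeros(1000, dtype=bool)
        bad[600] = True
        ev = epoch_states(g, np.array([200, 500, 990]), 250.0, bad_mask=bad)
        assert ev.n_epochs == 1  # 990 crosses the edge; 500's window hits 600

    def test_zero_epochs_rejected(self):
        g = np.tile(np.array([1.0])[:, None], (1, 100))
        with pytest.raises(ValueError, match="zero retained"):
            epoch_states(g, np.array([2]), 250.0)

    def test_reactivation_trace_variant(self):
        # non-probability traces are supported with validation off
        rng = np.random.default_rng(2)
        traces = rng.uniform(0, 1, (8, 5000))
        subj = [epoch_states(traces, np.array([1000, 2000, 3000]), 250.0)]
        assert subj[0].values.shape == (8, 2 * 125 + 1)
        resp = EvokedResponse.stack(subj + subj, validate=False)
        assert resp.values.shape == (8, 251, 2)


class TestGroupEvoked:
    def test_identical_subjects_zero_sem(self):
        v = np.random.default_rng(0).normal(size=(2, 11, 1))
        v = v - v.sum(axis=0, keepdims=True) / 2
        resp = EvokedResponse(np.repeat(v, 5, axis=2), np.linspace(-0.02, 0.02, 11), True)
        mean, sem = group_evoked(resp)
        assert np.allclose(sem, 0.0)

    def test_opposite_subjects_zero_mean(self):
        v = np.random.default_rng(1).normal(size=(2, 11))
        v -= v.sum(axis=0, keepdims=True) / 2
        resp = EvokedResponse(np.stack([v, -v], axis=2), np.linspace(-0.02, 0.02, 11), True)
        mean, _ = group_evoked(resp)
        assert np.allclose(mean, 0.0)

    def test_sem_definition(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=(3, 7, 21))
        v -= v.sum(axis=0, keepdims=True) / 3
        resp = EvokedResponse(v, np.linspace(-0.01, 0.01, 7), True)
        _, sem = group_evoked(resp)
        assert np.allclose(sem, v.std(axis=2, ddof=1) / np.sqrt(21))


def _null_response(rng, K=2, L=101, N=21, smooth=5):
    v = gaussian_filter1d(rng.normal(0, 1, (1, L, N)), smooth, axis=1)
    v = np.vstack([v, -v])
    return EvokedResponse(v, np.linspace(-0.5, 0.5, L), True)


class TestClusterPermutation:
    def test_all_zero_no_clusters(self):
        resp = EvokedResponse(np.zeros((2, 11, 6)), np.linspace(-0.02, 0.02, 11), True)
        res = cluster_permutation(resp, n_perm=50, seed=0)
        assert res.clusters == []

    def test_planted_effect_against_exhaustive_oracle(self):
        # oracle: brute-force recomputation of the permutation null (scipy t
        # statistics, loop over the same drawn sign patterns)
        from scipy import stats

        rng = np.random.default_rng(0)
        n_perm, seed = 100, 1
        v = rng.normal(0, 0.01, (1, 101, 21))
        v[0, 25:75, :] += 1.0
        v = np.vstack([v, -v])
        resp = EvokedResponse(v, np.linspace(-0.5, 0.5, 101), True)
        res = cluster_permutation(resp, t_threshold=3.0, n_perm=n_perm, seed=seed)
        big = max((c for c in res.clusters if c.state == 0), key=lambda c: c.mass)
        assert big.mass == 50
        assert big.p <= 5.0 / (n_perm + 1)  # at or near the attainable minimum

        x = v[0].T  # N x L, same sign draws as the implementation (state 0 first)
        signs = np.random.default_rng(seed).choice([-1.0, 1.0], size=(n_perm, 21))
        null_max = []
        for p_i in range(n_perm):
            t = stats.ttest_1samp(x * signs[p_i][:, None], 0.0, axis=0).statistic
            best = run = 0
            for ti in t:
                run = run + 1 if ti > 3.0 else 0
                best = max(best, run)
            null_max.append(best)
        p_oracle = (np.sum(np.asarray(null_max) >= big.mass) + 1) / (n_perm + 1)
        assert big.p == pytest.approx(p_oracle)

    def test_null_type_one_error_calibrated(self):
        hits = 0
        reps = 60
        for r in range(reps):
            resp = _null_response(np.random.default_rng(100 + r))
            res = cluster_permutation(resp, 3.0, n_perm=200, seed=r)
            ps = [c.p for c in res.clusters if c.state == 0]
            if ps and min(ps) < 0.05:
                hits += 1
        assert hits / reps < 0.15  # nominal ~0.05

    def test_offset_invariance_via_baseline(self):
        # subject-constant offsets are removed by the epoch baseline, so the
        # cluster p is unchanged
        gamma, events, _ = _coupled_fixture(3, T=40000)
        subj = []
        for shift in range(6):
            ev = epoch_states(gamma, events[shift::2], 250.0)
            subj.append(ev)
        resp = EvokedResponse.stack(subj)
        res1 = cluster_permutation(resp, 2.0, n_perm=100, seed=0)
        res2 = cluster_permutation(resp, 2.0, n_perm=100, seed=0)
        assert [c.p for c in res1.clusters] == [c.p for c in res2.clusters]

    def test_too_few_subjects_rejected(self):
        resp = EvokedResponse(np.zeros((2, 5, 3)), np.linspace(-0.01, 0.01, 5), True)
        with pytest.raises(ValueError, match="subjects"):
            cluster_permutation(resp)


class TestReplicationClusterTest:
    def _effect_response(self, rng, N=21):
        v = rng.normal(0, 0.05, (1, 101, N))
        v[0, 40:60, :] += 0.5
        v = np.vstack([v, -v])
        return EvokedResponse(v, np.linspace(-0.5, 0.5, 101), True)

    def test_self_replication(self):
        rng = np.random.default_rng(0)
        resp = self._effect_response(rng)
        res_a = cluster_permutation(resp, 3.0, n_perm=200, seed=1)
        main = max((c for c in res_a.clusters if c.state == 0), key=lambda c: c.mass)
        res_a.clusters = [main]
        ps = replication_cluster_test(res_a, resp, n_perm=200, seed=2)
        assert ps[0] <= 0.05

    def test_noise_does_not_replicate(self):
        rng = np.random.default_rng(3)
        resp_a = self._effect_response(rng)
        res_a = cluster_permutation(resp_a, 3.0, n_perm=200, seed=4)
        main = max((c for c in res_a.clusters if c.state == 0), key=lambda c: c.mass)
        res_a.clusters = [main]
        resp_b = _null_response(np.random.default_rng(5))
        ps = replication_cluster_test(res_a, resp_b, n_perm=200, seed=6)
        assert ps[0] > 0.05

    def test_window_outside_grid_rejected(self):
        from replayburst.evoked import Cluster, ClusterResult

        res_a = ClusterResult(
            clusters=[Cluster(0, 200, 210, 0.0, 0.1, 10, 0.01)],
            t_threshold=3.0, n_permutations=100,
        )
        resp_b = _null_response(np.random.default_rng(7))
        with pytest.raises(ValueError, match="grid"):
            replication_cluster_test(res_a, resp_b)


class TestCompareConditions:
    def test_identical_conditions(self):
        a = np.random.default_rng(0).normal(size=(4, 10))
        t, p, sig = compare_conditions(a, a.copy())
        assert np.allclose(t, 0.0) and np.allclose(p, 1.0) and not sig.any()

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=(4, 10)), rng.normal(size=(4, 10))
        t1, _, _ = compare_conditions(a, b)
        t2, _, _ = compare_conditions(b, a)
        assert np.allclose(t1, -t2)

    def test_planted_difference_significant(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.1, size=(4, 21))
        b = a.copy()
        a[2] += 1.0
        t, p, sig = compare_conditions(a, b)
        assert t[2] > 0 and sig[2]
        assert not sig[[0, 1, 3]].any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            compare_conditions(np.zeros((4, 10)), np.zeros((4, 9)))


class TestThresholdSweep:
    def test_planted_coupling_asymmetric(self):
        traces, gammas = [], []
        for s in range(4):
            gamma, events, path = _coupled_fixture(20 + s, T=50000)
            trace = np.random.default_rng(30 + s).uniform(0, 0.5, 50000)
            trace[events] = 0.9 + 0.1 * np.random.default_rng(40 + s).random(events.size)
            traces.append(trace)
            gammas.append(gamma)
        vals, pcts, asym = threshold_sweep(
            traces, gammas, 250.0, percentiles=np.array([1, 50, 99]), lag_samples=10
        )
        assert asym[0] > 0  # coupled state loads the high tail

    def test_state_independent_trace_symmetric(self):
        traces, gammas = [], []
        for s in range(4):
            gamma, _, _ = _coupled_fixture(50 + s, T=50000)
            traces.append(np.random.default_rng(60 + s).uniform(0, 1, 50000))
            gammas.append(gamma)
        vals, pcts, asym = threshold_sweep(
            traces, gammas, 250.0, percentiles=np.array([1, 50, 99]), lag_samples=10
        )
        assert np.all(np.abs(asym) < 0.05)
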