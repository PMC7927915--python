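import numpy as np
import pytest
from scipy import signal as sps

from replayburst.io import RecordingSession
from replayburst.synthetic import (
    SimConfig,
    StateComponent,
    gen_localizer,
    gen_replay_train,
    gen_state_path,
    gen_state_signals,
    lag_to_samples,
    plant_hf_bursts,
    plant_reactivations,
    simulate_subject,
)
from replayburst.bursts import fano_curve


class TestGenStatePath:
    def test_absorbing_identity_chain(self):
        path = gen_state_path(2, np.eye(2), 1000, seed=0, start=0)
        assert np.all(path == 0)

    def test_empirical_transition_rates(self):
        # oracle: direct counting of transitions on a long chain
        K, T = 3, 250_000
        off = 0.05
        trans = np.full((K, K), off)
        np.fill_diagonal(trans, 1 - 2 * off)
        path = gen_state_path(K, trans, T, seed=42)
        counts = np.zeros((K, K))
        np.add.at(counts, (path[:-1], path[1:]), 1)
        rates = counts / counts.sum(axis=1, keepdims=True)
        offdiag = rates[~np.eye(K, dtype=bool)]
        assert np.all(np.abs(offdiag - off) < 0.005)

    def test_symmetric_chain_occupancy(self):
        path = gen_state_path(2, np.full((2, 2), 0.5), 100_000, seed=1)
        occ = np.mean(path == 0)
        assert 0.49 <= occ <= 0.51

    def test_non_stochastic_rejected_naming_row(self):
        bad = np.array([[0.5, 0.5], [0.3, 0.3]])
        with pytest.raises(ValueError, match="row 1"):
            gen_state_path(2, bad, 100, seed=0)

    def test_needs_two_states(self):
        with pytest.raises(ValueError):
            gen_state_path(1, np.ones((1, 1)), 100, seed=0)


class TestGenStateSignals:
    def test_pure_sinusoid_psd_peak(self):
        # oracle: FFT of the output
        path = np.zeros(5000, dtype=int)
        spec = {0: [StateComponent(10.0, (0,), 1.0, False)]}
        sess = gen_state_signals(path, 250.0, spec, 0.0, 3, n_channels=2)
        freqs = np.fft.rfftfreq(5000, 1 / 250.0)
        amp = np.abs(np.fft.rfft(sess.data[0]))
        assert freqs[np.argmax(amp)] == pytest.approx(10.0, abs=0.05)
        assert np.ptp(sess.data[1]) == 0.0

    def test_shared_phase_coherence(self):
        path = np.zeros(30000, dtype=int)
        spec = {0: [StateComponent(10.0, (0, 1), 1.0, True)]}
        sess = gen_state_signals(path, 250.0, spec, 0.05, 4, n_channels=2)
        f, coh = sps.coherence(sess.data[0], sess.data[1], fs=250.0, nperseg=1024)
        assert coh[np.argmin(np.abs(f - 10.0))] > 0.95

    def test_white_noise_low_coherence(self):
        # white-noise coherence bias bound, T >= 60 s
        path = np.zeros(16000, dtype=int)
        sess = gen_state_signals(path, 250.0, {}, 1.0, 5, n_channels=2)
        f, coh = sps.coherence(sess.data[0], sess.data[1], fs=250.0, nperseg=512)
        assert np.all(coh < 0.2)

    def test_nyquist_rejected(self):
        spec = {0: [StateComponent(130.0, (0,), 1.0, False)]}
        with pytest.raises(ValueError, match="Nyquist"):
            gen_state_signals(np.zeros(100, int), 250.0, spec, 1.0, 0)


class TestGenReplayTrain:
    def test_homogeneous_fano_near_one(self):
        # equal rates give a homogeneous Poisson process; Fano ~ 1
        path = np.zeros(150_000, dtype=int)  # 600 s at 250 Hz
        fanos = []
        for s in range(10):
            ev = gen_replay_train(path, 250.0, {0}, 1.0, 1.0, seed=s)
            fanos.append(fano_curve(ev, 150_000, 250.0, None, np.array([10.0])).fano[0, 0])
        assert 0.7 <= np.mean(fanos) <= 1.3

    def test_rate_out_zero_events_in_coupled_state(self):
        path = gen_state_path(2, np.full((2, 2), 0.5), 50_000, seed=3)
        ev = gen_replay_train(path, 250.0, {1}, 5.0, 0.0, seed=4)
        assert ev.size > 0
        assert np.all(path[ev] == 1)

    def test_mmpp_is_bursty(self):
        # analytic MMPP: Fano > 1 when rates differ
        trans = np.array([[0.996, 0.004], [0.004 / 3, 1 - 0.004 / 3]])  # ~20% occupancy
        path = gen_state_path(2, trans, 150_000, seed=5)
        ev = gen_replay_train(path, 250.0, {0}, 3.0, 0.1, seed=6)
        f = fano_curve(ev, 150_000, 250.0, None, np.array([10.0])).fano[0, 0]
        assert f > 1.0

    def test_empty_coupled_with_zero_rate_out_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            ev = gen_replay_train(np.zeros(1000, int), 250.0, set(), 1.0, 0.0, seed=0)
        assert ev.size == 0

    def test_bad_rates_rejected(self):
        with pytest.raises(ValueError):
            gen_replay_train(np.zeros(100, int), 250.0, {0}, 1.0, 2.0, seed=0)

    def test_strictly_increasing(self):
        path = np.zeros(75_000, dtype=int)
        ev = gen_replay_train(path, 250.0, {0}, 3.0, 3.0, seed=9)
        assert np.all(np.diff(ev) > 0)


class TestGenLocalizer:
    def test_noiseless_trials_identical_at_peak(self):
        loc, patterns = gen_localizer(4, 16, 6, 100.0, 300.0, 150.0, np.inf, seed=0)
        idx = loc.sample_at(150.0)
        for lab in range(4):
            sel = loc.trials[loc.labels == lab, :, idx]
            assert np.allclose(sel, sel[0])
            assert np.allclose(sel[0], patterns[lab])

    def test_decodable_at_default_snr(self):
        # oracle: plain logistic regression on the generated fixture
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        loc, _ = gen_localizer(8, 160, 12, 250.0, 400.0, 200.0, 1.0, seed=1)
        x = loc.trials[:, :, loc.sample_at(200.0)]
        acc = cross_val_score(LogisticRegression(max_iter=2000), x, loc.labels, cv=5).mean()
        assert acc > 0.5  # chance is 0.125

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match="cross-validation"):
            gen_localizer(8, 15, 6, 100.0, 300.0, 150.0, 1.0, seed=0)

    def test_peak_outside_window_rejected(self):
        with pytest.raises(ValueError):
            gen_localizer(4, 16, 6, 100.0, 300.0, 400.0, 1.0, seed=0)


class TestPlantReactivations:
    def test_gain_zero_identity(self):
        sess = RecordingSession(np.random.default_rng(0).standard_normal((4, 1000)), 250.0)
        out = plant_reactivations(sess, np.zeros((2, 4)), np.array([100]), 40.0, [(0, 1)], 0.0)
        assert np.array_equal(out.data, sess.data)

    def test_lag_is_exactly_ten_samples(self):
        assert lag_to_samples(40.0, 250.0) == 10
        sess = RecordingSession(np.zeros((2, 1000)), 250.0)
        patterns = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = plant_reactivations(
            sess, patterns, np.array([500]), 40.0, [(0, 1)], 1.0, kernel=np.array([1.0])
        )
        assert out.data[0, 500] == 1.0
        assert out.data[1, 510] == 1.0
        assert out.data[:, :499].sum() == 0

    def test_fractional_lag_rejected(self):
        sess = RecordingSession(np.zeros((2, 100)), 250.0)
        with pytest.raises(ValueError, match="integer"):
            plant_reactivations(sess, np.zeros((2, 2)), np.array([10]), 10.0, [(0, 1)], 1.0)

    def test_decoder_sees_planted_event(self):
        # oracle: apply known weights beta to the constructed signal
        rng = np.random.default_rng(2)
        patterns = np.linalg.qr(rng.standard_normal((6, 2)))[0].T  # orthonormal
        sess = RecordingSession(0.01 * rng.standard_normal((6, 2000)), 250.0)
        out = plant_reactivations(
            sess, patterns, np.array([800]), 40.0, [(0, 1)], 5.0, kernel=np.array([1.0])
        )
        logit0 = patterns[0] @ out.data
        logit1 = patterns[1] @ out.data
        assert np.argmax(logit0) == 800
        assert np.argmax(logit1) == 810

    def test_event_near_end_dropped(self, caplog):
        sess = RecordingSession(np.zeros((2, 100)), 250.0)
        out = plant_reactivations(
            sess, np.ones((2, 2)), np.array([95]), 40.0, [(0, 1)], 1.0
        )
        assert np.all(out.data[:, 96:] == 0)  # successor would land at 105


class TestPlantHfBursts:
    def _wideband(self, T=60000):
        rng = np.random.default_rng(5)
        return RecordingSession(rng.standard_normal((4, T)), 600.0)

    def test_zero_sd_identity(self):
        sess = self._wideband(6000)
        out = plant_hf_bursts(sess, np.zeros(6000, int), 0, (102.0, 148.0), 0.0, seed=0)
        assert np.array_equal(out.data, sess.data)

    def test_psd_elevated_during_hf_state(self):
        # oracle: Welch PSD on state-masked segments
        T = 120000
        sess = self._wideband(T)
        path = np.zeros(T, dtype=int)
        path[: T // 2] = 1
        out = plant_hf_bursts(sess, path, 1, (102.0, 148.0), 2.0, seed=1, channels=(0, 1))
        f, p_on = sps.welch(out.data[0, : T // 2], fs=600.0, nperseg=1024)
        _, p_off = sps.welch(out.data[0, T // 2 :], fs=600.0, nperseg=1024)
        band = (f >= 102) & (f <= 148)
        gap_db = 10 * np.log10(p_on[band].mean() / p_off[band].mean())
        assert gap_db > 3.0

    def test_band_at_lowpass_rejected(self):
        sess = self._wideband(6000)
        with pytest.raises(ValueError, match="low-pass"):
            plant_hf_bursts(sess, np.zeros(6000, int), 0, (120.0, 160.0), 1.0, seed=0)

    def test_analysis_band_overlap_warns(self):
        sess = self._wideband(6000)
        with pytest.warns(UserWarning, match="contaminate"):
            plant_hf_bursts(sess, np.zeros(6000, int), 0, (30.0, 80.0), 1.0, seed=0)


class TestComposite:
    def test_determinism(self):
        cfg = SimConfig(n_subjects=1, duration_s=20.0, n_channels=6, K=3,
                        state_freqs=(4.0, 10.0, 25.0), n_trials=80)
        a = simulate_subject(cfg, 5)
        b = simulate_subject(cfg, 5)
        assert np.array_equal(a.session.data, b.session.data)
        assert np.array_equal(a.wideband.data, b.wideband.data)
        assert np.array_equal(a.truth.replay_times, b.truth.replay_times)
        c = simulate_subject(cfg, 6)
        assert not np.array_equal(a.session.data, c.session.data)

    def test_ground_truth_composability(self):
        cfg = SimConfig(n_subjects=1, duration_s=30.0, n_channels=6, K=3,
                        state_freqs=(4.0, 10.0, 25.0), n_trials=80)
        fx = simulate_subject(cfg, 0)
        assert fx.truth.state_path.size == fx.session.n_samples
        assert fx.truth.coupled_states == frozenset(cfg.coupled_states)
        assert fx.truth.hf_state == cfg.hf_state
        assert np.all(np.diff(fx.truth.replay_times) > 0)
        lag = lag_to_samples(cfg.replay_lag_ms, cfg.fs)
        max_chain = max(len(c) for c in cfg.sequences)
        assert fx.truth.replay_times.max() + lag * (max_chain - 1) < fx.session.n_samples

    def test_per_state_covariance_stationarity(self):
        # per-state sample covariance converges over long T (5% Frobenius)
        T = 250_000
        trans = np.array([[0.999, 0.001], [0.001, 0.999]])
        path = gen_state_path(2, trans, T, seed=7)
        spec = {0: [StateComponent(5.0, (0, 1), 1.5, True)],
                1: [StateComponent(25.0, (0, 1), 1.5, True)]}
        sess = gen_state_signals(path, 250.0, spec, 1.0, 8, n_channels=2)
        half = T // 2
        for k in range(2):
            m1 = (path[:half] == k)
            m2 = (path[half:] == k)
            c1 = np.cov(sess.data[:, :half][:, m1])
            c2 = np.cov(sess.data[:, half:][:, m2])
            rel = np.linalg.norm(c1 - c2) / np.linalg.norm(c1)
            assert rel < 0.05
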