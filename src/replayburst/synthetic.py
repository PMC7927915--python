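"""Synthetic fixture generation with planted ground truth.

Fixtures emulate: Markov-switching hidden states with distinct spectral
signatures, functional-localizer trials with stimulus-specific spatial
patterns, resting data carrying pairwise sequential reactivations at a
fixed lag whose event times form a state-coupled (Markov-modulated
Poisson) process, and a wideband twin carrying high-frequency power
bursts coupled to one state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import GroundTruth, LocalizerTrials, RecordingSession, SubjectFixture

logger = logging.getLogger(__name__)

__all__ = [
    "StateComponent",
    "SimConfig",
    "gen_state_path",
    "gen_state_signals",
    "gen_replay_train",
    "gen_localizer",
    "plant_reactivations",
    "plant_hf_bursts",
    "resample_path",
    "simulate_subject",
    "simulate_dataset",
]


def _check_stochastic(transition: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    transition = np.asarray(transition, dtype=float)
    if transition.ndim != 2 or transition.shape[0] != transition.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(transition < -tol):
        raise ValueError("transition matrix has negative entries")
    row_sums = transition.sum(axis=1)
    bad = np.flatnonzero(np.abs(row_sums - 1.0) > tol)
    if bad.size:
        raise ValueError(
            f"transition matrix row {bad[0]} sums to {row_sums[bad[0]]:.12f}, expected 1"
        )
    return transition


def gen_state_path(
    K: int,
    transition: np.ndarray,
    T: int,
    seed: int | np.random.Generator,
    start: int | None = None,
) -> np.ndarray:
    """Sample a length-``T`` Markov chain over states ``0..K-1``."""
    if K < 2:
        raise ValueError("need K >= 2 states")
    transition = _check_stochastic(transition)
    if transition.shape[0] != K:
        raise ValueError(f"transition matrix is {transition.shape[0]}x, expected {K}x")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(transition, axis=1)
    path = np.empty(T, dtype=int)
    if start is None:
        # start from the stationary distribution (power iteration)
        pi = np.full(K, 1.0 / K)
        for _ in range(200):
            pi = pi @ transition
        start = int(np.searchsorted(np.cumsum(pi), rng.random()))
    path[0] = start
    u = rng.random(T - 1)
    for t in range(1, T):
        path[t] = np.searchsorted(cum[path[t - 1]], u[t - 1], side="right")
    np.clip(path, 0, K - 1, out=path)
    return path


@dataclass
class StateComponent:
    """One oscillatory component active while its state is on."""

    freq: float
    channels: tuple[int, ...]
    amplitude: float = 1.0
    shared_phase: bool = False


def gen_state_signals(
    state_path: np.ndarray,
    fs: float,
    spec: dict[int, list[StateComponent]],
    noise_sd: float,
    seed: int | np.random.Generator,
    n_channels: int | None = None,
) -> RecordingSession:
    """Render a multichannel recording from a state path and per-state components.

    Shared-phase channels are copies of one randomly phased oscillator, so
    they are coherent at the component frequency; otherwise each channel
    gets an independent phase.
    """
    state_path = np.asarray(state_path, dtype=int)
    T = state_path.size
    rng = np.random.default_rng(seed)
    if n_channels is None:
        n_channels = 1 + max(
            (max(c.channels) for comps in spec.values() for c in comps), default=0
        )
    for comps in spec.values():
        for c in comps:
            if c.freq >= fs / 2:
                raise ValueError(f"component frequency {c.freq} Hz >= Nyquist ({fs / 2} Hz)")
    t = np.arange(T) / fs
    data = np.zeros((n_channels, T))
    for k, comps in spec.items():
        mask = state_path == k
        if not np.any(mask):
            continue
        for c in comps:
            if c.shared_phase:
                phase = rng.uniform(0, 2 * np.pi)
                wave = c.amplitude * np.sin(2 * np.pi * c.freq * t + phase)
                for ch in c.channels:
                    data[ch, mask] += wave[mask]
            else:
                for ch in c.channels:
                    phase = rng.uniform(0, 2 * np.pi)
                    data[ch, mask] += c.amplitude * np.sin(2 * np.pi * c.freq * t[mask] + phase)
    if noise_sd > 0:
        data += noise_sd * rng.standard_normal(data.shape)
    return RecordingSession(data=data, fs=fs)


def gen_replay_train(
    state_path: np.ndarray,
    fs: float,
    coupled_states: set[int] | frozenset[int],
    rate_in: float,
    rate_out: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Sample event sample-indices from a Markov-modulated Poisson process.

    Intensity is ``rate_in`` (Hz) while the path is in a coupled state and
    ``rate_out`` elsewhere.  Implemented by thinning a homogeneous process
    at the maximum rate, so equal rates give an exactly homogeneous train.
    """
    if rate_out < 0 or rate_in < rate_out:
        raise ValueError("need rate_in >= rate_out >= 0")
    state_path = np.asarray(state_path, dtype=int)
    coupled = frozenset(int(s) for s in coupled_states)
    if not coupled and rate_out == 0:
        warnings.warn("empty coupled_states with rate_out=0: returning empty event train")
        return np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    T = state_path.size
    duration = T / fs
    rate_max = max(rate_in, rate_out)
    if rate_max == 0:
        return np.array([], dtype=int)
    n = rng.poisson(rate_max * duration)
    times = np.sort(rng.uniform(0, duration, size=n))
    samples = np.minimum((times * fs).astype(int), T - 1)
    in_state = np.isin(state_path[samples], list(coupled))
    rate_at = np.where(in_state, rate_in, rate_out)
    keep = rng.random(samples.size) < rate_at / rate_max
    events = np.unique(samples[keep])
    return events


def gen_localizer(
    S: int,
    n_trials: int,
    P: int,
    fs: float,
    peri_ms: float,
    peak_ms: float,
    snr: float,
    seed: int | np.random.Generator,
    envelope_sd_ms: float = 40.0,
) -> tuple[LocalizerTrials, np.ndarray]:
    """Generate localizer trials plus the S x P planted spatial patterns.

    Each stimulus has a fixed random spatial pattern whose amplitude
    follows a Gaussian temporal envelope peaking at ``peak_ms``; unit-SD
    white noise is added everywhere, scaled relative to ``snr``.
    """
    if S < 2:
        raise ValueError("need at least 2 stimuli")
    if not 0 <= peak_ms <= peri_ms:
        raise ValueError(f"peak_ms={peak_ms} outside peri-stimulus window [0, {peri_ms}] ms")
    if n_trials < 2 * S:
        raise ValueError(f"n_trials={n_trials} < 2*S={2 * S}: cross-validation impossible")
    rng = np.random.default_rng(seed)
    patterns = rng.standard_normal((S, P))
    n_samp = int(round(peri_ms / 1000.0 * fs)) + 1
    times_ms = np.arange(n_samp) / fs * 1000.0
    envelope = np.exp(-0.5 * ((times_ms - peak_ms) / envelope_sd_ms) ** 2)
    labels = np.tile(np.arange(S), n_trials // S + 1)[:n_trials]
    labels = labels[rng.permutation(n_trials)]
    trials = np.zeros((n_trials, P, n_samp))
    amp = 1.0 if np.isinf(snr) else snr
    noise_sd = 0.0 if np.isinf(snr) else 1.0
    for i in range(n_trials):
        trials[i] = amp * patterns[labels[i]][:, None] * envelope[None, :]
    if noise_sd > 0:
        trials += noise_sd * rng.standard_normal(trials.shape)
    return LocalizerTrials(trials=trials, labels=labels, fs=fs, t0_offset=0.0), patterns


def lag_to_samples(lag_ms: float, fs: float, exact: bool = True) -> int:
    """Convert a lag in ms to samples: ``round(lag_ms * fs / 1000)``.

    With ``exact`` the conversion must land on an integer sample (the
    contract for planted/detected lags); scan grids may round.
    """
    lag = lag_ms * fs / 1000.0
    if exact and abs(lag - round(lag)) > 1e-6:
        raise ValueError(f"lag {lag_ms} ms is not an integer number of samples at fs={fs} Hz")
    return max(int(round(lag)), 1)


DEFAULT_REACTIVATION_KERNEL = np.array([0.5, 1.0, 0.5])


def _add_patterns(
    data: np.ndarray,
    patterns: np.ndarray,
    times: np.ndarray,
    items: np.ndarray,
    gain: float,
    kernel: np.ndarray,
) -> None:
    """Add ``gain * kernel * patterns[item]`` around each time, in place."""
    k_peak = int(np.argmax(kernel))
    T = data.shape[1]
    for t0, item in zip(times, items):
        for kk, kv in enumerate(kernel):
            t = int(t0) + kk - k_peak
            if 0 <= t < T:
                data[:, t] += gain * kv * patterns[item]


def plant_reactivations(
    session: RecordingSession,
    patterns: np.ndarray,
    replay_train: np.ndarray,
    lag_ms: float,
    sequence: list[tuple[int, int]],
    gain: float,
    kernel: np.ndarray | None = None,
) -> RecordingSession:
    """Add pairwise sequential pattern reinstatements at the given event times.

    At event time t the pattern of item i is added at t and of its ordered
    successor j at t + lag, each spread over a short temporal ``kernel``
    (default 3-sample raised bump, peak at the event sample); pairs are cycled
    deterministically over events.  Events too close to the recording end
    to fit the lag are dropped.
    """
    out = session.copy()
    if gain == 0 or len(replay_train) == 0:
        return out
    lag = lag_to_samples(lag_ms, session.fs)
    patterns = np.asarray(patterns, dtype=float)
    kernel = DEFAULT_REACTIVATION_KERNEL if kernel is None else np.asarray(kernel, dtype=float)
    n_dropped = 0
    for idx, e in enumerate(np.asarray(replay_train, dtype=int)):
        if e + lag >= session.n_samples:
            n_dropped += 1
            continue
        i, j = sequence[idx % len(sequence)]
        _add_patterns(
            out.data, patterns, np.array([e, e + lag]), np.array([i, j]), gain, kernel
        )
    if n_dropped:
        logger.info("plant_reactivations: dropped %d events too close to recording end", n_dropped)
    return out


def plant_sequences(
    session: RecordingSession,
    patterns: np.ndarray,
    replay_train: np.ndarray,
    lag_ms: float,
    sequences: tuple[tuple[int, ...], ...],
    gain: float,
    kernel: np.ndarray | None = None,
) -> RecordingSession:
    """Plant complete ordered chains: at event t the full sequence is
    reinstated at t, t+lag, t+2*lag, ...; chains alternate over events."""
    out = session.copy()
    if gain == 0 or len(replay_train) == 0:
        return out
    lag = lag_to_samples(lag_ms, session.fs)
    patterns = np.asarray(patterns, dtype=float)
    kernel = DEFAULT_REACTIVATION_KERNEL if kernel is None else np.asarray(kernel, dtype=float)
    n_dropped = 0
    for idx, e in enumerate(np.asarray(replay_train, dtype=int)):
        chain = sequences[idx % len(sequences)]
        if e + lag * (len(chain) - 1) >= session.n_samples:
            n_dropped += 1
            continue
        times = e + lag * np.arange(len(chain))
        _add_patterns(out.data, patterns, times, np.asarray(chain), gain, kernel)
    if n_dropped:
        logger.info("plant_sequences: dropped %d events too close to recording end", n_dropped)
    return out


def plant_hf_bursts(
    wideband_session: RecordingSession,
    state_path: np.ndarray,
    hf_state: int,
    band: tuple[float, float],
    burst_sd: float,
    seed: int | np.random.Generator,
    channels: tuple[int, ...] | None = None,
    lowpass_cutoff: float = 160.0,
) -> RecordingSession:
    """Add band-limited noise bursts on selected channels during ``hf_state``.

    ``lowpass_cutoff`` models the acquisition low-pass of the wideband
    data; the burst band must sit strictly below both it and Nyquist.
    """
    fs = wideband_session.fs
    lo, hi = band
    if hi >= min(fs / 2, lowpass_cutoff):
        raise ValueError(
            f"band upper edge {hi} Hz >= min(Nyquist {fs / 2} Hz, low-pass {lowpass_cutoff} Hz)"
        )
    if lo < 45.0:
        warnings.warn(
            f"burst band lower edge {lo} Hz overlaps the 1-45 Hz analysis band; "
            "this will contaminate state estimation"
        )
    state_path = np.asarray(state_path, dtype=int)
    if state_path.size != wideband_session.n_samples:
        raise ValueError("state_path length must match wideband session samples")
    out = wideband_session.copy()
    if burst_sd == 0:
        return out
    rng = np.random.default_rng(seed)
    if channels is None:
        channels = tuple(range(wideband_session.n_channels))
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    mask = (state_path == hf_state).astype(float)
    for ch in channels:
        noise = sps.sosfiltfilt(sos, rng.standard_normal(state_path.size))
        noise /= noise.std()
        out.data[ch] += burst_sd * noise * mask
    return out


def resample_path(path: np.ndarray, fs_from: float, fs_to: float, T_to: int) -> np.ndarray:
    """Nearest-sample resampling of an integer state path to another rate."""
    idx = np.minimum((np.arange(T_to) * fs_from / fs_to).astype(int), len(path) - 1)
    return np.asarray(path)[idx]


@dataclass
class SimConfig:
    """Defaults for the full multi-subject fixture."""

    n_subjects: int = 21
    duration_s: float = 300.0
    fs: float = 250.0
    fs_hi: float = 600.0
    n_channels: int = 12
    K: int = 4
    stay_prob: float = 0.999  # mean dwell ~4 s at 250 Hz
    state_freqs: tuple[float, ...] = (4.0, 10.0, 22.0, 35.0)
    osc_amplitude: float = 1.2
    noise_sd: float = 1.0
    coupled_states: tuple[int, ...] = (0,)
    rate_in: float = 1.5
    rate_out: float = 0.2
    hf_state: int | None = 0  # same state as replay coupling, as in the emulated effect
    hf_band: tuple[float, float] = (102.0, 148.0)
    hf_burst_sd: float = 2.0
    hf_channels: tuple[int, ...] = (0, 1, 2, 3)
    n_stimuli: int = 8
    n_trials: int = 160
    peri_ms: float = 400.0
    peak_ms: float = 200.0
    snr: float = 1.5
    replay_lag_ms: float = 40.0
    gain: float = 3.0
    sequences: tuple[tuple[int, ...], ...] = ((0, 1, 2, 3), (4, 5, 6, 7))
    base_seed: int = 0

    def transition(self) -> np.ndarray:
        off = (1.0 - self.stay_prob) / (self.K - 1)
        tm = np.full((self.K, self.K), off)
        np.fill_diagonal(tm, self.stay_prob)
        return tm

    def state_spec(self) -> dict[int, list[StateComponent]]:
        """One coherent oscillation per state on a contiguous channel group."""
        spec: dict[int, list[StateComponent]] = {}
        per = max(1, self.n_channels // self.K)
        for k in range(self.K):
            chans = tuple(range(k * per, min((k + 1) * per, self.n_channels)))
            freq = self.state_freqs[k % len(self.state_freqs)]
            spec[k] = [
                StateComponent(
                    freq=freq, channels=chans, amplitude=self.osc_amplitude, shared_phase=True
                )
            ]
        return spec

    def ordered_pairs(self) -> list[tuple[int, int]]:
        pairs = []
        for chain in self.sequences:
            pairs.extend(zip(chain[:-1], chain[1:]))
        return pairs


def simulate_subject(cfg: SimConfig, seed: int) -> SubjectFixture:
    """Build the complete fixture for one virtual subject."""
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(8)
    T = int(round(cfg.duration_s * cfg.fs))
    path = gen_state_path(cfg.K, cfg.transition(), T, np.random.default_rng(seeds[0]))
    session = gen_state_signals(
        path, cfg.fs, cfg.state_spec(), cfg.noise_sd,
        np.random.default_rng(seeds[1]), n_channels=cfg.n_channels,
    )
    localizer, patterns = gen_localizer(
        cfg.n_stimuli, cfg.n_trials, cfg.n_channels, cfg.fs, cfg.peri_ms, cfg.peak_ms,
        cfg.snr, np.random.default_rng(seeds[2]),
    )
    events = gen_replay_train(
        path, cfg.fs, set(cfg.coupled_states), cfg.rate_in, cfg.rate_out,
        np.random.default_rng(seeds[3]),
    )
    lag = lag_to_samples(cfg.replay_lag_ms, cfg.fs)
    max_chain = max(len(c) for c in cfg.sequences)
    events = events[events + lag * (max_chain - 1) < T]
    session = plant_sequences(
        session, patterns, events, cfg.replay_lag_ms, cfg.sequences, cfg.gain
    )
    wideband = None
    if cfg.fs_hi:
        T_hi = int(round(cfg.duration_s * cfg.fs_hi))
        path_hi = resample_path(path, cfg.fs, cfg.fs_hi, T_hi)
        wideband = gen_state_signals(
            path_hi, cfg.fs_hi, cfg.state_spec(), cfg.noise_sd,
            np.random.default_rng(seeds[4]), n_channels=cfg.n_channels,
        )
        if cfg.hf_state is not None:
            wideband = plant_hf_bursts(
                wideband, path_hi, cfg.hf_state, cfg.hf_band, cfg.hf_burst_sd,
                np.random.default_rng(seeds[5]), channels=cfg.hf_channels,
            )
    truth = GroundTruth(
        state_path=path,
        replay_times=events,
        replay_lag_ms=cfg.replay_lag_ms,
        coupled_states=frozenset(cfg.coupled_states),
        hf_state=cfg.hf_state,
    )
    return SubjectFixture(
        session=session, localizer=localizer, truth=truth, wideband=wideband,
        patterns=patterns, sequences=cfg.sequences,
    )


def simulate_dataset(cfg: SimConfig) -> list[SubjectFixture]:
    """Per-subject seeds are ``base_seed + subject_index``."""
    return [simulate_subject(cfg, cfg.base_seed + i) for i in range(cfg.n_subjects)]
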