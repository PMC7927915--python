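"""State-conditioned multitaper spectra, NNMF frequency modes,
evoked time-frequency reconstruction and high-frequency analyses.

State-conditioned estimates use hard segment assignment: maximal runs of
one state are cut into complete non-overlapping taper windows, and
cross-spectra are averaged over all windows of that state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import dpss
from sklearn.decomposition import NMF
from sklearn.mixture import GaussianMixture

from .io import RecordingSession

logger = logging.getLogger(__name__)

__all__ = [
    "StateSpectra",
    "SpectralModes",
    "state_multitaper",
    "nnmf_modes",
    "evoked_timefreq",
    "gmm_threshold",
    "hf_state_psd",
    "hf_replay_psd",
]


@dataclass
class StateSpectra:
    psd: np.ndarray  # K x P x F
    coherence: np.ndarray  # K x P x P x F
    freqs: np.ndarray
    params: dict
    n_windows: np.ndarray = field(default=None)  # windows per state

    def __post_init__(self) -> None:
        finite = np.isfinite(self.psd)
        if np.any(self.psd[finite] < 0):
            raise ValueError("psd must be nonnegative")

    @property
    def K(self) -> int:
        return self.psd.shape[0]


def _tapers(n_w: int, n_tapers: int) -> np.ndarray:
    """Unit-energy Slepian tapers with NW = (n_tapers + 1) / 2."""
    nw = (n_tapers + 1) / 2.0
    h = dpss(n_w, nw, Kmax=n_tapers)
    return h / np.sqrt(np.sum(h**2, axis=1, keepdims=True))


def _cross_spectra_windows(
    data: np.ndarray, starts: np.ndarray, n_w: int, tapers: np.ndarray, fs: float
) -> tuple[np.ndarray, int]:
    """Sum of one-sided multitaper cross-spectra over windows.

    Returns (P x P x F accumulator, window count).  Scaled so that the
    band-integrated psd approximates signal variance (Parseval).
    """
    P = data.shape[0]
    F = n_w // 2 + 1
    acc = np.zeros((P, P, F), dtype=complex)
    scale = np.full(F, 2.0 / fs)
    scale[0] = 1.0 / fs
    if n_w % 2 == 0:
        scale[-1] = 1.0 / fs
    for s in starts:
        seg = data[:, s : s + n_w]
        seg = seg - seg.mean(axis=1, keepdims=True)
        Y = np.fft.rfft(tapers[:, None, :] * seg[None, :, :], axis=-1)
        acc += np.einsum("kpf,kqf->pqf", Y, np.conj(Y)) / tapers.shape[0] * scale
    return acc, len(starts)


def _state_window_starts(path: np.ndarray, k: int, n_w: int) -> np.ndarray:
    """Starts of complete non-overlapping windows inside runs of state k."""
    mask = path == k
    padded = np.concatenate([[False], mask, [False]])
    run_starts = np.flatnonzero(~padded[:-1] & padded[1:])
    run_stops = np.flatnonzero(padded[:-1] & ~padded[1:])
    starts = []
    for rs, re in zip(run_starts, run_stops):
        n_full = (re - rs) // n_w
        starts.extend(rs + n_w * np.arange(n_full))
    return np.asarray(starts, dtype=int)


def state_multitaper(
    session: RecordingSession,
    state_path: np.ndarray,
    K: int | None = None,
    window_s: float = 2.0,
    n_tapers: int = 7,
    resolution_hz: float = 0.5,
    band: tuple[float, float] = (1.0, 45.0),
) -> StateSpectra:
    """State-conditioned multitaper power and coherence.

    ``state_path`` is a hard per-sample assignment over the full recording
    (-1 = unassigned); bad samples are treated as unassigned.
    """
    fs = session.fs
    if not 0 < band[0] < band[1] < fs / 2:
        raise ValueError(f"band {band} outside (0, {fs / 2}) Hz")
    state_path = np.asarray(state_path, dtype=int).copy()
    if state_path.size != session.n_samples:
        raise ValueError(
            f"state path length {state_path.size} != {session.n_samples} samples"
        )
    state_path[session.bad_mask] = -1
    if K is None:
        K = int(state_path.max()) + 1
    n_w = int(round(window_s * fs))
    if abs(fs / n_w - resolution_hz) > 1e-9:
        logger.info(
            "frequency grid spacing %.3f Hz (window %.2f s) differs from requested %.3f Hz",
            fs / n_w, window_s, resolution_hz,
        )
    tapers = _tapers(n_w, n_tapers)
    freqs = np.fft.rfftfreq(n_w, 1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    P = session.n_channels
    F = int(sel.sum())
    psd = np.full((K, P, F), np.nan)
    coh = np.full((K, P, P, F), np.nan)
    n_windows = np.zeros(K, dtype=int)
    for k in range(K):
        starts = _state_window_starts(state_path, k, n_w)
        if len(starts) == 0:
            logger.warning("state %d has no complete %.1f s windows; spectra NaN", k, window_s)
            continue
        acc, n = _cross_spectra_windows(session.data, starts, n_w, tapers, fs)
        S = acc[:, :, sel] / n
        n_windows[k] = n
        psd[k] = np.real(np.einsum("ppf->pf", S))
        auto = np.real(np.einsum("ppf->pf", S))
        denom = auto[:, None, :] * auto[None, :, :]
        coh[k] = np.abs(S) ** 2 / np.maximum(denom, 1e-300)
        np.clip(coh[k], 0.0, 1.0, out=coh[k])
    params = {
        "window_s": window_s,
        "n_tapers": n_tapers,
        "nw": (n_tapers + 1) / 2.0,
        "resolution_hz": fs / n_w,
        "band": band,
    }
    return StateSpectra(psd=psd, coherence=coh, freqs=freqs[sel], params=params, n_windows=n_windows)


@dataclass
class SpectralModes:
    mode_weights: np.ndarray  # n_modes x F, nonnegative
    psd_maps: np.ndarray  # n_modes x K x P
    coh_maps: np.ndarray  # n_modes x K x P x P
    freqs: np.ndarray
    reconstruction_error: float = np.nan

    def centroids(self) -> np.ndarray:
        w = self.mode_weights
        return (w * self.freqs[None, :]).sum(axis=1) / np.maximum(w.sum(axis=1), 1e-300)


def nnmf_modes(
    spectra: StateSpectra, n_modes: int, n_restarts: int = 10, seed: int = 0
) -> SpectralModes:
    """Nonnegative factorization of the stacked (state, channel[-pair]) x
    frequency spectral matrix into spatial loadings x spectral modes.

    Best of ``n_restarts`` random initializations by reconstruction error;
    modes are returned sorted by spectral centroid, ascending.
    """
    if n_modes < 1:
        raise ValueError("need n_modes >= 1")
    K, P, F = spectra.psd.shape
    iu = np.triu_indices(P, k=1)
    psd_rows = spectra.psd.reshape(K * P, F)
    coh_rows = spectra.coherence[:, iu[0], iu[1], :].reshape(K * len(iu[0]), F)
    mat = np.vstack([psd_rows, coh_rows])
    row_ok = np.isfinite(mat).all(axis=1)
    X = mat[row_ok]
    if X.shape[0] == 0:
        raise ValueError("no state has finite spectra; cannot factorize")
    if np.any(X < 0):
        raise ValueError("spectral matrix has negative entries")
    best = None
    for r in range(n_restarts):
        nmf = NMF(
            n_components=n_modes, init="random", random_state=seed + r,
            max_iter=1000, tol=1e-6,
        )
        W = nmf.fit_transform(X)
        if best is None or nmf.reconstruction_err_ < best[2]:
            best = (W, nmf.components_, nmf.reconstruction_err_)
    W, H, err = best
    centroids = (H * spectra.freqs[None, :]).sum(axis=1) / np.maximum(H.sum(axis=1), 1e-300)
    order = np.argsort(centroids)
    W, H = W[:, order], H[order]
    W_full = np.full((mat.shape[0], n_modes), np.nan)
    W_full[row_ok] = W
    psd_maps = W_full[: K * P].T.reshape(n_modes, K, P)
    coh_flat = W_full[K * P :].T.reshape(n_modes, K, len(iu[0]))
    coh_maps = np.full((n_modes, K, P, P), np.nan)
    coh_maps[:, :, iu[0], iu[1]] = coh_flat
    coh_maps[:, :, iu[1], iu[0]] = coh_flat
    return SpectralModes(
        mode_weights=H, psd_maps=psd_maps, coh_maps=coh_maps,
        freqs=spectra.freqs, reconstruction_error=float(err),
    )


@dataclass
class EvokedTimeFrequency:
    psd: np.ndarray  # lags x F, subject mean
    coherence: np.ndarray  # lags x F
    psd_baselined: np.ndarray  # time-mean removed per subject before averaging
    coherence_baselined: np.ndarray
    freqs: np.ndarray


def evoked_timefreq(evoked_values: np.ndarray, spectra: StateSpectra) -> EvokedTimeFrequency:
    """Weight per-state spectra by the (non-baselined) evoked state
    distribution: TF(lag, f) = sum_k B[k, lag, n] * spec_k(f), per subject
    then averaged."""
    B = np.asarray(evoked_values, dtype=float)  # K x L x N
    if B.ndim != 3 or B.shape[0] != spectra.K:
        raise ValueError("evoked values must be K x lags x subjects matching the spectra")
    colsums = B.sum(axis=0)
    if np.any(np.abs(colsums - 1.0) > 1e-3):
        raise ValueError(
            "evoked state weights do not sum to 1 over states; "
            "was a baseline-corrected response passed by mistake?"
        )
    state_psd = np.nanmean(spectra.psd, axis=1)  # K x F (channel mean)
    P = spectra.psd.shape[1]
    iu = np.triu_indices(P, k=1)
    state_coh = np.nanmean(spectra.coherence[:, iu[0], iu[1], :], axis=1)  # K x F
    tf_psd = np.einsum("kln,kf->lfn", B, state_psd)
    tf_coh = np.einsum("kln,kf->lfn", B, state_coh)
    psd_b = tf_psd - tf_psd.mean(axis=0, keepdims=True)
    coh_b = tf_coh - tf_coh.mean(axis=0, keepdims=True)
    return EvokedTimeFrequency(
        psd=tf_psd.mean(axis=2),
        coherence=tf_coh.mean(axis=2),
        psd_baselined=psd_b.mean(axis=2),
        coherence_baselined=coh_b.mean(axis=2),
        freqs=spectra.freqs,
    )


def gmm_threshold(values: np.ndarray, seed: int = 0) -> np.ndarray:
    """Two-component 1-D Gaussian mixture threshold.

    Returns a mask selecting values assigned to the higher-mean component,
    but only when the component means are separated by more than one
    pooled standard deviation; otherwise the mask is empty.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 20:
        raise ValueError(f"need at least 20 values for the mixture threshold, got {values.size}")
    if np.allclose(values, values[0]):
        warnings.warn("constant input to gmm_threshold; empty mask")
        return np.zeros(values.size, dtype=bool)
    gm1 = GaussianMixture(n_components=1, random_state=seed)
    gm1.fit(values[:, None])
    gm = GaussianMixture(n_components=2, random_state=seed, n_init=3)
    gm.fit(values[:, None])
    if gm1.bic(values[:, None]) <= gm.bic(values[:, None]):
        return np.zeros(values.size, dtype=bool)  # no distinct second mixture
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    hi = int(np.argmax(means))
    pooled_sd = np.sqrt(np.mean(sds**2))
    if abs(means[hi] - means[1 - hi]) <= pooled_sd:
        return np.zeros(values.size, dtype=bool)
    post = gm.predict_proba(values[:, None])[:, hi]
    return post > 0.5


def hf_state_psd(
    wideband: RecordingSession,
    state_path_hi: np.ndarray,
    K: int | None = None,
    band: tuple[float, float] = (1.0, 160.0),
    window_s: float = 2.0,
    n_tapers: int = 7,
) -> StateSpectra:
    """State-conditioned multitaper psd of wideband data over the full band.

    ``state_path_hi`` must be the low-band state path resampled to the
    wideband clock (same sample count as ``wideband``).
    """
    if len(state_path_hi) != wideband.n_samples:
        raise ValueError(
            f"resampled state path has {len(state_path_hi)} samples, "
            f"wideband session has {wideband.n_samples}"
        )
    if band[1] >= wideband.fs / 2:
        raise ValueError(f"band upper edge {band[1]} Hz >= Nyquist {wideband.fs / 2} Hz")
    return state_multitaper(
        wideband, state_path_hi, K=K, window_s=window_s, n_tapers=n_tapers,
        resolution_hz=wideband.fs / int(round(window_s * wideband.fs)), band=band,
    )


@dataclass
class HfReplayPsd:
    evoked: np.ndarray  # subjects x F, channel-mean psd in event windows
    baseline: np.ndarray  # subjects x F, subject-shuffled event times
    freqs: np.ndarray
    params: dict


def _event_window_psd(
    session: RecordingSession, events: np.ndarray, n_w: int, tapers: np.ndarray
) -> np.ndarray | None:
    half = n_w // 2
    good = ~session.bad_mask
    starts = []
    for e in events:
        s = int(e) - half
        if s < 0 or s + n_w > session.n_samples:
            continue
        if good[s : s + n_w].all():
            starts.append(s)
    if not starts:
        return None
    acc, n = _cross_spectra_windows(session.data, np.asarray(starts), n_w, tapers, session.fs)
    psd = np.real(np.einsum("ppf->pf", acc)) / n
    return psd.mean(axis=0)  # channel mean


def hf_replay_psd(
    sessions: list[RecordingSession],
    event_trains: list[np.ndarray],
    window_ms: float = 30.0,
    n_baseline_shuffles: int = 10,
    seed: int = 0,
    n_tapers: int = 7,
) -> HfReplayPsd:
    """Multitaper psd over short windows centered on replay events, with a
    baseline from event times shuffled over subjects (preserving each
    subject's event count)."""
    fs = sessions[0].fs
    n_w = int(round(window_ms / 1000.0 * fs))
    if n_w < 4:
        raise ValueError(f"window of {window_ms} ms is only {n_w} samples at {fs} Hz")
    n_tapers = min(n_tapers, n_w - 1)
    tapers = _tapers(n_w, n_tapers)
    freqs = np.fft.rfftfreq(n_w, 1.0 / fs)
    N = len(sessions)
    evoked = np.full((N, freqs.size), np.nan)
    for n, (sess, ev) in enumerate(zip(sessions, event_trains)):
        p = _event_window_psd(sess, ev, n_w, tapers)
        if p is None:
            raise ValueError(f"subject {n}: all event windows overlap bad samples or edges")
        evoked[n] = p
    rng = np.random.default_rng(seed)
    baseline_acc = np.zeros((N, freqs.size))
    counts = np.zeros(N)
    for _ in range(n_baseline_shuffles):
        perm = rng.permutation(N)
        while N > 1 and np.any(perm == np.arange(N)):
            perm = rng.permutation(N)
        for n in range(N):
            donor = event_trains[perm[n]]
            donor = donor[donor < sessions[n].n_samples]
            p = _event_window_psd(sessions[n], donor, n_w, tapers)
            if p is not None:
                baseline_acc[n] += p
                counts[n] += 1
    baseline = baseline_acc / np.maximum(counts[:, None], 1)
    half_bw = (n_tapers + 1) / 2.0 / (n_w / fs)
    params = {
        "window_ms": window_ms,
        "n_window_samples": n_w,
        "n_tapers": n_tapers,
        "frequency_resolution_hz": fs / n_w,
        "half_bandwidth_hz": half_bw,
        "n_baseline_shuffles": n_baseline_shuffles,
    }
    return HfReplayPsd(evoked=evoked, baseline=baseline, freqs=freqs, params=params)
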