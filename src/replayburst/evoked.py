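"""Event-evoked state-probability statistics.

Epochs of the posterior state time course are taken around event onsets,
baseline-corrected by each subject's session mean, and tested at the
group level with sign-flip cluster permutation statistics.
"""

from __future__ import annotations

import logging
from dataclasses import InitVar, dataclass

import numpy as np
from scipy import stats

from .replay import threshold_events

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectEvoked",
    "EvokedResponse",
    "ClusterResult",
    "epoch_states",
    "group_evoked",
    "cluster_permutation",
    "replication_cluster_test",
    "compare_conditions",
    "threshold_sweep",
]


@dataclass
class SubjectEvoked:
    values: np.ndarray  # K x lags
    lags_s: np.ndarray
    baseline_corrected: bool
    n_epochs: int


@dataclass
class EvokedResponse:
    """Group evoked state distribution: K states x lags x subjects."""

    values: np.ndarray
    lags_s: np.ndarray
    baseline_corrected: bool
    validate: InitVar[bool] = True  # False for non-probability traces (reactivations)

    def __post_init__(self, validate: bool) -> None:
        if not validate:
            return
        colsums = self.values.sum(axis=0)
        target = 0.0 if self.baseline_corrected else 1.0
        if np.any(np.abs(colsums - target) > 1e-6):
            raise ValueError(
                f"evoked columns must sum to {target} over states "
                f"(max deviation {np.max(np.abs(colsums - target)):.2e})"
            )

    @classmethod
    def stack(cls, subjects: list[SubjectEvoked], validate: bool = True) -> "EvokedResponse":
        if len(subjects) < 2:
            raise ValueError("need at least 2 subjects")
        ref = subjects[0]
        for s in subjects[1:]:
            if s.values.shape != ref.values.shape or s.baseline_corrected != ref.baseline_corrected:
                raise ValueError("subject evoked responses have mismatched shapes or baselines")
        return cls(
            values=np.stack([s.values for s in subjects], axis=2),
            lags_s=ref.lags_s,
            baseline_corrected=ref.baseline_corrected,
            validate=validate,
        )


def epoch_states(
    gamma_full: np.ndarray,
    events: np.ndarray,
    fs: float,
    window_s: float = 0.5,
    baseline: bool = True,
    bad_mask: np.ndarray | None = None,
) -> SubjectEvoked:
    """Average state probabilities in a +/- ``window_s`` window around events.

    The baseline is the per-state average over all (valid, good) samples of
    the session; epochs crossing recording edges, bad samples or
    undefined (NaN) posteriors are dropped entirely.
    """
    gamma_full = np.asarray(gamma_full, dtype=float)
    K, T = gamma_full.shape
    if bad_mask is None:
        bad_mask = np.zeros(T, dtype=bool)
    w = int(round(window_s * fs))
    ok_sample = np.isfinite(gamma_full).all(axis=0) & ~bad_mask
    epochs = []
    for e in np.asarray(events, dtype=int):
        s0, s1 = e - w, e + w + 1
        if s0 < 0 or s1 > T or not ok_sample[s0:s1].all():
            continue
        epochs.append(gamma_full[:, s0:s1])
    if not epochs:
        raise ValueError("zero retained epochs for this subject")
    evoked = np.mean(epochs, axis=0)
    if baseline:
        session_mean = gamma_full[:, ok_sample].mean(axis=1)
        evoked = evoked - session_mean[:, None]
    lags = (np.arange(-w, w + 1)) / fs
    return SubjectEvoked(
        values=evoked, lags_s=lags, baseline_corrected=baseline, n_epochs=len(epochs)
    )


def group_evoked(response: EvokedResponse | list[SubjectEvoked]) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise mean and SEM over subjects."""
    if isinstance(response, list):
        response = EvokedResponse.stack(response)
    v = response.values
    n = v.shape[2]
    return v.mean(axis=2), v.std(axis=2, ddof=1) / np.sqrt(n)


def _t_per_lag(x: np.ndarray) -> np.ndarray:
    """One-sample t across subjects; x is subjects x lags."""
    n = x.shape[0]
    m = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    return m / np.maximum(sd / np.sqrt(n), 1e-300)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) half-open runs of True."""
    padded = np.concatenate([[False], mask, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    stops = np.flatnonzero(padded[:-1] & ~padded[1:])
    return list(zip(starts, stops))


def _max_run_lengths(masks: np.ndarray) -> np.ndarray:
    """Max run length of True per row."""
    n_rows, L = masks.shape
    out = np.zeros(n_rows, dtype=int)
    padded = np.zeros((n_rows, L + 2), dtype=bool)
    padded[:, 1:-1] = masks
    d = np.diff(padded.astype(np.int8), axis=1)
    for r in range(n_rows):
        starts = np.flatnonzero(d[r] == 1)
        stops = np.flatnonzero(d[r] == -1)
        if starts.size:
            out[r] = int(np.max(stops - starts))
    return out


@dataclass
class Cluster:
    state: int
    start_idx: int
    stop_idx: int  # exclusive
    lag_start_s: float
    lag_end_s: float
    mass: int  # run length in lags
    p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    t_threshold: float
    n_permutations: int


def cluster_permutation(
    response: EvokedResponse,
    t_threshold: float = 3.0,
    n_perm: int = 5000,
    seed: int = 0,
) -> ClusterResult:
    """Sign-flip cluster permutation test, one-sided, per state.

    Observed clusters are maximal runs of lags with group t above the
    threshold; cluster mass is the run length; the null is the maximum
    cluster length under random per-subject sign flips.
    """
    v = response.values  # K x L x N
    K, L, N = v.shape
    if N < 5:
        raise ValueError(f"need at least 5 subjects, got {N}")
    rng = np.random.default_rng(seed)
    clusters: list[Cluster] = []
    for k in range(K):
        x = v[k].T  # N x L
        t_obs = _t_per_lag(x)
        obs_runs = [(s, e) for s, e in _runs(t_obs > t_threshold)]
        if not obs_runs:
            continue
        signs = rng.choice([-1.0, 1.0], size=(n_perm, N))
        mean_p = signs @ x / N
        ssq = (x**2).sum(axis=0)
        var_p = np.maximum(ssq[None, :] - N * mean_p**2, 0.0) / (N - 1)
        t_p = mean_p / np.maximum(np.sqrt(var_p / N), 1e-300)
        null_max = _max_run_lengths(t_p > t_threshold)
        for s, e in obs_runs:
            mass = e - s
            p = (np.sum(null_max >= mass) + 1.0) / (n_perm + 1.0)
            clusters.append(
                Cluster(
                    state=k, start_idx=int(s), stop_idx=int(e),
                    lag_start_s=float(response.lags_s[s]),
                    lag_end_s=float(response.lags_s[e - 1]),
                    mass=int(mass), p=float(p),
                )
            )
    return ClusterResult(clusters=clusters, t_threshold=t_threshold, n_permutations=n_perm)


def replication_cluster_test(
    result_a: ClusterResult,
    response_b: EvokedResponse,
    n_perm: int = 5000,
    seed: int = 0,
) -> list[float]:
    """Inflexible replication: for each dataset-A cluster, the threshold is
    the minimum dataset-B t-statistic inside the A window, and the p-value
    is the permutation probability of an equal-or-larger cluster anywhere
    in B at that threshold."""
    v = response_b.values
    K, L, N = v.shape
    rng = np.random.default_rng(seed)
    pvals: list[float] = []
    for cl in result_a.clusters:
        if cl.stop_idx > L or cl.start_idx >= L:
            raise ValueError("dataset-A cluster window does not fit dataset-B lag grid")
        x = v[cl.state].T  # N x L
        t_b = _t_per_lag(x)
        thresh = float(t_b[cl.start_idx : cl.stop_idx].min())
        signs = rng.choice([-1.0, 1.0], size=(n_perm, N))
        mean_p = signs @ x / N
        ssq = (x**2).sum(axis=0)
        var_p = np.maximum(ssq[None, :] - N * mean_p**2, 0.0) / (N - 1)
        t_p = mean_p / np.maximum(np.sqrt(var_p / N), 1e-300)
        null_max = _max_run_lengths(t_p >= thresh)
        p = (np.sum(null_max >= cl.mass) + 1.0) / (n_perm + 1.0)
        pvals.append(float(p))
    return pvals


def compare_conditions(
    values_a: np.ndarray, values_b: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-state paired two-sided t test between two conditions.

    ``values_*`` are K x N (one value per state per subject, e.g. the
    evoked distribution at lag 0).  Returns (t, p, bonferroni flags at
    alpha / K).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"condition shapes differ: {a.shape} vs {b.shape}")
    K, N = a.shape
    ts = np.zeros(K)
    ps = np.ones(K)
    for k in range(K):
        d = a[k] - b[k]
        if np.allclose(d, 0):
            ts[k], ps[k] = 0.0, 1.0
        else:
            ts[k], ps[k] = stats.ttest_rel(a[k], b[k])
    return ts, ps, ps < alpha / K


def threshold_sweep(
    traces: list[np.ndarray],
    gammas_full: list[np.ndarray],
    fs: float,
    percentiles: np.ndarray | None = None,
    window_s: float = 0.5,
    bad_masks: list[np.ndarray] | None = None,
    lag_samples: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Replay-evoked lag-0 values while sweeping the event threshold.

    Returns (values [K x percentiles] averaged over subjects, percentiles,
    asymmetry = value at the top percentile minus value at the bottom).
    Genuine replay coupling loads the high tail; variance artifacts are
    symmetric about the median.
    """
    if percentiles is None:
        percentiles = np.arange(1, 100)
    percentiles = np.asarray(percentiles, dtype=float)
    n_sub = len(traces)
    if bad_masks is None:
        bad_masks = [None] * n_sub
    K = gammas_full[0].shape[0]
    out = np.full((K, percentiles.size), np.nan)
    for pi, pct in enumerate(percentiles):
        subj_vals = []
        for trace, gamma, bad in zip(traces, gammas_full, bad_masks):
            # adjacency-only merging: at low percentiles lag-based merging
            # collapses the near-continuous suprathreshold trace to one run
            train = threshold_events(
                trace, fs, percentile=pct, merge_within_samples=1,
                bad_mask=bad, lag_samples=lag_samples,
            )
            if train.event_onsets.size == 0:
                continue
            try:
                ev = epoch_states(gamma, train.event_onsets, fs, window_s, True, bad)
            except ValueError:
                continue
            lag0 = ev.values.shape[1] // 2
            subj_vals.append(ev.values[:, lag0])
        if subj_vals:
            out[:, pi] = np.mean(subj_vals, axis=0)
    asymmetry = out[:, -1] - out[:, 0]
    return out, percentiles, asymmetry
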