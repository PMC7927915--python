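"""Fano-factor burstiness statistics for event trains.

The Fano factor F_W is the variance-to-mean ratio of event counts in
non-overlapping windows of length W: 1 for a homogeneous Poisson
process, above 1 for bursty (overdispersed) trains.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "FanoCurve",
    "ConditionedIntervals",
    "default_window_grid",
    "fano_curve",
    "group_fano",
    "interval_shuffle_test",
    "state_visit_fano",
    "conditioned_intervals",
]


def default_window_grid(n: int = 30, lo: float = 0.1, hi: float = 30.0) -> np.ndarray:
    """Log-spaced window lengths in seconds."""
    return np.geomspace(lo, hi, n)


@dataclass
class FanoCurve:
    window_lengths: np.ndarray  # seconds
    fano: np.ndarray  # subjects x windows (or 1 x windows)
    counts_used: np.ndarray  # windows retained, same shape as fano

    def __post_init__(self) -> None:
        finite = np.isfinite(self.fano)
        if np.any(self.fano[finite] < 0):
            raise ValueError("Fano factors must be nonnegative")


def _window_counts(
    events: np.ndarray, T: int, fs: float, window_s: float, bad_mask: np.ndarray | None
) -> np.ndarray:
    """Event counts in complete non-overlapping windows anchored at sample 0;
    windows containing bad samples are dropped."""
    w = int(round(window_s * fs))
    if w < 1:
        raise ValueError(f"window {window_s} s shorter than one sample")
    n_win = T // w
    if n_win == 0:
        return np.array([])
    idx = np.asarray(events, dtype=int) // w
    idx = idx[idx < n_win]
    counts = np.bincount(idx, minlength=n_win).astype(float)
    if bad_mask is not None and bad_mask.any():
        bad_win = np.bincount(
            np.flatnonzero(bad_mask[: n_win * w]) // w, minlength=n_win
        ) > 0
        counts = counts[~bad_win]
    return counts


def fano_curve(
    events: np.ndarray,
    T: int,
    fs: float,
    bad_mask: np.ndarray | None = None,
    window_grid: np.ndarray | None = None,
) -> FanoCurve:
    """Fano factor versus window length for one subject's event train.

    Intervals between consecutive events that overlap bad samples are
    excluded by dropping any window containing bad samples; NaN is
    reported where fewer than 2 windows survive.
    """
    if window_grid is None:
        window_grid = default_window_grid()
    window_grid = np.asarray(window_grid, dtype=float)
    if np.any(window_grid <= 0) or np.any(window_grid > T / fs):
        raise ValueError("window grid must lie in (0, T/fs]")
    fano = np.full(window_grid.size, np.nan)
    used = np.zeros(window_grid.size, dtype=int)
    for i, w in enumerate(window_grid):
        counts = _window_counts(events, T, fs, w, bad_mask)
        used[i] = counts.size
        if counts.size < 2:
            continue
        mu = counts.mean()
        if mu == 0:
            continue
        fano[i] = counts.var(ddof=1) / mu
    return FanoCurve(window_lengths=window_grid, fano=fano[None, :], counts_used=used[None, :])


def group_fano(curves: list[FanoCurve]) -> np.ndarray:
    """Mean over subjects of the per-subject Fano factors (NaN-aware)."""
    stacked = np.vstack([c.fano for c in curves])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(stacked, axis=0)


def shuffle_intervals(events: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Surrogate train with the same interval multiset in permuted order;
    the first event time is preserved."""
    events = np.asarray(events)
    iv = np.diff(events)
    return events[0] + np.concatenate([[0], np.cumsum(rng.permutation(iv))])


@dataclass
class IntervalShuffleResult:
    window_lengths: np.ndarray
    observed: np.ndarray  # group Fano per window
    threshold: np.ndarray  # max surrogate group Fano per window
    reject: np.ndarray  # observed > threshold
    n_permutations: int
    p_bound: float  # p < 1/n_perm where rejected


def interval_shuffle_test(
    event_trains: list[np.ndarray],
    T: int,
    fs: float,
    n_perm: int = 1000,
    window_grid: np.ndarray | None = None,
    seed: int = 0,
    bad_masks: list[np.ndarray] | None = None,
) -> IntervalShuffleResult:
    """Test the IID-interval null by interval shuffling.

    Surrogate trains permute each subject's inter-event intervals (the
    first event time is preserved), which keeps the interval multiset
    exact while destroying dependence between consecutive intervals.  The
    threshold is the maximum surrogate group Fano per window length.
    """
    if window_grid is None:
        window_grid = default_window_grid()
    window_grid = np.asarray(window_grid, dtype=float)
    if n_perm < 2:
        warnings.warn(f"n_perm={n_perm}: interval-shuffle test is near-powerless")
    for ev in event_trains:
        if len(ev) < 3:
            raise ValueError("need at least 3 events per subject for interval shuffling")
    if bad_masks is None:
        bad_masks = [None] * len(event_trains)
    rng = np.random.default_rng(seed)
    observed = group_fano(
        [fano_curve(ev, T, fs, bm, window_grid) for ev, bm in zip(event_trains, bad_masks)]
    )
    thresh = np.full(window_grid.size, -np.inf)
    for _ in range(n_perm):
        curves = []
        for ev, bm in zip(event_trains, bad_masks):
            curves.append(fano_curve(shuffle_intervals(ev, rng), T, fs, bm, window_grid))
        thresh = np.fmax(thresh, group_fano(curves))
    reject = observed > thresh
    return IntervalShuffleResult(
        window_lengths=window_grid, observed=observed, threshold=thresh,
        reject=reject, n_permutations=n_perm, p_bound=1.0 / n_perm,
    )


@dataclass
class StateVisitFanoResult:
    window_lengths: np.ndarray
    fano: np.ndarray  # K x subjects x windows
    anova_p: np.ndarray  # per window
    anova_p_bonferroni: np.ndarray
    anova_max_p: float  # highest p over windows (reporting convention)
    state_t: np.ndarray  # K, per-state two-sample t vs pooled others (max-p window)
    state_p: np.ndarray  # K, max p over windows per state


def state_visit_fano(
    visit_onsets: list[list[np.ndarray]],
    T: int,
    fs: float,
    window_grid: np.ndarray | None = None,
    bad_masks: list[np.ndarray] | None = None,
    min_visits: int = 3,
) -> StateVisitFanoResult:
    """Fano curves of state-visit onset trains, compared across states.

    ``visit_onsets[n][k]`` is subject n's onset train for state k.  Cells
    with fewer than ``min_visits`` visits are excluded.  A one-way ANOVA
    across states is run per window (Bonferroni over windows) and each
    state's subject Fanos are t-tested against the pooled remaining
    states; the maximum p over windows is reported per the convention of
    quoting only the least significant window.
    """
    if window_grid is None:
        window_grid = default_window_grid()
    window_grid = np.asarray(window_grid, dtype=float)
    n_sub = len(visit_onsets)
    K = len(visit_onsets[0])
    if bad_masks is None:
        bad_masks = [None] * n_sub
    fano = np.full((K, n_sub, window_grid.size), np.nan)
    for n in range(n_sub):
        for k in range(K):
            ev = visit_onsets[n][k]
            if len(ev) < min_visits:
                continue
            fano[k, n] = fano_curve(ev, T, fs, bad_masks[n], window_grid).fano[0]
    n_w = window_grid.size
    anova_p = np.full(n_w, np.nan)
    for wi in range(n_w):
        groups = [fano[k, :, wi][np.isfinite(fano[k, :, wi])] for k in range(K)]
        groups = [g for g in groups if g.size >= 2]
        if len(groups) < 2:
            continue
        anova_p[wi] = stats.f_oneway(*groups).pvalue
    bonf = np.minimum(anova_p * n_w, 1.0)
    state_t = np.full(K, np.nan)
    state_p = np.full(K, np.nan)
    for k in range(K):
        t_per_w, p_per_w = [], []
        for wi in range(n_w):
            own = fano[k, :, wi][np.isfinite(fano[k, :, wi])]
            rest = np.concatenate(
                [fano[j, :, wi][np.isfinite(fano[j, :, wi])] for j in range(K) if j != k]
            )
            if own.size < 2 or rest.size < 2:
                continue
            res = stats.ttest_ind(own, rest)
            t_per_w.append(res.statistic)
            p_per_w.append(res.pvalue)
        if p_per_w:
            worst = int(np.argmax(p_per_w))
            state_t[k] = t_per_w[worst]
            state_p[k] = p_per_w[worst]
    finite_p = anova_p[np.isfinite(anova_p)]
    return StateVisitFanoResult(
        window_lengths=window_grid, fano=fano, anova_p=anova_p, anova_p_bonferroni=bonf,
        anova_max_p=float(finite_p.max()) if finite_p.size else np.nan,
        state_t=state_t, state_p=state_p,
    )


@dataclass
class ConditionedIntervals:
    mean_interval: np.ndarray  # subjects x K, seconds; NaN where excluded
    n_obs: np.ndarray  # subjects x K
    excluded: np.ndarray  # subjects x K bool (fewer than min_obs)
    anova_p: float
    state_t: np.ndarray  # K
    state_p: np.ndarray  # K


def conditioned_intervals(
    event_trains: list[np.ndarray],
    gammas_full: list[np.ndarray],
    fs: float,
    bad_masks: list[np.ndarray] | None = None,
    min_obs: int = 10,
) -> ConditionedIntervals:
    """Mean inter-event interval conditioned on the most likely active
    state at each event.

    Intervals whose span overlaps bad samples are omitted; per-subject
    per-state means from fewer than ``min_obs`` observations are dropped.
    Subject means are compared across states with a one-way ANOVA and
    each state against all others combined with a two-sample t test.
    """
    n_sub = len(event_trains)
    K = gammas_full[0].shape[0]
    if K < 2:
        raise ValueError("conditioned-interval ANOVA undefined for a single state")
    if bad_masks is None:
        bad_masks = [None] * n_sub
    mean_interval = np.full((n_sub, K), np.nan)
    n_obs = np.zeros((n_sub, K), dtype=int)
    for n, (ev, gamma) in enumerate(zip(event_trains, gammas_full)):
        bad = bad_masks[n]
        acc: list[list[float]] = [[] for _ in range(K)]
        for i in range(len(ev) - 1):
            e0, e1 = int(ev[i]), int(ev[i + 1])
            if bad is not None and bad[e0 : e1 + 1].any():
                continue
            g = gamma[:, e0]
            if not np.all(np.isfinite(g)):
                continue
            acc[int(np.argmax(g))].append((e1 - e0) / fs)
        for k in range(K):
            n_obs[n, k] = len(acc[k])
            if len(acc[k]) >= min_obs:
                mean_interval[n, k] = float(np.mean(acc[k]))
    excluded = (n_obs < min_obs)
    groups = [mean_interval[:, k][np.isfinite(mean_interval[:, k])] for k in range(K)]
    groups_ok = [g for g in groups if g.size >= 2]
    if len(groups_ok) < 2:
        raise ValueError("all per-state cells excluded; cannot compare states")
    anova_p = float(stats.f_oneway(*groups_ok).pvalue)
    state_t = np.full(K, np.nan)
    state_p = np.full(K, np.nan)
    for k in range(K):
        own = groups[k]
        rest = np.concatenate([groups[j] for j in range(K) if j != k])
        if own.size >= 2 and rest.size >= 2:
            res = stats.ttest_ind(own, rest)
            state_t[k], state_p[k] = res.statistic, res.pvalue
    return ConditionedIntervals(
        mean_interval=mean_interval, n_obs=n_obs, excluded=excluded,
        anova_p=anova_p, state_t=state_t, state_p=state_p,
    )
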