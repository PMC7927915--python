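"""Replay detection: sparse stimulus decoders, lagged sequence evidence,
the combined replay probability trace and its thresholding into events.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .io import LocalizerTrials, RecordingSession
from .synthetic import lag_to_samples

logger = logging.getLogger(__name__)

_PROB_EPS = 1e-12

__all__ = [
    "ClassifierSet",
    "ReactivationProbabilities",
    "ReplayEventTrain",
    "train_classifiers",
    "pick_training_time",
    "apply_classifiers",
    "sequence_evidence",
    "replay_probability",
    "threshold_events",
    "events_to_frame",
]


@dataclass
class ClassifierSet:
    """One-vs-rest sparse logistic decoders, one per stimulus."""

    weights: np.ndarray  # S x P
    intercepts: np.ndarray  # S
    training_time_ms: float
    l1_penalty: float
    degenerate: np.ndarray = field(default=None)  # bool per stimulus: all-zero weights

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite classifier weights")
        if self.degenerate is None:
            self.degenerate = ~np.any(self.weights != 0, axis=1)

    @property
    def n_stimuli(self) -> int:
        return self.weights.shape[0]

    @property
    def n_channels(self) -> int:
        return self.weights.shape[1]


@dataclass
class ReactivationProbabilities:
    """Per-stimulus sigmoid decoder outputs over a recording."""

    probs: np.ndarray  # S x T, strictly inside (0, 1)
    fs: float
    bad_mask: np.ndarray | None = None
    stimulus_names: list[str] | None = None

    def __post_init__(self) -> None:
        if np.any(self.probs <= 0) or np.any(self.probs >= 1):
            raise ValueError("probabilities must lie strictly inside (0, 1)")
        if self.bad_mask is None:
            self.bad_mask = np.zeros(self.probs.shape[1], dtype=bool)


@dataclass
class ReplayEventTrain:
    """Thresholded replay probability trace and its event onsets."""

    trace: np.ndarray
    threshold: float
    event_onsets: np.ndarray
    lag_samples: int
    percentile: float
    fs: float = 250.0

    def __post_init__(self) -> None:
        if self.event_onsets.size and np.any(np.diff(self.event_onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")


def _fit_single(x: np.ndarray, y: np.ndarray, l1_penalty: float) -> tuple[np.ndarray, float]:
    if np.isinf(l1_penalty):
        return np.zeros(x.shape[1]), 0.0
    clf = LogisticRegression(
        l1_ratio=1.0, C=1.0 / l1_penalty, solver="liblinear", max_iter=2000
    )
    clf.fit(x, y)
    return clf.coef_[0], float(clf.intercept_[0])


def train_classifiers(
    localizer: LocalizerTrials, time_ms: float, l1_penalty: float = 1.0
) -> ClassifierSet:
    """Train one L1-regularised one-vs-rest logistic decoder per stimulus
    on the single peri-stimulus sample at ``time_ms``."""
    if len(np.unique(localizer.labels)) < 2:
        raise ValueError("localizer labels contain a single class")
    idx = localizer.sample_at(time_ms)
    x = localizer.trials[:, :, idx]
    s = localizer.n_stimuli
    weights = np.zeros((s, x.shape[1]))
    intercepts = np.zeros(s)
    for i in range(s):
        weights[i], intercepts[i] = _fit_single(x, (localizer.labels == i).astype(int), l1_penalty)
    cs = ClassifierSet(weights, intercepts, training_time_ms=time_ms, l1_penalty=l1_penalty)
    if np.any(cs.degenerate):
        warnings.warn(
            f"degenerate classifiers (all-zero weights) for stimuli "
            f"{np.flatnonzero(cs.degenerate).tolist()} at penalty {l1_penalty}"
        )
    return cs


def _argmax_earliest(values: np.ndarray) -> int:
    """First index attaining the maximum (earliest-time tie-break)."""
    return int(np.argmax(values))


@dataclass
class TrainingTimeResult:
    time_ms: float
    accuracies: np.ndarray  # mean CV accuracy per peri-stimulus sample
    times_ms: np.ndarray
    low_confidence: bool


def pick_training_time(
    localizer: LocalizerTrials,
    l1_penalty: float = 1.0,
    n_folds: int = 5,
    seed: int = 0,
) -> TrainingTimeResult:
    """Cross-validated accuracy per peri-stimulus sample; returns the time
    with the highest mean accuracy (ties broken earliest)."""
    if n_folds < 2:
        raise ValueError("need n_folds >= 2")
    times = localizer.times_ms
    labels = localizer.labels
    s = localizer.n_stimuli
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(labels)), labels))
    accs = np.zeros(len(times))
    for ti in range(len(times)):
        x_all = localizer.trials[:, :, ti]
        fold_accs = []
        for train_idx, test_idx in splits:
            scores = np.zeros((len(test_idx), s))
            for i in range(s):
                w, b = _fit_single(
                    x_all[train_idx], (labels[train_idx] == i).astype(int), l1_penalty
                )
                scores[:, i] = x_all[test_idx] @ w + b
            fold_accs.append(np.mean(np.argmax(scores, axis=1) == labels[test_idx]))
        accs[ti] = np.mean(fold_accs)
    best = _argmax_earliest(accs)
    chance = 1.0 / s
    low_confidence = accs[best] < chance + 2.0 * np.sqrt(chance * (1 - chance) / localizer.n_trials)
    if low_confidence:
        logger.warning(
            "pick_training_time: best CV accuracy %.3f is near chance %.3f", accs[best], chance
        )
    return TrainingTimeResult(
        time_ms=float(times[best]), accuracies=accs, times_ms=times, low_confidence=low_confidence
    )


def apply_classifiers(
    session: RecordingSession, classifiers: ClassifierSet
) -> ReactivationProbabilities:
    """probs[i, t] = sigmoid(X_t . beta_i + intercept_i)."""
    if session.n_channels != classifiers.n_channels:
        raise ValueError(
            f"channel mismatch: session has {session.n_channels}, "
            f"classifiers expect {classifiers.n_channels}"
        )
    z = classifiers.weights @ session.data + classifiers.intercepts[:, None]
    probs = 1.0 / (1.0 + np.exp(-z))
    np.clip(probs, _PROB_EPS, 1.0 - _PROB_EPS, out=probs)
    return ReactivationProbabilities(probs=probs, fs=session.fs, bad_mask=session.bad_mask.copy())


def _lagged_corr(a: np.ndarray, b: np.ndarray, lag: int, good: np.ndarray) -> float:
    """Pearson correlation of a[t] with b[t+lag], bad samples excluded pairwise."""
    x = a[:-lag] if lag > 0 else a
    y = b[lag:] if lag > 0 else b
    m = good[: len(x)] & good[lag : lag + len(x)]
    x, y = x[m], y[m]
    if x.size < 3 or x.std() == 0 or y.std() == 0:
        logger.info("degenerate trace in lagged correlation; returning 0")
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def sequence_evidence(
    probs: ReactivationProbabilities,
    ordered_pairs: list[tuple[int, int]],
    lags_ms: np.ndarray,
) -> pd.Series:
    """Task-minus-control mean lagged correlation per lag.

    Evidence at lag tau = mean correlation of probs[i, t] with probs[j, t+tau]
    over task-ordered pairs (i -> j), minus the same mean over all other
    ordered pairs of distinct stimuli.
    """
    s = probs.probs.shape[0]
    task = set((int(i), int(j)) for i, j in ordered_pairs)
    for i, j in task:
        if not (0 <= i < s and 0 <= j < s):
            raise ValueError(f"pair ({i},{j}) references invalid stimulus (S={s})")
    control = [(i, j) for i in range(s) for j in range(s) if i != j and (i, j) not in task]
    good = ~probs.bad_mask
    lags_ms = np.asarray(lags_ms, dtype=float)
    out = np.zeros(len(lags_ms))
    for li, lag_ms in enumerate(lags_ms):
        lag = lag_to_samples(lag_ms, probs.fs, exact=False)
        task_mean = np.mean([_lagged_corr(probs.probs[i], probs.probs[j], lag, good) for i, j in task])
        ctrl_mean = np.mean(
            [_lagged_corr(probs.probs[i], probs.probs[j], lag, good) for i, j in control]
        )
        out[li] = task_mean - ctrl_mean
    return pd.Series(out, index=pd.Index(lags_ms, name="lag_ms"), name="evidence")


def replay_probability(
    probs: ReactivationProbabilities,
    sequences: tuple[tuple[int, ...], ...],
    tau: int,
    mode: str = "product",
) -> np.ndarray:
    """Combined replay trace R_t over all consecutive within-chain pairs.

    Pair joints use the product rule (or min under ``mode='minmax'``) and
    the union is a noisy-OR (or max).  The last ``tau`` samples cannot be
    evaluated and are set to NaN.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1 sample")
    flat = [s for chain in sequences for s in chain]
    if len(set(flat)) != len(flat):
        raise ValueError("sequence chains must reference distinct stimuli")
    p = probs.probs
    T = p.shape[1]
    pairs = [(c[k], c[k + 1]) for c in sequences for k in range(len(c) - 1)]
    joints = np.empty((len(pairs), T - tau))
    for pi, (i, j) in enumerate(pairs):
        if mode == "product":
            joints[pi] = p[i, : T - tau] * p[j, tau:]
        elif mode == "minmax":
            joints[pi] = np.minimum(p[i, : T - tau], p[j, tau:])
        else:
            raise ValueError(f"unknown mode {mode!r}")
    trace = np.full(T, np.nan)
    if mode == "product":
        trace[: T - tau] = 1.0 - np.prod(1.0 - joints, axis=0)
    else:
        trace[: T - tau] = joints.max(axis=0)
    return trace


def threshold_events(
    trace: np.ndarray,
    fs: float,
    percentile: float = 99.0,
    merge_within_samples: int | None = None,
    bad_mask: np.ndarray | None = None,
    lag_samples: int = 10,
) -> ReplayEventTrain:
    """Threshold R_t at a percentile of its valid samples; events are the
    onsets of suprathreshold runs, with runs closer than
    ``merge_within_samples`` (default: the lag) merged."""
    if not 0 <= percentile < 100:
        raise ValueError("percentile must be in [0, 100)")
    trace = np.asarray(trace, dtype=float)
    T = trace.size
    if bad_mask is None:
        bad_mask = np.zeros(T, dtype=bool)
    if merge_within_samples is None:
        merge_within_samples = lag_samples
    valid = np.isfinite(trace) & ~bad_mask
    if not np.any(valid):
        raise ValueError("no valid samples in trace")
    vals = trace[valid]
    threshold = float(np.percentile(vals, percentile))
    if np.all(vals == vals[0]):
        warnings.warn("constant replay trace: no events detected")
        return ReplayEventTrain(trace, threshold, np.array([], dtype=int), lag_samples, percentile, fs)
    above = valid & (trace >= threshold)
    # run starts/ends
    padded = np.concatenate([[False], above, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])  # exclusive
    onsets: list[int] = []
    last_end = -(10 ** 9)
    for s0, e0 in zip(starts, ends):
        if s0 - last_end < merge_within_samples and onsets:
            last_end = e0
            continue
        onsets.append(int(s0))
        last_end = e0
    return ReplayEventTrain(
        trace=trace,
        threshold=threshold,
        event_onsets=np.asarray(onsets, dtype=int),
        lag_samples=lag_samples,
        percentile=percentile,
        fs=fs,
    )


def events_to_frame(train: ReplayEventTrain, subject: int = 0) -> pd.DataFrame:
    """Tabulate events as subject / onset_sample / onset_sec / trace_value."""
    return pd.DataFrame(
        {
            "subject": subject,
            "onset_sample": train.event_onsets,
            "onset_sec": train.event_onsets / train.fs,
            "trace_value": train.trace[train.event_onsets],
        }
    )
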