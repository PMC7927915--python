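"""State ordering from transition-derived distances, and visit statistics."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StateDistance",
    "MdsOrdering",
    "VisitStatistics",
    "transition_distance",
    "mds_order",
    "visit_statistics",
]


@dataclass
class StateDistance:
    psi: np.ndarray  # off-diagonal-normalized transitions, zero diagonal
    dist: np.ndarray  # symmetric distances, zero diagonal

    def __post_init__(self) -> None:
        if not np.allclose(self.dist, self.dist.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.dist), 0):
            raise ValueError("distance diagonal must be 0")


def transition_distance(transition: np.ndarray) -> StateDistance:
    """Distances between states from the transition matrix.

    Self-transitions are removed by zeroing the diagonal and renormalizing
    rows (psi); the directed distance is 1 - psi, symmetrized by
    averaging, with the self-distance forced to zero.
    """
    theta = np.asarray(transition, dtype=float)
    K = theta.shape[0]
    diag = np.diag(theta)
    absorbing = np.flatnonzero(diag >= 1.0 - 1e-12)
    if absorbing.size:
        raise ValueError(
            f"state {absorbing[0]} is absorbing (self-transition 1); cannot normalize"
        )
    psi = theta.copy()
    np.fill_diagonal(psi, 0.0)
    psi /= psi.sum(axis=1, keepdims=True)
    d = 1.0 - psi
    np.fill_diagonal(d, 1.0)  # formula value; overwritten on the symmetric matrix
    dhat = 0.5 * (d + d.T)
    np.fill_diagonal(dhat, 0.0)
    return StateDistance(psi=psi, dist=dhat)


@dataclass
class MdsOrdering:
    order: np.ndarray  # order[rank] = original state index
    labels: np.ndarray  # labels[state] = 1-based ordinal label
    coords: np.ndarray  # first-axis MDS coordinate per state
    degenerate: bool = False


def mds_order(distance: StateDistance) -> MdsOrdering:
    """Classical MDS first axis; states are labeled 1..K along it.

    Sign is fixed so the largest-magnitude coordinate is positive; exact
    coordinate ties break by original state index.
    """
    d = distance.dist
    K = d.shape[0]
    if K < 2:
        raise ValueError("need K >= 2 states")
    offdiag = d[~np.eye(K, dtype=bool)]
    if np.allclose(offdiag, offdiag[0]):
        warnings.warn("all-equal distances: degenerate MDS axis, returning identity order")
        order = np.arange(K)
        labels = np.arange(1, K + 1)
        return MdsOrdering(order=order, labels=labels, coords=np.zeros(K), degenerate=True)
    J = np.eye(K) - np.ones((K, K)) / K
    B = -0.5 * J @ (d ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    coords = evecs[:, -1] * np.sqrt(max(evals[-1], 0.0))
    if coords[np.argmax(np.abs(coords))] < 0:
        coords = -coords
    order = np.lexsort((np.arange(K), coords))
    labels = np.empty(K, dtype=int)
    labels[order] = np.arange(1, K + 1)
    return MdsOrdering(order=order, labels=labels, coords=coords)


@dataclass
class VisitStatistics:
    """Per-state visit lifetimes, inter-onset intervals and onset trains."""

    lifetimes: list[np.ndarray]  # seconds, one array per state
    intervals: list[np.ndarray]  # seconds, one array per state
    onsets: list[np.ndarray]  # sample indices, one array per state
    occupancy: np.ndarray = field(default=None)
    fs: float = 1.0

    @property
    def K(self) -> int:
        return len(self.lifetimes)

    def mean_lifetimes(self) -> np.ndarray:
        return np.array([lt.mean() if lt.size else np.nan for lt in self.lifetimes])

    def mean_intervals(self) -> np.ndarray:
        return np.array([iv.mean() if iv.size else np.nan for iv in self.intervals])


def _good_segments(n: int, bad_mask: np.ndarray | None) -> list[tuple[int, int]]:
    if bad_mask is None:
        return [(0, n)]
    good = ~np.asarray(bad_mask, dtype=bool)
    padded = np.concatenate([[False], good, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    stops = np.flatnonzero(padded[:-1] & ~padded[1:])
    return list(zip(starts, stops))


def visit_statistics(
    path: np.ndarray,
    fs: float,
    bad_mask: np.ndarray | None = None,
    K: int | None = None,
    exclude_truncated: bool = False,
) -> VisitStatistics:
    """Lifetime / interval / onset statistics of a hard state path.

    A visit is a maximal run of one state inside a good segment; its
    lifetime is the run length over ``fs`` and intervals are the gaps
    between consecutive onsets of the same state within a segment.  With
    ``exclude_truncated`` visits cut short by segment edges are dropped
    from the lifetime lists (they always count as onsets).
    """
    path = np.asarray(path, dtype=int)
    if K is None:
        K = int(path[path >= 0].max()) + 1
    lifetimes: list[list[float]] = [[] for _ in range(K)]
    intervals: list[list[float]] = [[] for _ in range(K)]
    onsets: list[list[int]] = [[] for _ in range(K)]
    time_in = np.zeros(K)
    good_time = 0
    for s0, s1 in _good_segments(path.size, bad_mask):
        seg = path[s0:s1]
        ok = seg >= 0
        good_time += int(ok.sum())
        change = np.flatnonzero(np.diff(seg) != 0) + 1
        run_starts = np.concatenate([[0], change])
        run_stops = np.concatenate([change, [len(seg)]])
        seg_onsets: dict[int, list[int]] = {}
        for rs, re in zip(run_starts, run_stops):
            k = seg[rs]
            if k < 0:
                continue
            time_in[k] += re - rs
            truncated = rs == 0 or re == len(seg)
            if not (exclude_truncated and truncated):
                lifetimes[k].append((re - rs) / fs)
            onsets[k].append(s0 + rs)
            seg_onsets.setdefault(int(k), []).append(rs)
        for k, ons in seg_onsets.items():
            if len(ons) > 1:
                intervals[k].extend(np.diff(ons) / fs)
    for k in range(K):
        if not onsets[k]:
            logger.info("state %d never visited", k)
    occ = time_in / max(good_time, 1)
    return VisitStatistics(
        lifetimes=[np.array(x) for x in lifetimes],
        intervals=[np.array(x) for x in intervals],
        onsets=[np.array(x, dtype=int) for x in onsets],
        occupancy=occ,
        fs=fs,
    )
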