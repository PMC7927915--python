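"""Hidden Markov model on time-delay-embedded, PCA-reduced observations.

The observation model is a zero-mean full-covariance Gaussian per state
over the embedded space, so each state encodes channel auto- and
cross-spectral content through its covariance.  Inference is Baum-Welch
EM with multi-restart selection by final log-likelihood; bad samples
break the chain, so forward-backward runs independently per good
segment and transitions are never counted across gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import linalg as sla
from scipy.optimize import linear_sum_assignment

from .io import RecordingSession

logger = logging.getLogger(__name__)

__all__ = [
    "EmbeddingConfig",
    "HmmModel",
    "StateTimecourse",
    "embed",
    "pca_reduce",
    "prepare_observations",
    "fit",
    "decode",
    "dual_fit",
    "match_states",
    "state_match_accuracy",
]


@dataclass
class EmbeddingConfig:
    """Time-delay embedding: window ``W = 2l + 1`` samples, then PCA."""

    l: int = 7
    pca_components: int | None = None  # default: 2 * n_channels

    def __post_init__(self) -> None:
        if self.l < 1:
            raise ValueError("need l >= 1")

    @property
    def window(self) -> int:
        return 2 * self.l + 1


@dataclass
class HmmModel:
    K: int
    covariances: np.ndarray  # K x D x D
    transition: np.ndarray  # K x K
    initial: np.ndarray  # K
    embedding: EmbeddingConfig
    pca_basis: np.ndarray | None  # full-dim x D projection
    objective: float  # final training log-likelihood

    def __post_init__(self) -> None:
        for k, cov in enumerate(self.covariances):
            if not np.allclose(cov, cov.T, atol=1e-8):
                raise ValueError(f"covariance {k} is not symmetric")
        if np.any(np.abs(self.transition.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition rows must sum to 1")


@dataclass
class StateTimecourse:
    """Posterior state probabilities over the embeddable sample range.

    ``gamma`` is K x T_valid; column ``t`` corresponds to recording sample
    ``valid_range[0] + t``.  Columns at invalid (bad-overlapping) frames
    are NaN and the Viterbi path is -1 there.
    """

    gamma: np.ndarray
    viterbi: np.ndarray
    valid_range: tuple[int, int]  # first/last embeddable sample, inclusive

    def __post_init__(self) -> None:
        ok = np.isfinite(self.gamma).all(axis=0)
        sums = self.gamma[:, ok].sum(axis=0)
        if ok.any() and np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("gamma columns must sum to 1")

    @property
    def K(self) -> int:
        return self.gamma.shape[0]

    def gamma_full(self, T: int) -> np.ndarray:
        """K x T gamma aligned to recording samples, NaN outside the valid range."""
        out = np.full((self.K, T), np.nan)
        lo, hi = self.valid_range
        out[:, lo : hi + 1] = self.gamma
        return out

    def viterbi_full(self, T: int) -> np.ndarray:
        out = np.full(T, -1, dtype=int)
        lo, hi = self.valid_range
        out[lo : hi + 1] = self.viterbi
        return out


def embed(
    session: RecordingSession, l: int, center: bool = True
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Time-delay embed a session into a (P*W) x T_valid matrix.

    Column t stacks the window X[:, t-l : t+l+1] channel-major; frames
    whose window touches a bad sample are flagged invalid.  Returns
    (embedded, valid, valid_range).
    """
    if l < 1:
        raise ValueError("need l >= 1")
    P, T = session.data.shape
    W = 2 * l + 1
    if T <= W:
        raise ValueError(f"recording of {T} samples too short for embedding window {W}")
    # windows: P x (T - W + 1) x W, windows[p, t, w] = X[p, t + w]
    windows = sliding_window_view(session.data, W, axis=1)
    Tv = T - W + 1
    E = np.ascontiguousarray(windows.transpose(0, 2, 1).reshape(P * W, Tv)).astype(float)
    bad = sliding_window_view(session.bad_mask, W).any(axis=1)
    valid = ~bad
    if center:
        if valid.any():
            E -= E[:, valid].mean(axis=1, keepdims=True)
        else:
            E -= E.mean(axis=1, keepdims=True)
    return E, valid, (l, T - l - 1)


def pca_reduce(
    embedded: np.ndarray, n_components: int, valid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Project embedded frames onto the top principal components.

    Returns (reduced data, basis [D_full x n_components], explained
    variance fraction).
    """
    D, Tv = embedded.shape
    if valid is None:
        valid = np.ones(Tv, dtype=bool)
    X = embedded[:, valid]
    cov = (X @ X.T) / X.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    rank = int(np.sum(evals > max(evals[0], 0) * 1e-12))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds data rank {rank}")
    basis = evecs[:, :n_components]
    explained = float(evals[:n_components].sum() / evals.sum())
    return basis.T @ embedded, basis, explained


def prepare_observations(
    session: RecordingSession, config: EmbeddingConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple[int, int]]:
    """embed + pca_reduce with the config defaults; returns
    (reduced, valid, basis, valid_range)."""
    E, valid, vr = embed(session, config.l)
    n_comp = config.pca_components or 2 * session.n_channels
    reduced, basis, _ = pca_reduce(E, n_comp, valid)
    return reduced, valid, basis, vr


def _segments(valid: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of valid frames as (start, stop) half-open pairs."""
    padded = np.concatenate([[False], valid, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    stops = np.flatnonzero(padded[:-1] & ~padded[1:])
    return list(zip(starts, stops))


def _log_emissions(X: np.ndarray, covariances: np.ndarray) -> np.ndarray:
    """Zero-mean Gaussian log-densities; X is frames x D, returns frames x K."""
    Tf, D = X.shape
    K = covariances.shape[0]
    out = np.empty((Tf, K))
    for k in range(K):
        cho = sla.cho_factor(covariances[k], lower=True)
        logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
        sol = sla.cho_solve(cho, X.T)
        quad = np.einsum("dt,dt->t", X.T, sol)
        out[:, k] = -0.5 * (D * np.log(2 * np.pi) + logdet + quad)
    return out


def _forward_backward(
    logB: np.ndarray, A: np.ndarray, pi: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward-backward over one segment.

    Returns (gamma [T x K], xi_sum [K x K], log-likelihood).
    """
    T, K = logB.shape
    offs = logB.max(axis=1)
    B = np.exp(logB - offs[:, None])
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = pi * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    if T > 1:
        xi_sum = A * (alpha[:-1].T @ (B[1:] * beta[1:] / c[1:, None]))
    else:
        xi_sum = np.zeros((K, K))
    loglik = float(np.sum(np.log(c)) + offs.sum())
    return gamma, xi_sum, loglik


def _viterbi(logB: np.ndarray, A: np.ndarray, pi: np.ndarray) -> np.ndarray:
    T, K = logB.shape
    logA = np.log(np.maximum(A, 1e-300))
    delta = np.log(np.maximum(pi, 1e-300)) + logB[0]
    back = np.empty((T, K), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def _m_step_covariances(
    X: np.ndarray, gamma: np.ndarray, cond_limit: float = 1e10
) -> np.ndarray:
    K = gamma.shape[1]
    D = X.shape[1]
    covs = np.empty((K, D, D))
    for k in range(K):
        w = gamma[:, k]
        n = w.sum()
        cov = (X * w[:, None]).T @ X / max(n, 1e-12)
        cov = 0.5 * (cov + cov.T)
        if np.linalg.cond(cov) > cond_limit:
            reg = 1e-6 * np.trace(cov) / D
            cov += reg * np.eye(D)
            logger.warning("covariance %d near-singular; regularized with %.3g * I", k, reg)
        covs[k] = cov
    return covs


def _em(
    X_frames: np.ndarray,
    seg_bounds: list[tuple[int, int]],
    K: int,
    covariances: np.ndarray,
    A: np.ndarray,
    pi: np.ndarray,
    max_iter: int,
    tol: float,
    update_covariances: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[float]]:
    """Run EM on pre-extracted valid frames (concatenated segments).

    ``seg_bounds`` indexes into X_frames.  Returns (covs, A, pi, gamma,
    loglik history).
    """
    Tf = X_frames.shape[0]
    gamma = np.empty((Tf, K))
    history: list[float] = []
    prev = -np.inf
    for it in range(max_iter):
        logB = _log_emissions(X_frames, covariances)
        xi_total = np.zeros((K, K))
        pi_acc = np.zeros(K)
        loglik = 0.0
        for s0, s1 in seg_bounds:
            g, xi, ll = _forward_backward(logB[s0:s1], A, pi)
            gamma[s0:s1] = g
            xi_total += xi
            pi_acc += g[0]
            loglik += ll
        if history and loglik < history[-1] - 1e-8 * max(1.0, abs(history[-1])):
            logger.warning("EM log-likelihood decreased: %.6f -> %.6f", history[-1], loglik)
        history.append(loglik)
        # M-step
        if K > 1:
            rowsum = xi_total.sum(axis=1, keepdims=True)
            A = np.where(rowsum > 0, xi_total / np.maximum(rowsum, 1e-300), 1.0 / K)
            A /= A.sum(axis=1, keepdims=True)
            pi = pi_acc / pi_acc.sum()
        if update_covariances:
            covariances = _m_step_covariances(X_frames, gamma)
        if it > 0 and abs(loglik - prev) < tol * max(1.0, abs(prev)):
            break
        prev = loglik
    # final E-step so the returned posteriors match the returned parameters
    logB = _log_emissions(X_frames, covariances)
    for s0, s1 in seg_bounds:
        g, _, _ = _forward_backward(logB[s0:s1], A, pi)
        gamma[s0:s1] = g
    return covariances, A, pi, gamma, history


def fit(
    reduced: np.ndarray,
    valid: np.ndarray,
    K: int,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    embedding: EmbeddingConfig | None = None,
    pca_basis: np.ndarray | None = None,
    valid_range: tuple[int, int] | None = None,
) -> tuple[HmmModel, StateTimecourse]:
    """Multi-restart Baum-Welch; keeps the restart with the highest final
    log-likelihood.  ``reduced`` is D x T_valid."""
    X = np.asarray(reduced, dtype=float).T  # frames x D
    Tv = X.shape[0]
    valid = np.asarray(valid, dtype=bool)
    segs = _segments(valid)
    if not segs:
        raise ValueError("no valid frames to fit")
    frames = np.concatenate([np.arange(s0, s1) for s0, s1 in segs])
    Xf = X[frames]
    bounds = []
    pos = 0
    for s0, s1 in segs:
        bounds.append((pos, pos + (s1 - s0)))
        pos += s1 - s0
    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_restarts):
        resp = rng.dirichlet(np.ones(K), size=Xf.shape[0])
        covs = _m_step_covariances(Xf, resp)
        A = np.full((K, K), 1.0 / K) if K > 1 else np.ones((1, 1))
        if K > 1:
            A = A + 0.1 * rng.dirichlet(np.ones(K), size=K)
            A /= A.sum(axis=1, keepdims=True)
        pi = np.full(K, 1.0 / K)
        covs, A, pi, gamma_f, hist = _em(Xf, bounds, K, covs, A, pi, max_iter, tol)
        logger.info("restart %d: final log-likelihood %.2f after %d iters", r, hist[-1], len(hist))
        if best is None or hist[-1] > best[-1]:
            best = (covs, A, pi, gamma_f, hist[-1])
    covs, A, pi, gamma_f, objective = best
    model = HmmModel(
        K=K,
        covariances=covs,
        transition=A,
        initial=pi,
        embedding=embedding or EmbeddingConfig(),
        pca_basis=pca_basis,
        objective=float(objective),
    )
    stc = _build_timecourse(model, X, valid, segs, frames, gamma_f, valid_range)
    return model, stc


def _build_timecourse(
    model: HmmModel,
    X: np.ndarray,
    valid: np.ndarray,
    segs: list[tuple[int, int]],
    frames: np.ndarray,
    gamma_f: np.ndarray,
    valid_range: tuple[int, int] | None,
) -> StateTimecourse:
    Tv = X.shape[0]
    K = model.K
    gamma = np.full((K, Tv), np.nan)
    gamma[:, frames] = gamma_f.T
    viterbi = np.full(Tv, -1, dtype=int)
    logB_all = _log_emissions(X[frames], model.covariances)
    pos = 0
    for s0, s1 in segs:
        n = s1 - s0
        viterbi[s0:s1] = _viterbi(logB_all[pos : pos + n], model.transition, model.initial)
        pos += n
    vr = valid_range if valid_range is not None else (0, Tv - 1)
    return StateTimecourse(gamma=gamma, viterbi=viterbi, valid_range=vr)


def decode(
    model: HmmModel,
    reduced: np.ndarray,
    valid: np.ndarray | None = None,
    valid_range: tuple[int, int] | None = None,
) -> StateTimecourse:
    """Forward-backward posteriors and Viterbi path under a fixed model."""
    X = np.asarray(reduced, dtype=float).T
    D = model.covariances.shape[1]
    if X.shape[1] != D:
        raise ValueError(f"data dimension {X.shape[1]} does not match model dimension {D}")
    if valid is None:
        valid = np.ones(X.shape[0], dtype=bool)
    segs = _segments(np.asarray(valid, dtype=bool))
    frames = np.concatenate([np.arange(s0, s1) for s0, s1 in segs])
    logB = _log_emissions(X[frames], model.covariances)
    gamma_f = np.empty((len(frames), model.K))
    pos = 0
    for s0, s1 in segs:
        n = s1 - s0
        g, _, _ = _forward_backward(logB[pos : pos + n], model.transition, model.initial)
        gamma_f[pos : pos + n] = g
        pos += n
    return _build_timecourse(model, X, valid, segs, frames, gamma_f, valid_range)


def dual_fit(
    model: HmmModel,
    reduced: np.ndarray,
    valid: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    valid_range: tuple[int, int] | None = None,
) -> tuple[StateTimecourse, np.ndarray]:
    """Hold state covariances fixed; re-estimate the transition matrix and
    posteriors on new data by EM.  Returns (timecourse, new transition)."""
    X = np.asarray(reduced, dtype=float).T
    D = model.covariances.shape[1]
    if X.shape[1] != D:
        raise ValueError(f"data dimension {X.shape[1]} does not match model dimension {D}")
    if valid is None:
        valid = np.ones(X.shape[0], dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    segs = _segments(valid)
    frames = np.concatenate([np.arange(s0, s1) for s0, s1 in segs])
    Xf = X[frames]
    bounds = []
    pos = 0
    for s0, s1 in segs:
        bounds.append((pos, pos + (s1 - s0)))
        pos += s1 - s0
    _, A, pi, gamma_f, _ = _em(
        Xf, bounds, model.K, model.covariances, model.transition.copy(),
        model.initial.copy(), max_iter, tol, update_covariances=False,
    )
    refit = HmmModel(
        K=model.K, covariances=model.covariances, transition=A, initial=pi,
        embedding=model.embedding, pca_basis=model.pca_basis, objective=model.objective,
    )
    stc = _build_timecourse(refit, X, valid, segs, frames, gamma_f, valid_range)
    return stc, A


def match_states(cov_a: np.ndarray, cov_b: np.ndarray) -> np.ndarray:
    """Permutation p minimizing total Frobenius distance, cov_b[p[k]] ~ cov_a[k]."""
    K = cov_a.shape[0]
    cost = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            cost[i, j] = np.linalg.norm(cov_a[i] - cov_b[j])
    _, col = linear_sum_assignment(cost)
    return col


def state_match_accuracy(path_true: np.ndarray, path_est: np.ndarray, K: int) -> float:
    """Best-permutation agreement between two hard state paths (valid entries)."""
    ok = (path_true >= 0) & (path_est >= 0)
    a, b = path_true[ok], path_est[ok]
    conf = np.zeros((K, K))
    np.add.at(conf, (a, b), 1)
    row, col = linear_sum_assignment(-conf)
    return float(conf[row, col].sum() / max(ok.sum(), 1))
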