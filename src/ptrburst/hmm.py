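"""Univariate time-delay embedded hidden Markov models.

Each brain region gets its own K-state HMM (K = 3 by default) whose
observations are vectors of lagged copies of the region's signal inside a
sliding window (230 ms by default -> 23 lags at 100 Hz).  States are
zero-mean Gaussians distinguished purely by their lag-space covariance,
i.e. by their autocovariance and hence their spectral fingerprint.  One
state typically captures transient high-amplitude oscillatory bursts, the
mechanism behind post-task responses.

Inference is maximum-likelihood EM (Baum-Welch) with a scaled
forward-backward E-step, best of ``n_restarts`` random initialisations.
Posterior state probabilities thresholded at 2/3 give mutually exclusive
binary "on/off" timecourses, and maximal runs of "on" samples give state
lifetimes, interpreted as burst durations.

A brute-force log-likelihood (explicit summation over all K^T state paths)
is provided as an independent oracle for the forward algorithm on tiny
instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import logsumexp

from ._hmm_core import forward_backward, forward_loglik

__all__ = [
    "EmbeddingConfig",
    "Embedding",
    "TdeHmmModel",
    "PosteriorMatrix",
    "BinaryStateMatrix",
    "embed",
    "fit",
    "loglik",
    "loglik_bruteforce",
    "threshold",
    "lifetimes",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class EmbeddingConfig:
    """Time-delay embedding window.  ``n_lags`` is round(window*fs) forced odd
    so the lags are symmetric about zero."""

    window: float = 0.230
    fs: float = 100.0

    @property
    def n_lags(self) -> int:
        n = int(round(self.window * self.fs))
        if n % 2 == 0:
            n += 1
        if n < 3:
            raise ValueError("embedding window too short (need >= 3 lags)")
        return n


@dataclass
class Embedding:
    """Lag-embedded matrix (n_lags x T) plus the contiguous valid range.

    Row ``l`` holds the series shifted by lag ``l - (n_lags-1)/2``; the
    half-window of columns at each edge is zero-padded and excluded from
    likelihood computations via ``valid`` (a slice).
    """

    matrix: np.ndarray
    valid: slice
    cfg: EmbeddingConfig

    @property
    def n_lags(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def valid_points(self) -> np.ndarray:
        """Valid embedded vectors as (T_valid, n_lags) rows."""
        return self.matrix[:, self.valid].T.copy()


def embed(series: np.ndarray, cfg: EmbeddingConfig) -> Embedding:
    """Time-delay embed a 1-D series: X[l, t] = x[t + (l - half)]"""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("embed expects a 1-D series")
    n_lags = cfg.n_lags
    T = x.shape[0]
    if T <= n_lags:
        raise ValueError("series shorter than embedding window")
    half = (n_lags - 1) // 2
    X = np.zeros((n_lags, T))
    for ell in range(n_lags):
        lag = ell - half
        if lag >= 0:
            X[ell, : T - lag] = x[lag:]
        else:
            X[ell, -lag:] = x[:lag]
    return Embedding(matrix=X, valid=slice(half, T - half), cfg=cfg)


@dataclass
class TdeHmmModel:
    """Fitted model: K states, row-stochastic transitions, simplex initial
    distribution, and one lag-space covariance per (zero-mean) state."""

    K: int
    transition: np.ndarray
    initial: np.ndarray
    covariances: np.ndarray
    loglik_trajectory: list[float] = field(default_factory=list)
    window_s: float | None = None
    fs: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")


@dataclass
class PosteriorMatrix:
    """State posteriors gamma (K x T); columns sum to 1."""

    gamma: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.gamma < -1e-12) or np.any(self.gamma > 1 + 1e-12):
            raise ValueError("posteriors must lie in [0, 1]")


@dataclass
class BinaryStateMatrix:
    """Thresholded on/off timecourses (K x T, entries in {0,1})."""

    onoff: np.ndarray
    threshold: float = 2.0 / 3.0


def _state_logpdf(X: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """log N(x; 0, cov) for each row of X (T, d)."""
    d = cov.shape[0]
    jitter = 0.0
    for _ in range(6):
        try:
            L = linalg.cholesky(cov + jitter * np.eye(d), lower=True)
            break
        except linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10 * np.trace(cov) / d)
    else:
        raise np.linalg.LinAlgError("degenerate state covariance")
    y = linalg.solve_triangular(L, X.T, lower=True)
    quad = np.einsum("ij,ij->j", y, y)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return -0.5 * (d * _LOG2PI + logdet + quad)


def _log_b(X: np.ndarray, covariances: np.ndarray) -> np.ndarray:
    return np.stack([_state_logpdf(X, c) for c in covariances], axis=1)


def _scaled_fb(logB: np.ndarray, A: np.ndarray, pi: np.ndarray):
    shift = logB.max(axis=1)
    b = np.exp(logB - shift[:, None])
    gamma, xi, log_scale = forward_backward(b, A, pi)
    return gamma, xi, log_scale + shift.sum()


def _init_params(X: np.ndarray, K: int, rng: np.random.Generator, reg_scale: float):
    """Random contiguous-chunk partition of timepoints -> state covariances.

    Chunks (rather than single samples) are assigned to states so that the
    initial covariances reflect local signal structure (e.g. chunks that
    happen to contain bursts), giving EM an asymmetric starting point.
    """
    T, d = X.shape
    n_chunks = max(K * 20, 8)
    edges = np.linspace(0, T, n_chunks + 1).astype(int)
    assign = rng.integers(0, K, size=n_chunks)
    covs = np.empty((K, d, d))
    for k in range(K):
        rows = np.concatenate(
            [X[edges[i]: edges[i + 1]] for i in range(n_chunks) if assign[i] == k]
            or [X[rng.integers(0, T, size=max(T // K, d + 1))]]
        )
        covs[k] = rows.T @ rows / rows.shape[0]
        covs[k] += reg_scale * np.trace(covs[k]) / d * np.eye(d)
    A = np.full((K, K), 0.2 / max(K - 1, 1))
    np.fill_diagonal(A, 0.8)
    if K == 1:
        A = np.ones((1, 1))
    pi = np.full(K, 1.0 / K)
    return A, pi, covs


def fit(
    embedding: Embedding | np.ndarray,
    K: int = 3,
    seed: int = 0,
    n_restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 100,
    reg: float = 1e-6,
) -> tuple[TdeHmmModel, PosteriorMatrix]:
    """Baum-Welch EM on the valid embedded columns.

    The M-step covariance update adds ``reg * mean(diag)`` times the
    identity to guard against degeneracy.  Convergence is declared when the
    log-likelihood improves by less than ``tol * max(1, |loglik|)``; the
    best of ``n_restarts`` runs (by final log-likelihood) is returned.  The
    returned posteriors cover the full embedding length, with the invalid
    edge columns filled uniformly (1/K, i.e. "off" after thresholding).
    """
    if isinstance(embedding, Embedding):
        X = embedding.valid_points()
        full_T = embedding.n_samples
        valid = embedding.valid
        cfg = embedding.cfg
    else:
        X = np.asarray(embedding, dtype=float).T.copy()
        full_T = X.shape[0]
        valid = slice(0, full_T)
        cfg = None
    if K < 1:
        raise ValueError("K must be >= 1")
    T, d = X.shape
    if T < 10 * K * d:
        raise ValueError(f"need >= {10 * K * d} valid samples to fit K={K}, d={d}")

    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng([int(seed), r])
        A, pi, covs = _init_params(X, K, rng, reg)
        trajectory: list[float] = []
        gamma = None
        for _ in range(max_iter):
            logB = _log_b(X, covs)
            gamma, xi, ll = _scaled_fb(logB, A, pi)
            trajectory.append(float(ll))
            if len(trajectory) > 1 and (
                trajectory[-1] - trajectory[-2]
            ) < tol * max(1.0, abs(trajectory[-1])):
                break
            # M-step
            if K > 1:
                rowsum = xi.sum(axis=1, keepdims=True)
                A = np.where(rowsum > 0, xi / np.where(rowsum == 0, 1, rowsum),
                             1.0 / K)
                pi = gamma[0] / gamma[0].sum()
            occ = gamma.sum(axis=0)
            for k in range(K):
                Xw = X * np.sqrt(gamma[:, k])[:, None]
                covs[k] = Xw.T @ Xw / occ[k]
                covs[k] += reg * np.trace(covs[k]) / d * np.eye(d)
        if best is None or trajectory[-1] > best[0]:
            best = (trajectory[-1], A.copy(), pi.copy(), covs.copy(), trajectory, gamma)

    _, A, pi, covs, trajectory, gamma = best
    model = TdeHmmModel(
        K=K,
        transition=A,
        initial=pi,
        covariances=covs,
        loglik_trajectory=trajectory,
        window_s=cfg.window if cfg else None,
        fs=cfg.fs if cfg else None,
        seed=int(seed),
    )
    gamma_full = np.full((K, full_T), 1.0 / K)
    gamma_full[:, valid] = gamma.T
    return model, PosteriorMatrix(gamma=gamma_full)


def loglik(model: TdeHmmModel, X: np.ndarray) -> float:
    """Scaled forward-algorithm log-likelihood of points X (T, d)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    logB = _log_b(X, model.covariances)
    shift = logB.max(axis=1)
    b = np.exp(logB - shift[:, None])
    return float(forward_loglik(b, model.transition, model.initial) + shift.sum())


def loglik_bruteforce(model: TdeHmmModel, X: np.ndarray) -> float:
    """Exact log-likelihood by summation over all K^T state paths.

    Test oracle only; rejects instances with T > 10 or K > 3.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = X.shape[0]
    K = model.K
    if T > 10 or K > 3:
        raise ValueError("brute-force oracle limited to T <= 10, K <= 3")
    logB = _log_b(X, model.covariances)
    logA = np.log(model.transition)
    logpi = np.log(model.initial)
    path_logs = []
    for path in itertools.product(range(K), repeat=T):
        lp = logpi[path[0]] + logB[0, path[0]]
        for t in range(1, T):
            lp += logA[path[t - 1], path[t]] + logB[t, path[t]]
        path_logs.append(lp)
    return float(logsumexp(path_logs))


def threshold(posterior: PosteriorMatrix, thresh: float = 2.0 / 3.0) -> BinaryStateMatrix:
    """Binarise posteriors: on where gamma > thresh (strictly).

    Any threshold > 1/2 guarantees mutual exclusivity (at most one state on
    per sample) because two posteriors cannot both exceed 1/2.
    """
    if not (0.0 < thresh < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    return BinaryStateMatrix(
        onoff=(posterior.gamma > thresh).astype(np.uint8), threshold=thresh
    )


def _runs(row: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of 1s as half-open (start, stop) sample intervals."""
    padded = np.concatenate(([0], row.astype(np.int8), [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts, stops))


def lifetimes(
    onoff: BinaryStateMatrix,
    fs: float,
    boundaries: list[int] | None = None,
    region_name: str = "",
    segment_labels: list[str] | None = None,
) -> pd.DataFrame:
    """State lifetimes (burst durations) from binary timecourses.

    Runs of 1s that touch a concatenation boundary are split there, so no
    burst spans two participants; each piece is attributed to the segment
    it lies in.  Returns a BurstTable dataframe with columns
    region, state, onset_s, offset_s, duration_s, participant.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    boundaries = sorted(boundaries or [])
    T = onoff.onoff.shape[1]
    edges = [0] + [b for b in boundaries if 0 < b < T] + [T]
    if segment_labels is None:
        segment_labels = [f"p{i:02d}" for i in range(len(edges) - 1)]
    records = []
    for state, row in enumerate(onoff.onoff):
        for seg_idx in range(len(edges) - 1):
            lo, hi = edges[seg_idx], edges[seg_idx + 1]
            for start, stop in _runs(row[lo:hi]):
                records.append(
                    (
                        region_name,
                        state,
                        (lo + start) / fs,
                        (lo + stop) / fs,
                        (stop - start) / fs,
                        segment_labels[seg_idx],
                    )
                )
    return pd.DataFrame(
        records,
        columns=["region", "state", "onset_s", "offset_s", "duration_s", "participant"],
    )
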