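"""Numba kernels for the scaled forward-backward recursions."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def forward_backward(b: np.ndarray, A: np.ndarray, pi: np.ndarray):
    """Scaled forward-backward on per-sample likelihoods ``b`` (T, K).

    ``b`` must already be shifted so each row's maximum is O(1) (the caller
    subtracts the per-sample max log-density before exponentiating and adds
    the shifts back to the returned log-scale sum).

    Returns (gamma (T, K), xi_sum (K, K), log_scale_sum).
    """
    T, K = b.shape
    alpha = np.empty((T, K))
    beta = np.empty((T, K))
    scale = np.empty(T)

    a0 = pi * b[0]
    s = a0.sum()
    scale[0] = s
    alpha[0] = a0 / s
    for t in range(1, T):
        at = np.dot(alpha[t - 1], A) * b[t]
        s = at.sum()
        scale[t] = s
        alpha[t] = at / s

    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = np.dot(A, b[t + 1] * beta[t + 1]) / scale[t + 1]

    gamma = alpha * beta
    for t in range(T):
        gamma[t] /= gamma[t].sum()

    xi = np.zeros((K, K))
    for t in range(1, T):
        denom = scale[t]
        for i in range(K):
            ai = alpha[t - 1, i]
            for j in range(K):
                xi[i, j] += ai * A[i, j] * b[t, j] * beta[t, j] / denom
    return gamma, xi, np.log(scale).sum()


@njit(cache=True)
def forward_loglik(b: np.ndarray, A: np.ndarray, pi: np.ndarray) -> float:
    """Log of the scaled-likelihood normaliser (forward pass only)."""
    T, K = b.shape
    a = pi * b[0]
    s = a.sum()
    ll = np.log(s)
    a = a / s
    for t in range(1, T):
        a = np.dot(a, A) * b[t]
        s = a.sum()
        ll += np.log(s)
        a = a / s
    return ll
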