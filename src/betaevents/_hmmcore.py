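"""Numerical kernels for HMM message passing (numba-compiled).

All kernels take per-sample log "emission" scores (for variational
inference these are expected log-densities under the posterior, so they
need not be normalised densities) plus log initial/transition scores, and
use scaled forward-backward recursions in the linear domain.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def forward_backward(log_b, log_pi, log_a):
    """Scaled forward-backward.

    Returns (gamma, xi_sum, logz): posterior marginals (T, K), summed
    pairwise transition posteriors (K, K) and the log normaliser.
    """
    T, K = log_b.shape
    b = np.empty((T, K))
    shift = np.empty(T)
    for t in range(T):
        m = log_b[t, 0]
        for k in range(1, K):
            if log_b[t, k] > m:
                m = log_b[t, k]
        shift[t] = m
        for k in range(K):
            b[t, k] = np.exp(log_b[t, k] - m)

    a = np.empty((K, K))
    for i in range(K):
        for j in range(K):
            a[i, j] = np.exp(log_a[i, j])
    pi = np.empty(K)
    for k in range(K):
        pi[k] = np.exp(log_pi[k])

    alpha = np.empty((T, K))
    c = np.empty(T)
    s = 0.0
    for k in range(K):
        alpha[0, k] = pi[k] * b[0, k]
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for j in range(K):
            acc = 0.0
            for i in range(K):
                acc += alpha[t - 1, i] * a[i, j]
            alpha[t, j] = acc * b[t, j]
            s += alpha[t, j]
        c[t] = s
        for j in range(K):
            alpha[t, j] /= s

    beta = np.empty((T, K))
    for k in range(K):
        beta[T - 1, k] = 1.0
    for t in range(T - 2, -1, -1):
        for i in range(K):
            acc = 0.0
            for j in range(K):
                acc += a[i, j] * b[t + 1, j] * beta[t + 1, j]
            beta[t, i] = acc / c[t + 1]

    gamma = np.empty((T, K))
    for t in range(T):
        s = 0.0
        for k in range(K):
            gamma[t, k] = alpha[t, k] * beta[t, k]
            s += gamma[t, k]
        for k in range(K):
            gamma[t, k] /= s

    xi_sum = np.zeros((K, K))
    for t in range(1, T):
        for i in range(K):
            for j in range(K):
                xi_sum[i, j] += (
                    alpha[t - 1, i] * a[i, j] * b[t, j] * beta[t, j] / c[t]
                )

    logz = 0.0
    for t in range(T):
        logz += np.log(c[t]) + shift[t]
    return gamma, xi_sum, logz


@njit(cache=True)
def viterbi(log_b, log_pi, log_a):
    """Max-product decoding; returns the most probable state path (T,)."""
    T, K = log_b.shape
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = log_pi[k] + log_b[0, k]
    for t in range(1, T):
        for j in range(K):
            best = delta[t - 1, 0] + log_a[0, j]
            arg = 0
            for i in range(1, K):
                v = delta[t - 1, i] + log_a[i, j]
                if v > best:
                    best = v
                    arg = i
            delta[t, j] = best + log_b[t, j]
            psi[t, j] = arg
    path = np.empty(T, dtype=np.int64)
    best = delta[T - 1, 0]
    arg = 0
    for k in range(1, K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path
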