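"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a route deliberately different from the
package implementation: dense joint-Gaussian algebra instead of Kalman
recursions, O(N²) DFT sums instead of FFT, and full permutation enumeration
instead of rank algebra.
"""

from __future__ import annotations

import itertools

import numpy as np

DIFFUSE_KAPPA = 1e7


def _longdouble_solve(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Gaussian elimination with partial pivoting in extended precision
    (LAPACK has no long-double path)."""
    A = A.copy()
    b = b.copy()
    n = b.size
    for i in range(n):
        p = i + int(np.argmax(np.abs(A[i:, i])))
        if p != i:
            A[[i, p]] = A[[p, i]]
            b[[i, p]] = b[[p, i]]
        for j in range(i + 1, n):
            f = A[j, i] / A[i, i]
            A[j, i:] -= f * A[i, i:]
            b[j] -= f * b[i]
    x = np.zeros(n, dtype=A.dtype)
    for i in range(n - 1, -1, -1):
        x[i] = (b[i] - A[i, i + 1 :] @ x[i + 1 :]) / A[i, i]
    return x


def dense_llt_posterior(
    y, var_obs, var_level, var_slope, kappa=DIFFUSE_KAPPA
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean of the LLT states by dense joint-Gaussian algebra.

    Builds the full 2n × 2n prior covariance of the stacked (level, slope)
    states from the random-walk recursions — initial state N(0, kappa·I) —
    and conditions on all observations at once. Extended precision keeps the
    large-kappa prior from swamping the solve.
    """
    dtype = np.longdouble
    y = np.asarray(y, dtype=dtype)
    n = y.size
    T = np.array([[1.0, 1.0], [0.0, 1.0]], dtype=dtype)
    Q = np.diag(np.array([var_level, var_slope], dtype=dtype))
    P = [np.eye(2, dtype=dtype) * dtype(kappa)]
    for _ in range(1, n):
        P.append(T @ P[-1] @ T.T + Q)
    S = np.zeros((2 * n, 2 * n), dtype=dtype)
    for t in range(n):
        S[2 * t : 2 * t + 2, 2 * t : 2 * t + 2] = P[t]
        M = P[t]
        for u in range(t + 1, n):
            M = M @ T.T
            S[2 * t : 2 * t + 2, 2 * u : 2 * u + 2] = M
            S[2 * u : 2 * u + 2, 2 * t : 2 * t + 2] = M.T
    Z = np.zeros((n, 2 * n), dtype=dtype)
    for t in range(n):
        Z[t, 2 * t] = 1.0
    C = Z @ S @ Z.T + np.eye(n, dtype=dtype) * dtype(var_obs)
    mean_states = S @ Z.T @ _longdouble_solve(C, y)
    return (
        np.asarray(mean_states[0::2], dtype=float),
        np.asarray(mean_states[1::2], dtype=float),
    )


def brute_windowed_power(x: np.ndarray, window: np.ndarray, max_bin: int) -> np.ndarray:
    """O(N²) DFT power of a windowed signal at bins 0..max_bin."""
    xw = np.asarray(x, dtype=float) * window
    n = xw.size
    t = np.arange(n)
    power = np.empty(max_bin + 1)
    for k in range(max_bin + 1):
        re = float(np.sum(xw * np.cos(-2 * np.pi * k * t / n)))
        im = float(np.sum(xw * np.sin(-2 * np.pi * k * t / n)))
        power[k] = re * re + im * im
    return power


def brute_friedman(table: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Friedman statistic and exact permutation p by full
    (k!)^b enumeration of within-block permutations."""
    from scipy.stats import rankdata

    table = np.asarray(table, dtype=float)
    b, k = table.shape
    ranks = rankdata(table, axis=1)

    def stat(r):
        col = r.sum(axis=0)
        num = (k - 1) * float(np.sum((col - b * (k + 1) / 2.0) ** 2))
        den = float(np.sum(r**2)) - b * k * (k + 1) ** 2 / 4.0
        return 0.0 if den <= 0 else num / den

    observed = stat(ranks)
    perms = list(itertools.permutations(range(k)))
    hits = total = 0
    for combo in itertools.product(perms, repeat=b):
        permuted = np.array([ranks[i, list(p)] for i, p in enumerate(combo)])
        total += 1
        if stat(permuted) >= observed - 1e-12:
            hits += 1
    return observed, hits / total
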