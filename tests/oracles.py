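"""Independent brute-force oracles used to cross-check the implementations.

Everything here is written straight from definitions (loops, enumeration,
dense linear algebra) and shares no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------- CompPASS


def compass_bruteforce(counts: np.ndarray) -> dict[str, np.ndarray]:
    """Straight-line CompPASS stats from a (baits, preys, replicates) count array."""
    n_baits, n_preys, n_reps = counts.shape
    x = counts.mean(axis=2)
    z = np.zeros((n_baits, n_preys))
    wd = np.zeros((n_baits, n_preys))
    entropy = np.zeros((n_baits, n_preys))
    for j in range(n_preys):
        col = x[:, j]
        mu = sum(col) / n_baits
        var = sum((v - mu) ** 2 for v in col) / (n_baits - 1)
        sigma = math.sqrt(var)
        f = sum(1 for v in col if v > 0)
        omega = max(1.0, sigma / mu) if mu > 0 else 1.0
        for i in range(n_baits):
            z[i, j] = 0.0 if sigma == 0 else (col[i] - mu) / sigma
            p = sum(1 for r in range(n_reps) if counts[i, j, r] > 0)
            if col[i] > 0:
                wd[i, j] = math.sqrt(col[i] * ((n_baits / f) * omega) ** p)
            qs = [(counts[i, j, r] + 1.0 / n_reps) for r in range(n_reps)]
            total = sum(qs)
            entropy[i, j] = -sum((q / total) * math.log2(q / total) for q in qs)
    return {"x_avg": x, "z": z, "wd": wd, "entropy": entropy}


# ---------------------------------------------------------- urn / BH


def hypergeom_sf_enumeration(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) summed from binomial coefficients."""
    denom = math.comb(N, n)
    total = 0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x)
    return total / denom


def bh_stepup(p_values, q_level: float):
    """Reference BH step-up: (q_values, reject flags)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = ranked * m / (np.arange(m) + 1)
    for i in range(m - 2, -1, -1):
        q[i] = min(q[i], q[i + 1])
    q = np.minimum(q, 1.0)
    reject = np.zeros(m, dtype=bool)
    below = np.flatnonzero(ranked <= (np.arange(m) + 1) / m * q_level)
    if below.size:
        reject[: below[-1] + 1] = True
    q_out = np.empty(m)
    r_out = np.empty(m, dtype=bool)
    q_out[order] = q
    r_out[order] = reject
    return q_out, r_out


# ---------------------------------------------------------- alignment


def nw_affine_oracle(a: str, b: str, blosum, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Gotoh global alignment with gap cost ``gap_open + gap_extend * L``.

    End gaps are penalized. ``blosum`` is a Biopython substitution matrix used
    purely as a score lookup table.
    """
    first = gap_open + gap_extend  # cost of a gap of length 1
    neg = float("-inf")
    la, lb = len(a), len(b)
    M = [[neg] * (lb + 1) for _ in range(la + 1)]
    X = [[neg] * (lb + 1) for _ in range(la + 1)]  # gap in b (a aligned to gap)
    Y = [[neg] * (lb + 1) for _ in range(la + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = -(gap_open + gap_extend * i)
    for j in range(1, lb + 1):
        Y[0][j] = -(gap_open + gap_extend * j)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = blosum[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend, Y[i - 1][j] - first)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend, X[i][j - 1] - first)
    return max(M[la][lb], X[la][lb], Y[la][lb])


# ---------------------------------------------------------- graphs


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = len(adj)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0)
    d[adj > 0] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def dominant_eigenvector(adj: np.ndarray) -> np.ndarray:
    """Dense eigendecomposition; returns |v| of the largest eigenvalue, max=1."""
    vals, vecs = np.linalg.eigh(adj)
    v = np.abs(vecs[:, np.argmax(vals)])
    return v / v.max()
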