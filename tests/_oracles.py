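"""Independent brute-force oracles used by the metric and network tests.

Each oracle recomputes a quantity by a different route than the library
(explicit loops, Floyd–Warshall, SVD) so agreement is evidence, not
tautology.
"""

import numpy as np


def pearson_oracle(segment):
    """Element-wise |PCC| via the covariance formula, one pair at a time."""
    seg = np.asarray(segment, dtype=float)
    n = seg.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            xi = seg[i] - seg[i].mean()
            xj = seg[j] - seg[j].mean()
            out[i, j] = abs((xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum()))
    return out


def clustering_oracle(w):
    """Per-node geometric-mean triangle clustering by exhaustive triple loop."""
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    w_max = w.max()
    if w_max == 0:
        return np.zeros(n)
    w_hat = w / w_max
    out = np.zeros(n)
    for i in range(n):
        k = int((w[i] > 0).sum())
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for l in range(n):
                if j == i or l == i or j == l:
                    continue
                total += (w_hat[i, j] * w_hat[i, l] * w_hat[j, l]) ** (1.0 / 3.0)
        out[i] = total / (k * (k - 1))
    return out


def floyd_warshall_oracle(w):
    """All-pairs shortest-path distances on lengths 1/weight, by triple loop."""
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def path_length_oracle(w):
    """(L over reachable ordered pairs, unreachable fraction)."""
    d = floyd_warshall_oracle(w)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        return np.nan, 1.0
    return d[finite].mean(), 1.0 - finite.sum() / off.sum()


def efficiency_oracle(w):
    """Mean inverse distance over ordered pairs, 1/inf = 0."""
    d = floyd_warshall_oracle(w)
    n = d.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def energy_oracle(w):
    """Graph energy via singular values (equals sum |eigenvalues| for symmetric w)."""
    return float(np.linalg.svd(np.asarray(w, dtype=float), compute_uv=False).sum())


def random_fbn_weights(rng, n=8, density=0.7):
    """Random symmetric weight matrix in [0,1] with zero diagonal."""
    w = rng.uniform(0.05, 1.0, size=(n, n))
    mask = rng.random((n, n)) < density
    w = np.triu(w * mask, 1)
    w = w + w.T
    return w
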