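"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's vectorized code paths: plain double
sums over the weight matrix, so agreement is evidence rather than tautology.
"""

import numpy as np


def dense_weights(nbrs):
    """Dense W from neighbour lists, honouring the structure's weight mode."""
    n = nbrs.n
    W = np.zeros((n, n))
    for i, (nb, w) in enumerate(zip(nbrs.neighbors, nbrs.weight_rows())):
        for j, wij in zip(nb, w):
            W[i, j] = wij
    return W


def brute_moran(values, nbrs):
    v = np.asarray(values, dtype=float)
    W = dense_weights(nbrs)
    n = v.size
    z = v - v.mean()
    num = sum(W[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return (n / W.sum()) * num / (z ** 2).sum()


def brute_geary(values, nbrs):
    v = np.asarray(values, dtype=float)
    W = dense_weights(nbrs)
    n = v.size
    z = v - v.mean()
    num = sum(W[i, j] * (v[i] - v[j]) ** 2 for i in range(n) for j in range(n))
    return (n - 1) * num / (2 * W.sum() * (z ** 2).sum())


def brute_tango_c(counts, populations, centroids, lam):
    counts = np.asarray(counts, dtype=float)
    pop = np.asarray(populations, dtype=float)
    cen = np.asarray(centroids, dtype=float)
    r = counts / counts.sum()
    p = pop / pop.sum()
    n = counts.size
    total = 0.0
    for i in range(n):
        for j in range(n):
            d2 = ((cen[i] - cen[j]) ** 2).sum()
            total += np.exp(-4.0 * d2 / lam ** 2) * (r[i] - p[i]) * (r[j] - p[j])
    return total
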