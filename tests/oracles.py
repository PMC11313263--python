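"""Independent brute-force oracles used only by the test suite.

Deliberately naive implementations — O(n³) full re-scans, explicit
double loops, direct formula evaluation — kept structurally unlike the
package code so agreement is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def naive_pairwise(vectors: np.ndarray, metric: str,
                   covariance: np.ndarray | None = None) -> np.ndarray:
    """Double-loop pairwise dissimilarities straight from the definitions."""
    X = np.asarray(vectors, dtype=float)
    n = len(X)
    D = np.zeros((n, n))
    vi = None if covariance is None else np.linalg.inv(covariance)
    for i in range(n):
        for j in range(n):
            x, y = X[i], X[j]
            if metric == "euclidean":
                D[i, j] = math.sqrt(float(((x - y) ** 2).sum()))
            elif metric == "manhattan":
                D[i, j] = float(np.abs(x - y).sum())
            elif metric == "correlation":
                xc, yc = x - x.mean(), y - y.mean()
                D[i, j] = 1.0 - float(
                    (xc * yc).sum()
                    / math.sqrt((xc * xc).sum() * (yc * yc).sum())
                )
            elif metric == "cosine":
                D[i, j] = 1.0 - float(
                    (x * y).sum()
                    / math.sqrt((x * x).sum() * (y * y).sum())
                )
            elif metric == "mahalanobis":
                d = x - y
                D[i, j] = math.sqrt(float(d @ vi @ d))
            else:
                raise ValueError(metric)
    np.fill_diagonal(D, 0.0)
    return D


def naive_agglomerate(D: np.ndarray, linkage: str) -> list[tuple[int, int, float]]:
    """Full-rescan agglomeration returning (a, b, height) per merge.

    Maintains an explicit list of active clusters and recomputes the
    best pair by scanning all pairs each step; inter-cluster distances
    stored in a plain dict keyed by unordered id pairs and updated with
    the textbook Lance–Williams formulas written out per linkage.
    """
    n = len(D)
    active = {i: 1 for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = float(D[i, j])
    merges = []
    nid = n
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                d = dist[frozenset((i, j))]
                if best is None or d < best[0] or (d == best[0] and (i, j) < best[1:]):
                    best = (d, i, j)
        h, a, b = best
        na, nb = active[a], active[b]
        for k in sorted(active):
            if k in (a, b):
                continue
            dka = dist[frozenset((k, a))]
            dkb = dist[frozenset((k, b))]
            dab = dist[frozenset((a, b))]
            nk = active[k]
            if linkage == "single":
                dnew = min(dka, dkb)
            elif linkage == "complete":
                dnew = max(dka, dkb)
            elif linkage == "average":
                dnew = (na * dka + nb * dkb) / (na + nb)
            elif linkage == "mcquitty":
                dnew = (dka + dkb) / 2.0
            elif linkage == "median":
                dnew = dka / 2 + dkb / 2 - dab / 4
            elif linkage == "centroid":
                s = na + nb
                dnew = na / s * dka + nb / s * dkb - na * nb / s**2 * dab
            elif linkage == "ward":
                s = na + nb + nk
                dnew = ((na + nk) * dka + (nb + nk) * dkb - nk * dab) / s
            else:
                raise ValueError(linkage)
            dist[frozenset((k, nid))] = dnew
        del active[a], active[b]
        active[nid] = na + nb
        merges.append((a, b, h))
        nid += 1
    return merges


def naive_pca(X: np.ndarray):
    """Eigendecomposition of the explicit covariance of row-vectors."""
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (len(X) - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]
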