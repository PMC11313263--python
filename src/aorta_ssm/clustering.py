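"""Agglomerative hierarchical clustering of shape vectors.

The engine is metric-agnostic: inter-cluster dissimilarities are
updated with the Lance–Williams recurrence

    d(k, i∪j) = a_i d(k,i) + a_j d(k,j) + b d(i,j) + g |d(k,i) - d(k,j)|

applied *directly to the supplied dissimilarities* for every linkage.
This is required because the default configuration pairs a
non-Euclidean metric (correlation distance) with McQuitty/WPGMA
linkage; centroid, median and Ward updates are only geometrically
interpretable for squared-Euclidean input, which is logged as a caveat
when they are requested on other metrics.

Determinism: merge ties are broken by the smallest (cluster_a,
cluster_b) id pair, so dendrograms are bit-reproducible.  Cluster ids
follow the usual convention — leaves are 0..n-1 and the cluster formed
at merge step s gets id n+s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import distance as _sdist

from .errors import InvalidParameterError, UndefinedCorrelationError

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "ClusterAssignment",
    "ContingencyTable",
    "METRICS",
    "LINKAGES",
    "dissimilarity_matrix",
    "agglomerate",
    "cut_at_height",
    "cut_to_k",
    "cluster_contingency",
    "majority_cluster_fraction",
    "to_newick",
    "to_scipy_linkage",
]

log = logging.getLogger(__name__)

METRICS = ("euclidean", "manhattan", "correlation", "cosine", "mahalanobis")
LINKAGES = ("single", "complete", "average", "centroid", "median", "ward", "mcquitty")

# Lance–Williams coefficients (a_i, a_j, b, g) for size-independent linkages
_LW_FIXED = {
    "single": (0.5, 0.5, 0.0, -0.5),
    "complete": (0.5, 0.5, 0.0, 0.5),
    "mcquitty": (0.5, 0.5, 0.0, 0.0),
    "median": (0.5, 0.5, -0.25, 0.0),
}


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a named metric."""

    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidParameterError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise InvalidParameterError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise InvalidParameterError("distance matrix diagonal must be zero")
        if np.any(v < -1e-12):
            raise InvalidParameterError("dissimilarities must be non-negative")
        object.__setattr__(self, "values", np.maximum(v, 0.0))

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class Dendrogram:
    """Binary merge tree: (cluster_a, cluster_b, height, new_size) per step."""

    merges: tuple[tuple[int, int, float, int], ...]
    leaf_labels: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    @property
    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat clustering: contiguous 1..k labels per subject plus the cut used."""

    labels: np.ndarray
    cut: float | int
    cut_kind: str  # "height" | "k"

    @property
    def k(self) -> int:
        return int(self.labels.max())


@dataclass(frozen=True)
class ContingencyTable:
    """Surgical-group (rows) by cluster (columns) count table."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))


def dissimilarity_matrix(
    vectors: np.ndarray, metric: str = "correlation",
    covariance: np.ndarray | None = None,
) -> DistanceMatrix:
    """Pairwise dissimilarities between the rows of ``vectors``.

    ``correlation`` is 1 - Pearson r of the two rows (range [0, 2]),
    ``cosine`` is 1 - cosine similarity; ``mahalanobis`` needs a
    positive-definite ``covariance``.  Zero-variance rows are rejected
    under the correlation metric: an undefined Pearson r must not
    silently cluster.
    """
    X = np.asarray(vectors, dtype=np.float64)
    if X.ndim != 2 or len(X) < 2:
        raise InvalidParameterError("need a 2-D matrix with >= 2 rows")
    if metric == "correlation":
        sd = X.std(axis=1)
        bad = np.nonzero(sd == 0)[0]
        if len(bad):
            raise UndefinedCorrelationError(
                f"row(s) {bad.tolist()} have zero variance; correlation "
                "distance is undefined"
            )
        d = _sdist.squareform(_sdist.pdist(X, metric="correlation"))
    elif metric == "euclidean":
        d = _sdist.squareform(_sdist.pdist(X, metric="euclidean"))
    elif metric == "manhattan":
        d = _sdist.squareform(_sdist.pdist(X, metric="cityblock"))
    elif metric == "cosine":
        d = _sdist.squareform(_sdist.pdist(X, metric="cosine"))
    elif metric == "mahalanobis":
        if covariance is None:
            raise InvalidParameterError("mahalanobis metric requires a covariance")
        cov = np.asarray(covariance, dtype=np.float64)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise InvalidParameterError(
                "covariance must be positive definite"
            ) from exc
        d = _sdist.squareform(_sdist.pdist(X, metric="mahalanobis",
                                           VI=np.linalg.inv(cov)))
    else:
        raise InvalidParameterError(
            f"unknown metric {metric!r}; choose from {METRICS}"
        )
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2.0, metric)


def _lw_coefficients(linkage: str, ni: int, nj: int, nk: int):
    if linkage in _LW_FIXED:
        return _LW_FIXED[linkage]
    if linkage == "average":
        return (ni / (ni + nj), nj / (ni + nj), 0.0, 0.0)
    if linkage == "centroid":
        s = ni + nj
        return (ni / s, nj / s, -ni * nj / s**2, 0.0)
    if linkage == "ward":
        s = ni + nj + nk
        return ((ni + nk) / s, (nj + nk) / s, -nk / s, 0.0)
    raise InvalidParameterError(
        f"unknown linkage {linkage!r}; choose from {LINKAGES}"
    )


def agglomerate(D: DistanceMatrix, linkage: str = "mcquitty",
                leaf_labels: list[str] | None = None) -> Dendrogram:
    """Full agglomerative merge sequence via the Lance–Williams recurrence.

    Exactly n-1 merges; at each step the globally closest active pair is
    merged (ties -> smallest sorted id pair) and the dissimilarity of the
    new cluster to every survivor is updated per the linkage.
    """
    if linkage not in LINKAGES:
        raise InvalidParameterError(
            f"unknown linkage {linkage!r}; choose from {LINKAGES}"
        )
    if linkage in ("centroid", "median", "ward") and D.metric not in ("euclidean",):
        log.info(
            "%s linkage applied to %s dissimilarities: the Lance-Williams update "
            "is used verbatim but is only geometrically interpretable for "
            "squared Euclidean input", linkage, D.metric,
        )
    n = D.n
    labels = tuple(leaf_labels) if leaf_labels is not None else tuple(
        str(i) for i in range(n)
    )
    if len(labels) != n:
        raise InvalidParameterError("leaf_labels length mismatch")
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D.values[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    size = {i: 1 for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        na, nb = size.pop(a), size.pop(b)
        new_size = na + nb
        dab = dist.pop((a, b))
        updates = {}
        for k in size:
            dka = dist.pop(tuple(sorted((k, a))))
            dkb = dist.pop(tuple(sorted((k, b))))
            ai, aj, beta, gamma = _lw_coefficients(linkage, na, nb, size[k])
            updates[(k, next_id)] = (
                ai * dka + aj * dkb + beta * dab + gamma * abs(dka - dkb)
            )
        dist.update(updates)
        size[next_id] = new_size
        merges.append((a, b, h, new_size))
        next_id += 1
    return Dendrogram(tuple(merges), labels)


def _labels_from_unions(n: int, pairs: list[tuple[int, int]]) -> np.ndarray:
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    roots: dict[int, int] = {}
    labels = np.empty(n, dtype=np.int64)
    for i in range(n):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots) + 1  # label order = first leaf occurrence
        labels[i] = roots[r]
    return labels


def _merge_leaf_reps(dendro: Dendrogram) -> list[int]:
    """First-leaf representative of every cluster id (leaves then merges)."""
    reps = list(range(dendro.n_leaves))
    for a, b, _, _ in dendro.merges:
        reps.append(min(reps[a], reps[b]))
    return reps


def cut_at_height(dendro: Dendrogram, h: float) -> ClusterAssignment:
    """Flat clusters from merges at height <= ``h`` (monotone dendrograms)."""
    if h < 0:
        raise InvalidParameterError("cut height must be >= 0")
    reps = _merge_leaf_reps(dendro)
    pairs = [(reps[a], reps[b]) for a, b, height, _ in dendro.merges if height <= h]
    return ClusterAssignment(_labels_from_unions(dendro.n_leaves, pairs), h, "height")


def cut_to_k(dendro: Dendrogram, k: int) -> ClusterAssignment:
    """Undo the last k-1 merges, leaving exactly ``k`` flat clusters."""
    n = dendro.n_leaves
    if not 1 <= k <= n:
        raise InvalidParameterError(f"k must be in [1, {n}], got {k}")
    reps = _merge_leaf_reps(dendro)
    pairs = [(reps[a], reps[b]) for a, b, _, _ in dendro.merges[: n - k]]
    return ClusterAssignment(_labels_from_unions(n, pairs), k, "k")


def cluster_contingency(
    assignment: ClusterAssignment, group_labels: np.ndarray,
    group_order: list[str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate surgical group (rows) against cluster (columns)."""
    groups = np.asarray(group_labels)
    if len(groups) != len(assignment.labels):
        raise InvalidParameterError("group labels misaligned with cluster labels")
    rows = group_order if group_order is not None else list(
        dict.fromkeys(groups.tolist())
    )
    k = assignment.k
    counts = np.zeros((len(rows), k), dtype=np.int64)
    row_index = {g: i for i, g in enumerate(rows)}
    for g, c in zip(groups, assignment.labels):
        counts[row_index[str(g)], int(c) - 1] += 1
    return ContingencyTable(
        counts, tuple(rows), tuple(f"cluster_{j + 1}" for j in range(k))
    )


def majority_cluster_fraction(
    assignment: ClusterAssignment, group_labels: np.ndarray, group: str
) -> float:
    """Largest fraction of one surgical group falling in a single cluster."""
    groups = np.asarray(group_labels)
    members = assignment.labels[groups == group]
    if len(members) == 0:
        raise InvalidParameterError(f"group {group!r} not present")
    _, counts = np.unique(members, return_counts=True)
    return float(counts.max() / len(members))


def to_newick(dendro: Dendrogram) -> str:
    """Newick export with ultrametric branch lengths (half merge heights)."""
    n = dendro.n_leaves
    height = [0.0] * n + [m[2] for m in dendro.merges]
    children: list[tuple[int, int] | None] = [None] * n + [
        (m[0], m[1]) for m in dendro.merges
    ]

    def render(idx: int, parent_h: float) -> str:
        length = max(0.0, (parent_h - height[idx]) / 2.0)
        if children[idx] is None:
            return f"{dendro.leaf_labels[idx]}:{length:.10g}"
        a, b = children[idx]
        return f"({render(a, height[idx])},{render(b, height[idx])}):{length:.10g}"

    root = n + len(dendro.merges) - 1
    return render(root, height[root]) + ";"


def to_scipy_linkage(dendro: Dendrogram) -> np.ndarray:
    """Merge list as a scipy-style (n-1, 4) linkage matrix for plotting."""
    return np.array(
        [[a, b, h, s] for a, b, h, s in dendro.merges], dtype=np.float64
    )
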