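"""Nonparametric and contingency statistics for cluster comparisons.

The test statistics — Pearson chi-squared (no continuity correction),
Kruskal–Wallis H with mid-rank tie correction, Dunn's pairwise rank z,
and ordinary least squares — are implemented from their defining
formulas; tail probabilities come from the standard chi-squared, normal
and t distributions (regularised incomplete gamma and friends).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special as _sp
from scipy import stats as _st

from .clustering import ContingencyTable
from .errors import CollinearityError, DegenerateTableError, InvalidParameterError

__all__ = [
    "TestResult",
    "RegressionResult",
    "pearson_chi_squared",
    "kruskal_wallis",
    "dunn_pairwise",
    "ols_fit",
    "chi2_sf",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p: float
    method: str
    pair: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.statistic):
            raise InvalidParameterError("test statistic must be finite")
        if not 0.0 <= self.p <= 1.0:
            raise InvalidParameterError("p must lie in [0, 1]")


@dataclass(frozen=True)
class RegressionResult:
    coefficients: dict[str, float]
    p_values: dict[str, float]
    std_errors: dict[str, float]
    r_squared: float
    n: int


def chi2_sf(x: float, df: int) -> float:
    """Upper tail of the chi-squared distribution, 1 - P(df/2, x/2)."""
    if x < 0 or df < 1:
        raise InvalidParameterError("need x >= 0 and df >= 1")
    return float(_sp.gammaincc(df / 2.0, x / 2.0))


def pearson_chi_squared(table: ContingencyTable | np.ndarray) -> TestResult:
    """Pearson chi-squared test of independence, no continuity correction.

    ``statistic = sum (O - E)^2 / E`` with ``E = row * col / N`` and
    ``df = (rows - 1)(cols - 1)``.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    counts = np.asarray(counts, dtype=np.float64)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise DegenerateTableError("need a table with >= 2 rows and >= 2 columns")
    if np.any(counts < 0) or np.any(counts != np.round(counts)):
        raise InvalidParameterError("counts must be non-negative integers")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise DegenerateTableError("zero row/column margin: chi-squared undefined")
    expected = np.outer(row, col) / counts.sum()
    stat = float(((counts - expected) ** 2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    return TestResult(stat, df, chi2_sf(stat, df), "pearson_chi_squared")


def _joint_ranks(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, float]:
    pooled = np.concatenate(groups)
    ranks = _st.rankdata(pooled)  # mid-ranks on ties
    sizes = np.array([len(g) for g in groups])
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    return ranks, sizes, tie_term


def kruskal_wallis(groups: list[np.ndarray]) -> TestResult:
    """Kruskal–Wallis H across >= 2 groups, mid-rank ties with tie correction."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise InvalidParameterError("need >= 2 non-empty groups")
    ranks, sizes, tie_term = _joint_ranks(groups)
    n = int(sizes.sum())
    if n < 3:
        raise InvalidParameterError("need total n >= 3")
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array(
        [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))]
    )
    h = 12.0 / (n * (n + 1)) * float(np.sum(sizes * mean_ranks**2)) - 3.0 * (n + 1)
    correction = 1.0 - tie_term / (n**3 - n)
    if correction <= 0:  # every observation identical
        h = 0.0
    else:
        h /= correction
    h = max(h, 0.0)
    df = len(groups) - 1
    return TestResult(h, df, chi2_sf(h, df), "kruskal_wallis")


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    m = len(p)
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    if method == "holm":
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            adj[i] = min(1.0, running)
        return adj
    if method == "bh":
        running = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            running = min(running, m * p[i] / (rank + 1))
            adj[i] = min(1.0, running)
        return adj
    raise InvalidParameterError(
        f"unknown adjustment {method!r}; choose none/bonferroni/holm/bh"
    )


def dunn_pairwise(
    groups: list[np.ndarray],
    adjustment: str = "none",
    names: list[str] | None = None,
) -> list[TestResult]:
    """Dunn's post-hoc pairwise comparisons on joint ranks.

    For each pair ``z = (Ri - Rj) / sqrt((N(N+1)/12 - T/(12(N-1))) *
    (1/ni + 1/nj))`` where T is the tie term; two-sided normal p-values
    with optional multiplicity adjustment over the pair family.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise InvalidParameterError("need >= 2 non-empty groups")
    names = names if names is not None else [str(i + 1) for i in range(len(groups))]
    ranks, sizes, tie_term = _joint_ranks(groups)
    n = int(sizes.sum())
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_ranks = np.array(
        [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))]
    )
    var_term = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))
    pairs, zs = [], []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            pairs.append((names[i], names[j]))
            zs.append(z)
    raw = np.array([2.0 * _st.norm.sf(abs(z)) for z in zs])
    adj = _adjust(raw, adjustment)
    return [
        TestResult(float(z), 0, float(min(1.0, p)), f"dunn[{adjustment}]", pair)
        for z, p, pair in zip(zs, adj, pairs)
    ]


def ols_fit(
    y: np.ndarray, X: np.ndarray, names: list[str] | None = None
) -> RegressionResult:
    """Ordinary least squares with an automatic intercept.

    ``X`` holds one column per predictor (no intercept column).  Returns
    coefficients, two-sided t-test p per coefficient, and r².
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if len(y) != n:
        raise InvalidParameterError("y and X row counts differ")
    if n <= k + 1:
        raise InvalidParameterError(f"need n > predictors + 1 (n={n}, k={k})")
    names = names if names is not None else [f"x{i + 1}" for i in range(k)]
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < k + 1:
        raise CollinearityError("design matrix is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if tss == 0 else 1.0 - rss / tss
    dof = n - k - 1
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * _st.t.sf(np.abs(tvals), dof)
    labels = ["intercept"] + list(names)
    return RegressionResult(
        coefficients=dict(zip(labels, beta.tolist())),
        p_values=dict(zip(labels, pvals.tolist())),
        std_errors=dict(zip(labels, se.tolist())),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        n=n,
    )
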