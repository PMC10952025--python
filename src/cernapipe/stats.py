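"""Self-contained statistical primitives used by every pipeline stage.

The pipeline leans on a small, fixed vocabulary of tests: Welch's t and
Welch's one-way ANOVA for clinical associations, Pearson and Spearman
correlation for co-expression and immune-infiltration filtering, a
hypergeometric upper tail for over-representation, and Benjamini–Hochberg
step-up adjustment wherever a family of p-values is reported.

All location tests are two-sided.  Missing values (NaN) are dropped
pairwise / listwise before testing and the dropped count is retained on the
result object.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats as sps

from .errors import DegenerateDataError, InsufficientDataError, InvalidInputError

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "CorrelationResult",
    "bh_adjust",
    "welch_t",
    "welch_anova",
    "pearson_test",
    "spearman_test",
    "hypergeom_enrich",
    "associate_feature",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``df`` is a float for single-df tests and a ``(df1, df2)`` tuple for F
    tests; ``None`` for tests without a df concept (exact hypergeometric).
    """

    statistic: float
    df: float | tuple[float, float] | None
    p_value: float
    method: str
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise InvalidInputError(f"p-value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation coefficient with its two-sided test."""

    coefficient: float
    p_value: float
    n: int
    method: str = "pearson"

    def __post_init__(self) -> None:
        if abs(self.coefficient) > 1.0 + 1e-12:
            raise InvalidInputError(f"|coefficient| {self.coefficient} exceeds 1")


def _clean(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    return a[~np.isnan(a)]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved.

    adj_p[i] = min over j with rank(j) >= rank(i) of p[j] * m / rank(j),
    capped at 1.  Monotone in the ranked p-values by construction.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise InvalidInputError("p-values must all lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def welch_t(a, b) -> TestResult:
    """Welch's unequal-variance two-sample t-test (two-sided)."""
    a, b = _clean(a), _clean(b)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError(
            f"welch_t needs >=2 values per group, got {n1} and {n2}"
        )
    m1, m2 = a.mean(), b.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        if m1 == m2:
            return TestResult(0.0, float(n1 + n2 - 2), 1.0, "welch_t")
        raise DegenerateDataError(
            "both groups have zero variance with unequal means; t undefined"
        )
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(min(p, 1.0)), "welch_t")


def welch_anova(groups) -> TestResult:
    """Welch's heteroscedastic one-way ANOVA over ``k >= 2`` groups."""
    gs = [_clean(g) for g in groups]
    k = len(gs)
    if k < 2:
        raise InvalidInputError("welch_anova needs at least 2 groups")
    if any(g.size < 2 for g in gs):
        raise InsufficientDataError("every group needs >=2 values")
    n = np.array([g.size for g in gs], dtype=float)
    mean = np.array([g.mean() for g in gs])
    var = np.array([g.var(ddof=1) for g in gs])
    if np.all(var == 0.0):
        if np.all(mean == mean[0]):
            return TestResult(0.0, (float(k - 1), float(n.sum() - k)), 1.0, "welch_anova")
        raise DegenerateDataError("all groups constant with unequal means")
    w = n / var
    sw = w.sum()
    grand = (w * mean).sum() / sw
    a = (w * (mean - grand) ** 2).sum() / (k - 1)
    tail = ((1.0 - w / sw) ** 2 / (n - 1.0)).sum()
    b = 1.0 + 2.0 * (k - 2) / (k**2 - 1.0) * tail
    f = a / b
    df1 = float(k - 1)
    df2 = (k**2 - 1.0) / (3.0 * tail)
    p = sps.f.sf(f, df1, df2)
    return TestResult(float(f), (df1, float(df2)), float(min(p, 1.0)), "welch_anova")


def _paired_clean(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise InvalidInputError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    dropped = int((~keep).sum())
    if dropped:
        logger.debug("correlation: dropped %d incomplete pairs", dropped)
    return x[keep], y[keep]


def pearson_test(x, y) -> CorrelationResult:
    """Pearson correlation with two-sided p from the t-transform (n-2 df)."""
    x, y = _paired_clean(x, y)
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"pearson_test needs >=3 pairs, got {n}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateDataError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), n, "pearson")


# int8 keeps the n<=10 permutation tables (<= 3.6e6 x 10) at ~36 MB.
def _all_permutations(n: int) -> np.ndarray:
    perms = np.zeros((1, 1), dtype=np.int8)
    for k in range(2, n + 1):
        m, prev = perms.shape[0], perms
        perms = np.empty((m * k, k), dtype=np.int8)
        for pos in range(k):
            block = perms[pos * m : (pos + 1) * m]
            block[:, pos] = k - 1
            cols = [c for c in range(k) if c != pos]
            block[:, cols] = prev
    return perms


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Two-sided exact p by full enumeration of y-rank permutations (n<=10)."""
    n = rx.size
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = math.sqrt((cx**2).sum() * (cy**2).sum())
    perms = _all_permutations(n)
    observed = abs(rho)
    count = 0
    for lo in range(0, perms.shape[0], 200_000):  # bound peak memory
        chunk = cy[perms[lo : lo + 200_000]] @ cx / denom
        count += int(np.sum(np.abs(chunk) >= observed - 1e-12))
    return count / perms.shape[0]


def spearman_test(x, y) -> CorrelationResult:
    """Spearman rank correlation (mid-ranks for ties).

    p-value: exact permutation enumeration for n <= 10, two-sided
    t-approximation otherwise.
    """
    x, y = _paired_clean(x, y)
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"spearman_test needs >=3 pairs, got {n}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateDataError("zero variance: correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 10:
        p = _spearman_exact_p(rx, ry, rho)
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(rho, min(p, 1.0), n, "spearman")


def hypergeom_enrich(k: int, n: int, K: int, N: int) -> TestResult:
    """One-sided over-representation p = P(X >= k), X ~ Hypergeom(N, K, n).

    ``k`` hits in a list of ``n`` drawn from a universe of ``N`` containing
    ``K`` set members.
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if int(v) != v or v < 0:
            raise InvalidInputError(f"{name} must be a non-negative integer")
    if not (k <= min(n, K) and max(n, K) <= N):
        raise InvalidInputError(
            f"inconsistent counts: need k <= min(n, K) <= N, got k={k} n={n} K={K} N={N}"
        )
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return TestResult(float(k), None, min(p, 1.0), "hypergeom")


def associate_feature(values, labels) -> TestResult:
    """Association of one gene's expression with a categorical clinical feature.

    Samples with a missing label or value are dropped; levels left with fewer
    than 2 observations are discarded (counted in ``details``).  Dispatches
    Welch's t for two remaining levels and Welch's ANOVA for more.
    """
    values = np.asarray(values, dtype=float).ravel()
    labels = np.asarray(labels, dtype=object).ravel()
    if values.size != labels.size:
        raise InvalidInputError("values and labels must align")
    n_total = values.size
    keep = ~np.isnan(values)
    missing_label = np.array(
        [lab is None or (isinstance(lab, float) and math.isnan(lab)) for lab in labels]
    )
    keep &= ~missing_label
    values, labels = values[keep], labels[keep]
    levels = sorted({str(lab) for lab in labels})
    groups, counts, thin = [], {}, {}
    for lev in levels:
        g = values[np.array([str(lab) == lev for lab in labels])]
        if g.size >= 2:
            groups.append(g)
            counts[lev] = int(g.size)
        else:
            thin[lev] = int(g.size)
    if len(groups) < 2:
        raise InsufficientDataError(
            f"fewer than 2 usable label levels (usable={list(counts)})"
        )
    if len(groups) == 2:
        res = welch_t(groups[0], groups[1])
    else:
        res = welch_anova(groups)
    details = dict(res.details)
    n_used = int(sum(counts.values()))
    details.update(
        level_counts=counts,
        n=n_used,
        n_dropped=int(n_total - n_used),
        dropped_levels=thin,
    )
    return TestResult(res.statistic, res.df, res.p_value, res.method, details)


def pairwise_pearson(x_mat: np.ndarray, y_mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r and two-sided p between rows of two matrices.

    Rows are variables, columns matched samples.  Returns (r, p) of shape
    (x_rows, y_rows).  Used for the lncRNA x mRNA co-expression grid where
    per-pair calls would be wasteful.
    """
    x = np.asarray(x_mat, dtype=float)
    y = np.asarray(y_mat, dtype=float)
    if x.shape[1] != y.shape[1]:
        raise InvalidInputError("sample dimensions differ")
    n = x.shape[1]
    if n < 3:
        raise InsufficientDataError("need >=3 shared samples")
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xs = np.sqrt((xc**2).sum(axis=1))
    ys = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc.T) / np.outer(xs, ys)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    return r, p
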