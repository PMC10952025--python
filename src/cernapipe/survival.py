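"""Kaplan–Meier estimation, log-rank testing and prognostic screening.

Candidate checkpoint genes are screened by dichotomizing their expression —
either at the median or at the maximally selected (optimal) cutpoint — and
comparing overall / progression-free survival between the high and low
groups with the log-rank test.

The maximally selected cutpoint scans every observed expression value whose
split keeps both groups within configurable size fractions and keeps the
threshold with the largest log-rank chi-square.  Because the threshold is
chosen to maximize the statistic, the naive p-value at the optimum is
selection-inflated; a permutation-corrected p-value (expression shuffled
against survival) is computed alongside when ``n_perm > 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateSplitError,
    InsufficientDataError,
    InvalidInputError,
    NoCutpointError,
)
from .stats import TestResult

logger = logging.getLogger(__name__)

SURVIVAL_COLUMNS = ("sample_id", "time", "event", "endpoint")
ENDPOINTS = ("OS", "PFS")


def validate_survival(table: pd.DataFrame) -> pd.DataFrame:
    """Check a survival table (sample_id, time, event, endpoint) and return it."""
    missing = [c for c in SURVIVAL_COLUMNS if c not in table.columns]
    if missing:
        raise InvalidInputError(f"survival table missing columns {missing}")
    dup_mask = table.duplicated(subset=["sample_id", "endpoint"])
    if dup_mask.any():
        dup = table.loc[dup_mask, "sample_id"].iloc[0]
        raise InvalidInputError(
            f"duplicate sample_id {dup!r} within one endpoint of the survival table"
        )
    if (table["time"] < 0).any():
        raise InvalidInputError("negative survival times")
    if not table["event"].isin([0, 1]).all():
        raise InvalidInputError("event must be 0 (censored) or 1 (event)")
    bad = set(table["endpoint"]) - set(ENDPOINTS)
    if bad:
        raise InvalidInputError(f"unknown endpoint(s) {sorted(bad)}")
    return table


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate over the distinct event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5, NaN if never reached."""
        below = self.survival <= 0.5
        return float(self.times[below][0]) if below.any() else float("nan")


def km_estimate(time, event) -> KMCurve:
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event, dtype=int).ravel()
    if time.size == 0:
        raise InsufficientDataError("empty survival input")
    if time.size != event.size:
        raise InvalidInputError("time and event must align")
    event_times = np.unique(time[event == 1])
    surv, at_risk, d_out = [], [], []
    s = 1.0
    for t in event_times:
        n_t = int((time >= t).sum())
        d_t = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d_t / n_t
        surv.append(s)
        at_risk.append(n_t)
        d_out.append(d_t)
    return KMCurve(
        times=event_times,
        survival=np.asarray(surv),
        at_risk=np.asarray(at_risk, dtype=int),
        n_events=np.asarray(d_out, dtype=int),
    )


def _logrank_scan(time, event, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Log-rank chi-square (1 df) for many candidate groupings at once.

    ``groups`` is a boolean (n_candidates, n_samples) matrix; row k defines
    "group 1" membership.  Returns (chi2, observed_minus_expected) per row.
    Uses the hypergeometric variance at each distinct event time with the
    simultaneous-event (tied) convention.
    """
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event, dtype=int).ravel()
    g = np.asarray(groups, dtype=float)
    if g.ndim == 1:
        g = g[None, :]
    event_times = np.unique(time[event == 1])
    if event_times.size == 0:
        raise InsufficientDataError("no events observed")
    # at-risk and event-at-t indicator matrices: samples x event-times
    at_risk = time[:, None] >= event_times[None, :]
    died = (time[:, None] == event_times[None, :]) & (event[:, None] == 1)
    n_t = at_risk.sum(axis=0).astype(float)
    d_t = died.sum(axis=0).astype(float)
    n1_t = g @ at_risk  # candidates x times
    d1_t = g @ died
    frac = n1_t / n_t
    expected = d_t * frac
    with np.errstate(invalid="ignore", divide="ignore"):
        var_t = d_t * frac * (1.0 - frac) * (n_t - d_t) / np.maximum(n_t - 1.0, 1.0)
    o_minus_e = (d1_t - expected).sum(axis=1)
    var = var_t.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.where(var > 0, o_minus_e**2 / np.maximum(var, 1e-300), 0.0)
    return chi2, o_minus_e


def logrank(time_a, event_a, time_b, event_b) -> TestResult:
    """Two-group log-rank test; chi-square with 1 df, two-sided p."""
    ta = np.asarray(time_a, dtype=float).ravel()
    tb = np.asarray(time_b, dtype=float).ravel()
    ea = np.asarray(event_a, dtype=int).ravel()
    eb = np.asarray(event_b, dtype=int).ravel()
    if ta.size == 0 or tb.size == 0:
        raise InvalidInputError("both groups must be non-empty")
    time = np.concatenate([ta, tb])
    event = np.concatenate([ea, eb])
    membership = np.zeros(time.size, dtype=bool)
    membership[: ta.size] = True
    chi2, o_minus_e = _logrank_scan(time, event, membership[None, :])
    p = float(sps.chi2.sf(chi2[0], 1)) if chi2[0] > 0 else 1.0
    return TestResult(
        float(chi2[0]),
        1.0,
        min(p, 1.0),
        "logrank",
        details={"o_minus_e_group_a": float(o_minus_e[0])},
    )


def split_by_median(values) -> np.ndarray:
    """Boolean high/low labels: strictly above the median is 'high'.

    Samples equal to the median go to the low group (<= median).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 4:
        raise InsufficientDataError("median split needs >=4 samples")
    if np.ptp(v) == 0.0:
        raise DegenerateSplitError("constant expression: no median split")
    high = v > np.median(v)
    if not high.any() or high.all():
        raise DegenerateSplitError("median split produced an empty group")
    return high


@dataclass(frozen=True)
class CutpointResult:
    threshold: float
    statistic: float
    p_naive: float
    p_permutation: float | None
    n_high: int
    n_low: int
    selection_inflated: bool = True
    details: dict = field(default_factory=dict)


def _admissible_thresholds(expr: np.ndarray, q_low: float, q_high: float) -> np.ndarray:
    """Candidate cutpoints: observed values whose '>' split keeps both group
    fractions inside [q_low, q_high]."""
    n = expr.size
    cands = np.unique(expr)
    n_high = (expr[None, :] > cands[:, None]).sum(axis=1)
    frac_high = n_high / n
    ok = (frac_high >= q_low) & (frac_high <= q_high)
    # both groups constrained: low fraction = 1 - high fraction
    ok &= (1.0 - frac_high >= q_low) & (1.0 - frac_high <= q_high)
    return cands[ok]


def optimal_cutpoint(
    expr,
    time,
    event,
    q_low: float = 0.1,
    q_high: float = 0.9,
    n_perm: int = 1000,
    seed: int | None = None,
) -> CutpointResult:
    """Maximally selected log-rank cutpoint with optional permutation p.

    Scans every admissible observed expression value, maximizes the log-rank
    chi-square, and reports the naive p (selection-inflated) plus, when
    ``n_perm > 0``, p = (b + 1) / (n_perm + 1) where b counts permutations of
    the expression vector whose maximal statistic reaches the observed one.
    """
    expr = np.asarray(expr, dtype=float).ravel()
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event, dtype=int).ravel()
    if not (0.0 < q_low < q_high < 1.0):
        raise NoCutpointError(f"invalid admissible range [{q_low}, {q_high}]")
    if expr.size < 20 or int(event.sum()) < 5:
        raise InsufficientDataError("optimal cutpoint needs >=20 samples and >=5 events")
    cands = _admissible_thresholds(expr, q_low, q_high)
    if cands.size == 0:
        raise NoCutpointError("no admissible candidate threshold")
    groups = expr[None, :] > cands[:, None]
    chi2, _ = _logrank_scan(time, event, groups)
    best = int(np.argmax(chi2))
    stat = float(chi2[best])
    threshold = float(cands[best])
    high = groups[best]
    p_naive = float(sps.chi2.sf(stat, 1)) if stat > 0 else 1.0
    p_perm = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        b = 0
        for _ in range(n_perm):
            perm_expr = rng.permutation(expr)
            pc = _admissible_thresholds(perm_expr, q_low, q_high)
            pg = perm_expr[None, :] > pc[:, None]
            pchi, _ = _logrank_scan(time, event, pg)
            if pchi.max() >= stat - 1e-12:
                b += 1
        p_perm = (b + 1) / (n_perm + 1)
    return CutpointResult(
        threshold=threshold,
        statistic=stat,
        p_naive=min(p_naive, 1.0),
        p_permutation=p_perm,
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        details={"n_candidates": int(cands.size)},
    )


def _direction(time, event, high: np.ndarray) -> str:
    """'favorable' if the high-expression group fares better.

    Primary criterion: KM median survival difference (high - low); when a
    median is undefined (curve never crosses 0.5) falls back to the sign of
    the high group's observed-minus-expected event count.
    """
    km_high = km_estimate(time[high], event[high]) if event[high].sum() else None
    km_low = km_estimate(time[~high], event[~high]) if event[~high].sum() else None
    if km_high is not None and km_low is not None:
        mh, ml = km_high.median(), km_low.median()
        if not (np.isnan(mh) or np.isnan(ml)) and mh != ml:
            return "favorable" if mh > ml else "unfavorable"
    _, ome = _logrank_scan(time, event, high[None, :])
    return "favorable" if ome[0] <= 0 else "unfavorable"


def screen_checkpoints(
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    gene_list,
    method: str = "median",
    alpha: float = 0.05,
    q_low: float = 0.1,
    q_high: float = 0.9,
    n_perm: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-gene, per-endpoint prognostic screen of candidate checkpoints.

    ``expr`` is genes x samples; ``survival`` a long table holding one or
    more endpoints.  Returns one row per (gene, endpoint) with the log-rank
    p, a ``significant`` flag at ``p < alpha``, the threshold used and the
    prognostic direction.  Genes absent from the matrix are recorded with
    status 'missing' rather than raising.
    """
    if method not in ("median", "optimal"):
        raise InvalidInputError(f"unknown screening method {method!r}")
    validate_survival(survival)
    rows = []
    for endpoint in sorted(survival["endpoint"].unique()):
        sub = survival[survival["endpoint"] == endpoint]
        shared = [s for s in sub["sample_id"] if s in expr.columns]
        sub = sub.set_index("sample_id").loc[shared]
        time = sub["time"].to_numpy(dtype=float)
        event = sub["event"].to_numpy(dtype=int)
        for gene in gene_list:
            row = {"gene": gene, "endpoint": endpoint, "method": method}
            if gene not in expr.index:
                row.update(status="missing", p=np.nan, significant=False)
                rows.append(row)
                continue
            values = expr.loc[gene, shared].to_numpy(dtype=float)
            try:
                if method == "median":
                    high = split_by_median(values)
                    threshold = float(np.median(values))
                    res = logrank(time[high], event[high], time[~high], event[~high])
                    stat, p = res.statistic, res.p_value
                else:
                    cut = optimal_cutpoint(
                        values, time, event, q_low, q_high, n_perm=n_perm, seed=seed
                    )
                    threshold = cut.threshold
                    high = values > threshold
                    stat, p = cut.statistic, cut.p_naive
                    row["p_permutation"] = cut.p_permutation
                row.update(
                    status="ok",
                    threshold=threshold,
                    statistic=stat,
                    p=p,
                    significant=bool(p < alpha),
                    direction=_direction(time, event, high),
                    n_high=int(high.sum()),
                    n_low=int((~high).sum()),
                )
            except (DegenerateSplitError, InsufficientDataError, NoCutpointError) as exc:
                logger.warning("screen %s/%s failed: %s", gene, endpoint, exc)
                row.update(status="degenerate", p=np.nan, significant=False)
            rows.append(row)
    return pd.DataFrame(rows)
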