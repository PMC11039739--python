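"""Expression-cutoff survival analysis and tumour-volume utilities.

A cohort of (time, event, expression) records is split into high and low
expression groups either at a z-score cutoff (z computed over the whole
cohort) or at an absolute expression value chosen from the distribution
(useful when expression is bimodal).  Group survival is summarised by the
Kaplan-Meier product-limit estimator and compared with the two-group
log-rank test.  Estimation and testing are delegated to lifelines; the
median-survival convention used here is the smallest observed time with
S(t) <= 0.5.  Tumour volumes from calliper measurements use the modified
ellipsoid formula V = a * b^2 / 2 with a >= b.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "KMCurve",
    "LogRankResult",
    "dichotomize_expression",
    "km_estimate",
    "logrank_test",
    "ellipsoid_volume",
]


@dataclass
class KMCurve:
    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk just before each event time
    median: float  # NaN when the curve never reaches 0.5


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def dichotomize_expression(cohort: pd.DataFrame, z_cutoff: float = 1.0,
                           absolute_cutoff: float | None = None) -> pd.DataFrame:
    """Assign high/low groups by expression.

    By default the cohort-wide z-score is used and ``group = high`` iff
    z >= z_cutoff.  Supplying ``absolute_cutoff`` switches to a raw
    expression-value cutoff (the manual-cutoff procedure for bimodal
    distributions).  A resulting empty group is flagged with a warning.
    """
    if "expression" not in cohort.columns:
        raise ValueError("cohort needs an 'expression' column")
    expr = cohort["expression"].astype(float)
    if expr.isna().any():
        raise ValueError("expression missing for some subjects")
    out = cohort.copy()
    if absolute_cutoff is not None:
        high = expr >= absolute_cutoff
    else:
        sd = expr.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            raise ValueError("expression has zero variance; cannot z-score")
        z = (expr - expr.mean()) / sd
        high = z >= z_cutoff
    out["group"] = np.where(high, "high", "low")
    for label in ("high", "low"):
        if (out["group"] == label).sum() == 0:
            warnings.warn(f"group {label!r} is empty after dichotomization")
    return out


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit curve.

    Censored subjects leave the risk set without a survival step; ties
    between events and censorings at the same time are resolved events-first
    (the standard convention).  The median is the smallest observed event
    time with S <= 0.5, NaN if the curve never drops that far.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty cohort")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    event_times = np.unique(times[events])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    # number at risk just before each event time
    at_risk = np.array([(times >= t).sum() for t in event_times])
    below = event_times[surv <= 0.5 + 1e-12]
    median = float(below[0]) if below.size else float("nan")
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk, median=median)


def logrank_test(cohort: pd.DataFrame) -> LogRankResult:
    """Two-group log-rank test on a cohort with columns time, event, group.

    The statistic is the usual observed-minus-expected chi-square with
    hypergeometric variance accumulated over distinct event times, referred
    to a chi-square distribution with 1 degree of freedom.
    """
    for col in ("time", "event", "group"):
        if col not in cohort.columns:
            raise ValueError(f"cohort needs a {col!r} column")
    labels = cohort["group"].unique()
    if len(labels) != 2:
        raise ValueError(f"log-rank test needs exactly 2 groups, got {len(labels)}")
    g0 = cohort[cohort["group"] == labels[0]]
    g1 = cohort[cohort["group"] == labels[1]]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("both groups must be non-empty")
    if not cohort["event"].astype(bool).any():
        raise ValueError("no events in the cohort")
    res = _ll_logrank(g0["time"], g1["time"],
                      event_observed_A=g0["event"].astype(bool),
                      event_observed_B=g1["event"].astype(bool))
    return LogRankResult(statistic=float(res.test_statistic), df=1,
                         p_value=float(res.p_value))


def ellipsoid_volume(a: float, b: float) -> float:
    """Modified ellipsoid tumour volume V = a * b^2 / 2 (a = length >= b = width).

    Swapped inputs are reordered with a warning; non-positive measurements
    raise.
    """
    if a <= 0 or b <= 0:
        raise ValueError("measurements must be positive")
    if b > a:
        warnings.warn("length < width: swapping to enforce a >= b")
        a, b = b, a
    return a * b * b / 2.0
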