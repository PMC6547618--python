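"""Percentile-group survival: Kaplan-Meier estimation and the log-rank test.

Subjects are ranked by an expression value; the bottom ``low_pct`` and top
``high_pct`` fractions form the two groups compared by the product-limit
estimator and the two-group log-rank test (asymptotic chi-square, df = 1).
When an event and a censoring share a time, the event is counted first, so
the censored subject still sits in that time's risk set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank

__all__ = [
    "assign_percentile_groups",
    "km_estimate",
    "logrank_test",
    "LogrankResult",
    "compare_groups",
]


def assign_percentile_groups(
    cohort: pd.DataFrame,
    low_pct: float = 0.10,
    high_pct: float = 0.10,
    expression_col: str = "expression",
) -> pd.DataFrame:
    """Label the bottom/top expression percentiles as "low"/"high".

    The bottom ``floor(low_pct * n)`` subjects by expression become the low
    group, the top ``floor(high_pct * n)`` the high group, everyone else is
    excluded.  Ties at a boundary are broken by stable input order, so the
    grouping is deterministic.
    """
    if not (0.0 < low_pct and 0.0 < high_pct and low_pct + high_pct <= 1.0):
        raise ValueError("percentiles must be positive with low + high <= 1")
    n = len(cohort)
    n_low = int(np.floor(low_pct * n))
    n_high = int(np.floor(high_pct * n))
    if n_low == 0 or n_high == 0:
        raise ValueError("percentile group of size 0; cohort too small")
    order = np.argsort(cohort[expression_col].to_numpy(), kind="stable")
    group = np.array(["excluded"] * n, dtype=object)
    group[order[:n_low]] = "low"
    group[order[n - n_high :]] = "high"
    out = cohort.copy()
    out["group"] = group
    return out


def km_estimate(times: Sequence[float], events: Sequence[int]) -> pd.DataFrame:
    """Product-limit survival curve with Greenwood standard errors.

    Returns one row per distinct event time t with columns n_at_risk,
    n_events, survival S(t) = prod_{t_i <= t} (1 - d_i / n_i), and the
    Greenwood SE sqrt(S^2 * sum d_i / (n_i (n_i - d_i))).  Times with only
    censorings shrink the risk set but add no row.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("at least one subject required")
    if (times < 0).any():
        raise ValueError("negative follow-up time")

    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    rows = []
    surv = 1.0
    greenwood = 0.0
    n_at_risk = times.size
    for t in np.unique(times):
        at_t = times == t
        d = int(events[at_t].sum())
        c = int(at_t.sum() - d)
        if d > 0:
            surv *= 1.0 - d / n_at_risk
            if n_at_risk > d:
                greenwood += d / (n_at_risk * (n_at_risk - d))
                se = surv * np.sqrt(greenwood)
            else:
                se = 0.0  # survival hit zero; variance degenerates
            rows.append((t, n_at_risk, d, surv, se))
        n_at_risk -= d + c
    return pd.DataFrame(
        rows, columns=["time", "n_at_risk", "n_events", "survival", "greenwood_se"]
    )


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p_value: float
    n_low: int
    n_high: int
    events_low: int
    events_high: int


def logrank_test(
    times_low: Sequence[float],
    events_low: Sequence[int],
    times_high: Sequence[float],
    events_high: Sequence[int],
) -> LogrankResult:
    """Two-group log-rank test (asymptotic chi-square with 1 df).

    At each distinct event time the observed events in one group are
    compared with their hypergeometric expectation given the pooled risk
    set; chi^2 = (sum O - sum E)^2 / sum V.
    """
    tl = np.asarray(times_low, dtype=float)
    th = np.asarray(times_high, dtype=float)
    el = np.asarray(events_low, dtype=int)
    eh = np.asarray(events_high, dtype=int)
    if tl.size == 0 or th.size == 0:
        raise ValueError("both groups must be non-empty")
    if el.sum() + eh.sum() == 0:
        raise ValueError("no events observed; log-rank statistic undefined")
    res = _lifelines_logrank(tl, th, event_observed_A=el, event_observed_B=eh)
    return LogrankResult(
        chi_square=float(res.test_statistic),
        p_value=float(res.p_value),
        n_low=int(tl.size),
        n_high=int(th.size),
        events_low=int(el.sum()),
        events_high=int(eh.sum()),
    )


def compare_groups(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, LogrankResult]:
    """KM curves and log-rank comparison of the low vs high percentile groups."""
    if "group" not in cohort.columns:
        raise ValueError("cohort has no group column; run assign_percentile_groups")
    low = cohort[cohort["group"] == "low"]
    high = cohort[cohort["group"] == "high"]
    km_low = km_estimate(low["time"], low["event"])
    km_high = km_estimate(high["time"], high["event"])
    res = logrank_test(low["time"], low["event"], high["time"], high["event"])
    return km_low, km_high, res
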