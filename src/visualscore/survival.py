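"""Progression-to-severity survival analysis.

Kaplan-Meier estimates of the cumulative probability of progression to severe
clinical evolution (Cluster B), on the age axis, stratified by the VISUAL
risk groups (total >= 10 vs < 10), compared with the Mantel-Cox log-rank
test.  Non-progressors are censored at their age at last follow-up.  No
left-truncation for delayed entry at diagnosis is applied; see the methods
note for the implications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .exceptions import EmptyCohortError

GROUP_HIGH = "visual_ge_10"
GROUP_LOW = "visual_lt_10"


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit estimate over the distinct event times of one group.

    Returns a step-function table with columns ``time``, ``at_risk``,
    ``events``, ``censored``, ``survival`` and ``cum_progression``
    (= 1 - survival).  Censoring tied with an event time is handled
    events-before-censoring (the lifelines convention).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise EmptyCohortError("empty group: no samples for the KM estimate")
    if np.any(t <= 0):
        raise ValueError("times must be positive")

    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table.copy()  # indexed by time, includes t=0 row
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "events": table["observed"].to_numpy(dtype=int),
            "censored": table["censored"].to_numpy(dtype=int),
            "survival": surv.reindex(table.index).to_numpy(dtype=float),
        }
    )
    out = out[out["time"] > 0].reset_index(drop=True)
    out["cum_progression"] = 1.0 - out["survival"]
    return out


def km_median_time(times, events) -> float | None:
    """Smallest time with survival <= 0.5; ``None`` if never reached."""
    kmf = KaplanMeierFitter().fit(
        np.asarray(times, dtype=float), event_observed=np.asarray(events, dtype=int)
    )
    med = kmf.median_survival_time_
    return None if np.isinf(med) else float(med)


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    df: int
    p_value: float
    n_events: int
    undefined: bool = False

    def to_dict(self) -> dict:
        return {
            "chi_square": self.chi_square,
            "df": self.df,
            "p_value": self.p_value,
            "n_events": self.n_events,
            "undefined": self.undefined,
        }


def logrank_test(times, events, groups) -> LogrankResult:
    """Mantel-Cox log-rank comparison of two groups' event distributions.

    Sums observed-minus-expected events over the distinct event times with the
    hypergeometric variance; the statistic is chi-square with 1 df.  With no
    events at all the test is undefined and flagged (chi-square NaN, p NaN).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if not (t.size == e.size == g.size):
        raise ValueError("times, events and groups must have the same length")
    uniq = np.unique(g)
    if uniq.size != 2:
        raise ValueError(f"exactly 2 groups required, got {uniq.tolist()}")
    n_events = int(e.sum())
    if n_events == 0:
        return LogrankResult(float("nan"), 1, float("nan"), 0, undefined=True)
    m = g == uniq[0]
    res = _ll_logrank(t[m], t[~m], event_observed_A=e[m], event_observed_B=e[~m])
    return LogrankResult(
        chi_square=float(res.test_statistic),
        df=1,
        p_value=min(float(res.p_value), 1.0),
        n_events=n_events,
    )


def km_by_group(followup: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """KM tables per risk group from a follow-up frame with columns
    ``age_progression_or_censor``, ``event``, ``group``."""
    out = {}
    for name, grp in followup.groupby("group", sort=True):
        out[str(name)] = km_estimate(grp["age_progression_or_censor"], grp["event"])
    return out
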