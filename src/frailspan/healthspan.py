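"""Frailty-threshold healthspan: survival analysis of severe-deficit onset.

Healthspan is defined as the length of life lived with fewer than four
severe (maximum-score) deficits.  The event is the age at the first
assessment with ``n_severe >= threshold``; mice that die without crossing
are censored at death.  Kaplan-Meier estimation and the log-rank test come
from lifelines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .endpoints import quantile_test, summarize_lifespan

__all__ = [
    "compute_healthspan",
    "km_curve",
    "logrank",
    "healthspan_summary",
]

DEFAULT_SEVERE_THRESHOLD = 4


def compute_healthspan(
    fgi_results: pd.DataFrame,
    mice: pd.DataFrame,
    assessments: pd.DataFrame,
    threshold: int = DEFAULT_SEVERE_THRESHOLD,
) -> pd.DataFrame:
    """First-passage time of the severe-deficit count across ``threshold``.

    Returns one row per mouse: mouse_id, event_age_days, event_observed.
    Event age is the assessment age at the first observed crossing (no
    interpolation between weekly visits); censored mice carry their lifespan.
    """
    ages = assessments[["mouse_id", "date", "age_days"]]
    df = fgi_results.merge(ages, on=["mouse_id", "date"]).sort_values(
        ["mouse_id", "age_days"]
    )
    rows = []
    lifespans = mice.set_index("mouse_id")["lifespan_days"]
    for mouse_id, sub in df.groupby("mouse_id", sort=False):
        if len(sub) == 0:
            raise ValueError(f"mouse {mouse_id!r} has no assessments")
        crossed = sub.loc[sub["n_severe"] >= threshold]
        lifespan = float(lifespans[mouse_id])
        if len(crossed):
            event_age = float(crossed["age_days"].iloc[0])
            rows.append((mouse_id, min(event_age, lifespan), True))
        else:
            rows.append((mouse_id, lifespan, False))
    missing = set(lifespans.index) - set(df["mouse_id"])
    if missing:
        raise ValueError(f"mice with no assessments: {sorted(missing)[:3]}")
    return pd.DataFrame(rows, columns=["mouse_id", "event_age_days", "event_observed"])


def km_curve(records: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Kaplan-Meier survival function and median for one group of records."""
    if records["event_observed"].sum() == 0:
        raise ValueError("need at least one observed event for KM estimation")
    kmf = KaplanMeierFitter()
    kmf.fit(records["event_age_days"], records["event_observed"])
    sf = kmf.survival_function_.reset_index()
    sf.columns = ["age_days", "survival"]
    return sf, float(kmf.median_survival_time_)


def logrank(records: pd.DataFrame, groups) -> tuple[float, float]:
    """Log-rank chi-square test across groups; returns (statistic, p_value)."""
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least two groups")
    res = multivariate_logrank_test(
        records["event_age_days"], groups, records["event_observed"]
    )
    return float(res.test_statistic), float(res.p_value)


def healthspan_summary(
    records: pd.DataFrame,
    mice: pd.DataFrame,
    group_by: str | list[str] = "strain",
    q: float = 0.9,
    include_censored: bool = False,
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Quantile summaries of event ages per group plus the q=0.9 quantile test.

    Naive quantiles exclude censored records unless ``include_censored``;
    KM-based medians are available through :func:`km_curve`.
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    df = records.merge(mice[["mouse_id"] + group_by], on="mouse_id")
    used = df if include_censored else df[df["event_observed"]]
    summary = summarize_lifespan(used, group_by=group_by, value_col="event_age_days")
    key = used[group_by[0]] if len(group_by) == 1 else used[group_by].astype(str).agg("|".join, axis=1)
    test = quantile_test(used["event_age_days"], key, q=q)
    return summary, test
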