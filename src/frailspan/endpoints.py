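"""Proportion-of-life-lived endpoints, lifespan statistics, and trajectories.

PLL (proportion of life lived) is current age divided by eventual lifespan;
the binary 95PLL event marks assessments in the last 5% of life (PLL strictly
greater than 0.95).  This module also provides lifespan summary quantiles,
the quantile test of proportions used for "maximum lifespan" (90th
percentile) comparisons, a Brown-Forsythe median-deviation variance test,
life-expectancy correlations for every deficit item, and locally weighted
smoothing of trajectories on the PLL scale with curvature-based inflection
estimation.

All internal ages and durations are in days; 1 month = 30.4375 days when
converting for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .fgi import DeficitCatalog

__all__ = [
    "DAYS_PER_MONTH",
    "label_assessments",
    "summarize_lifespan",
    "quantile_test",
    "median_deviation_variance_test",
    "deficit_le_correlations",
    "pll_trajectory",
    "estimate_inflection",
]

DAYS_PER_MONTH = 30.4375

PLL_EVENT_THRESHOLD = 0.95


def label_assessments(assessments: pd.DataFrame, mice: pd.DataFrame) -> pd.DataFrame:
    """Per-assessment PLL, 95PLL event flag, and remaining life expectancy.

    ``pll = age / lifespan``; ``is_95pll`` is strict (> 0.95);
    ``life_expectancy_days = lifespan - age``.
    """
    merged = assessments[["mouse_id", "date", "age_days"]].merge(
        mice[["mouse_id", "lifespan_days"]], on="mouse_id", how="left"
    )
    if merged["lifespan_days"].isna().any():
        missing = merged.loc[merged["lifespan_days"].isna(), "mouse_id"].iloc[0]
        raise KeyError(f"no lifespan for mouse {missing!r}")
    if (merged["age_days"] > merged["lifespan_days"]).any():
        bad = merged.loc[merged["age_days"] > merged["lifespan_days"]].iloc[0]
        raise ValueError(
            f"assessment age {bad['age_days']} exceeds lifespan for {bad['mouse_id']!r}"
        )
    pll = merged["age_days"] / merged["lifespan_days"]
    return pd.DataFrame(
        {
            "mouse_id": merged["mouse_id"],
            "date": merged["date"],
            "pll": pll,
            "is_95pll": pll > PLL_EVENT_THRESHOLD,
            "life_expectancy_days": merged["lifespan_days"] - merged["age_days"],
        }
    )


def _quantile(values: np.ndarray, q: float) -> float:
    # single pinned convention: linear interpolation, used everywhere
    return float(np.quantile(values, q, method="linear"))


def summarize_lifespan(
    mice: pd.DataFrame,
    group_by: str | list[str] = "strain",
    value_col: str = "lifespan_days",
) -> pd.DataFrame:
    """Median / Q1 / Q3 / 90th-percentile summaries per group (linear quantiles)."""
    if isinstance(group_by, str):
        group_by = [group_by]
    rows = []
    for key, sub in mice.groupby(group_by, observed=True):
        if len(sub) == 0:
            raise ValueError("empty group")
        if not isinstance(key, tuple):
            key = (key,)
        v = sub[value_col].to_numpy(dtype=float)
        rows.append(
            dict(zip(group_by, key))
            | {
                "n": len(v),
                "median": _quantile(v, 0.5),
                "q1": _quantile(v, 0.25),
                "q3": _quantile(v, 0.75),
                "p90": _quantile(v, 0.9),
            }
        )
    return pd.DataFrame(rows)


def quantile_test(values, groups, q: float = 0.9) -> tuple[float, float]:
    """Test of equal proportions above the pooled q-th quantile.

    The pooled q-th quantile (linear interpolation) is the threshold; per
    group the counts strictly above/at-or-below the threshold form a 2 x k
    contingency table.  Tested by chi-square without continuity correction;
    for 2 x 2 tables with any expected cell below 5, Fisher's exact test.

    Returns (statistic, p_value); statistic is NaN on the exact path.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if np.ptp(values) == 0:
        raise ValueError("degenerate input: all values identical")
    threshold = _quantile(values, q)
    table = np.array(
        [
            [(values[groups == g] > threshold).sum(), (values[groups == g] <= threshold).sum()]
            for g in labels
        ]
    )
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if table.shape == (2, 2) and (expected < 5).any():
        _, p = stats.fisher_exact(table)
        return float("nan"), float(p)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def median_deviation_variance_test(values, groups) -> tuple[float, float]:
    """Brown-Forsythe homogeneity-of-variance test.

    One-way ANOVA on absolute deviations from group medians; robust to
    non-normality.  Returns (W statistic, p_value).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in np.unique(groups)]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs at least two values")
    stat, p = stats.levene(*samples, center="median")
    return float(stat), float(p)


def _fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1.0:
        return float("nan"), float("nan")
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    crit = stats.norm.ppf(0.5 + level / 2)
    return float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se))


def deficit_le_correlations(
    assessments: pd.DataFrame,
    labels: pd.DataFrame,
    fgi_results: pd.DataFrame,
    catalog: DeficitCatalog,
) -> pd.DataFrame:
    """Pearson correlation of life expectancy with each item and summary measure.

    One row per deficit item plus fgi_score, n_severe (deficit count), age,
    weight, and temperature, with Fisher-z 95% CIs.  Items with zero variance
    (never observed, or constant) get a blank (NaN) coefficient, mirroring
    how never-seen items are reported.  Sorted by descending |r|.
    """
    df = assessments.merge(labels[["mouse_id", "date", "life_expectancy_days"]],
                           on=["mouse_id", "date"])
    df = df.merge(fgi_results[["mouse_id", "date", "fgi_score", "n_severe"]],
                  on=["mouse_id", "date"])
    if len(df) < 3:
        raise ValueError("need at least 3 matched assessments")
    le = df["life_expectancy_days"].to_numpy(dtype=float)
    measures = (
        ["fgi_score", "n_severe", "age_days", "weight_g", "temp_C"] + catalog.names
    )
    rows = []
    for m in measures:
        x = df[m].to_numpy(dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(le)
        n = int(ok.sum())
        if n < 3 or np.ptp(x[ok]) == 0:
            rows.append({"item": m, "r": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p_value": np.nan, "n": n})
            continue
        r, p = stats.pearsonr(x[ok], le[ok])
        lo, hi = _fisher_ci(r, n)
        rows.append({"item": m, "r": float(r), "ci_low": lo, "ci_high": hi,
                     "p_value": float(p), "n": n})
    out = pd.DataFrame(rows)
    order = out["r"].abs().fillna(-1.0)
    return out.loc[order.sort_values(ascending=False).index].reset_index(drop=True)


# ---------------------------------------------------------------------------
# PLL-scaled trajectories

PLL_GRID_STEP = 0.005
INFLECTION_WINDOW = (0.6, 1.0)
#: lowess span for dense weekly-cohort trajectories (thousands of points);
#: small enough that boundary flattening does not displace the curvature peak
DENSE_TRAJECTORY_SPAN = 0.08


def pll_trajectory(
    values, pll, span: float = 0.3, grid_step: float = PLL_GRID_STEP
) -> pd.DataFrame:
    """Locally weighted (lowess) smoothing of ``values`` against PLL.

    Fit on a fixed PLL grid covering the observed range.  Returns a frame
    with columns ``pll`` and ``smoothed``.
    """
    values = np.asarray(values, dtype=float)
    pll = np.asarray(pll, dtype=float)
    ok = ~np.isnan(values) & ~np.isnan(pll)
    values, pll = values[ok], pll[ok]
    if len(values) < 30:
        raise ValueError("need at least 30 points for trajectory smoothing")
    lo = np.ceil(pll.min() / grid_step) * grid_step
    hi = np.floor(pll.max() / grid_step) * grid_step
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    if span * len(values) < 10:
        raise ValueError("span too small for data density")
    sm = lowess(values, pll, frac=span, xvals=grid)
    if np.isnan(sm).any():
        raise ValueError("smoothing failed on part of the grid; increase span")
    return pd.DataFrame({"pll": grid, "smoothed": sm})


def estimate_inflection(
    curve: pd.DataFrame,
    window: tuple[float, float] = INFLECTION_WINDOW,
    min_curvature: float = 1e-4,
) -> float | None:
    """PLL at maximal upward curvature of a smoothed trajectory.

    Curvature is the centered second difference of the smoothed curve on its
    grid; the estimate is the interior grid point maximizing it within
    ``window``.  Returns None when the maximal curvature is below
    ``min_curvature`` times the curve's value range (e.g. straight lines).
    """
    grid = curve["pll"].to_numpy()
    y = curve["smoothed"].to_numpy()
    mask = (grid >= window[0]) & (grid <= window[1])
    g, v = grid[mask], y[mask]
    if len(g) < 5:
        raise ValueError("too few grid points inside the inflection window")
    d2 = np.diff(v, 2)  # second difference at g[1:-1]
    scale = max(np.ptp(y), np.finfo(float).tiny)
    i = int(np.argmax(d2))
    if d2[i] < min_curvature * scale:
        return None
    return float(g[1 + i])
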