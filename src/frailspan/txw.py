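"""Temperature x weight (TxW) terminal-decline criterion.

TxW is the product of rectal temperature (C) and body weight (g).  The
terminal-decline rule compares the mean TxW in the most recent weeks against
a benchmark mean from roughly three months earlier: a sustained drop of 10%
or more flags imminent terminal decline.

Window bookkeeping (day arithmetic, config-exposed):

* benchmark window: observations in ``(t - 91 d, t - 63 d]`` — the first four
  weeks of a 13-week look-back;
* recent window: observations in ``(t - 21 d, t]`` — up to the last three
  weeks, including the current visit;
* both windows need at least ``min_obs`` (default 2) non-missing TxW values,
  else the status is ``insufficient``;
* ``fail`` when the recent mean is at or below 90% of the benchmark mean
  (inclusive boundary at exactly -10%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TxwParams", "txw", "evaluate_txw", "txw_status_table", "validate_txw"]


@dataclass(frozen=True)
class TxwParams:
    benchmark_start_days: int = 91  # exclusive left edge, days before t
    benchmark_end_days: int = 63  # inclusive right edge
    recent_days: int = 21
    min_obs: int = 2
    drop_threshold_pct: float = -10.0


def txw(weight_g: float, temp_C: float) -> float:
    """Product of weight (g) and temperature (C); missing propagates."""
    if weight_g is None or temp_C is None:
        return float("nan")
    w, t = float(weight_g), float(temp_C)
    if np.isnan(w) or np.isnan(t):
        return float("nan")
    if w <= 0 or t <= 0:
        raise ValueError(f"weight and temperature must be positive, got {w}, {t}")
    return w * t


def evaluate_txw(
    series: pd.DataFrame, current_date, params: TxwParams = TxwParams()
) -> dict:
    """Evaluate the rule for one mouse at one date.

    ``series`` has columns ``date`` and ``txw`` sorted by date (one row per
    visit; missing TxW as NaN).  ``current_date`` must be a date present in
    the series.  Returns a dict with benchmark_mean, recent_mean, pct_change,
    and flag in {"pass", "fail", "insufficient"}.
    """
    dates = pd.to_datetime(series["date"])
    if dates.duplicated().any():
        raise ValueError("duplicate dates in TxW series")
    if not dates.is_monotonic_increasing:
        raise ValueError("TxW series must be sorted by date")
    t = pd.Timestamp(current_date)
    if not (dates == t).any():
        raise ValueError(f"current_date {current_date} not present in series")
    vals = series["txw"].to_numpy(dtype=float)
    delta = (t - dates).dt.days.to_numpy()
    bench_mask = (delta < params.benchmark_start_days) & (delta >= params.benchmark_end_days)
    recent_mask = (delta < params.recent_days) & (delta >= 0)
    bench = vals[bench_mask & ~np.isnan(vals)]
    recent = vals[recent_mask & ~np.isnan(vals)]
    if len(bench) < params.min_obs or len(recent) < params.min_obs:
        return {
            "benchmark_mean": float("nan"),
            "recent_mean": float("nan"),
            "pct_change": float("nan"),
            "flag": "insufficient",
        }
    bm, rm = float(bench.mean()), float(recent.mean())
    pct = 100.0 * (rm - bm) / bm
    return {
        "benchmark_mean": bm,
        "recent_mean": rm,
        "pct_change": pct,
        "flag": "fail" if pct <= params.drop_threshold_pct else "pass",
    }


def txw_status_table(
    assessments: pd.DataFrame, params: TxwParams = TxwParams()
) -> pd.DataFrame:
    """Rule status for every assessment row of every mouse.

    Expects columns mouse_id, date, weight_g, temp_C.  Returns one row per
    assessment: mouse_id, date, benchmark_mean, recent_mean, pct_change, flag.
    """
    out = []
    for mouse_id, sub in assessments.groupby("mouse_id", sort=False):
        sub = sub.sort_values("date")
        dates = pd.to_datetime(sub["date"]).to_numpy()
        with np.errstate(invalid="ignore"):
            vals = sub["weight_g"].to_numpy(dtype=float) * sub["temp_C"].to_numpy(dtype=float)
        day = dates.astype("datetime64[D]").astype(int)
        obs = ~np.isnan(vals)
        for i in range(len(sub)):
            delta = day[i] - day
            bench_mask = (delta < params.benchmark_start_days) & (delta >= params.benchmark_end_days) & obs
            recent_mask = (delta < params.recent_days) & (delta >= 0) & obs
            nb, nr = int(bench_mask.sum()), int(recent_mask.sum())
            if nb < params.min_obs or nr < params.min_obs:
                row = (mouse_id, sub["date"].iloc[i], np.nan, np.nan, np.nan, "insufficient")
            else:
                bm = vals[bench_mask].mean()
                rm = vals[recent_mask].mean()
                pct = 100.0 * (rm - bm) / bm
                flag = "fail" if pct <= params.drop_threshold_pct else "pass"
                row = (mouse_id, sub["date"].iloc[i], bm, rm, pct, flag)
            out.append(row)
    return pd.DataFrame(
        out,
        columns=["mouse_id", "date", "benchmark_mean", "recent_mean", "pct_change", "flag"],
    )


def validate_txw(
    statuses: pd.DataFrame,
    labels: pd.DataFrame,
    mice: pd.DataFrame,
    group_by: str | list[str] = "strain",
) -> pd.DataFrame:
    """PPV/NPV of the rule against the 95PLL label, per group.

    A ``fail`` flag is a positive prediction of being within the last 5% of
    life; ``insufficient`` rows are excluded.  PPV = TP/(TP+FP) and
    NPV = TN/(TN+FN); NaN when a denominator is zero.
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    df = statuses.merge(labels[["mouse_id", "date", "is_95pll"]], on=["mouse_id", "date"])
    if len(df) != len(statuses):
        raise ValueError("some statuses have no matching 95PLL label")
    df = df[df["flag"] != "insufficient"]
    df = df.merge(mice[["mouse_id"] + group_by], on="mouse_id", how="left")
    rows = []
    for key, sub in df.groupby(group_by, observed=True):
        if not isinstance(key, tuple):
            key = (key,)
        pos = sub["flag"] == "fail"
        event = sub["is_95pll"].astype(bool)
        tp = int((pos & event).sum())
        fp = int((pos & ~event).sum())
        tn = int((~pos & ~event).sum())
        fn = int((~pos & event).sum())
        rows.append(
            dict(zip(group_by, key))
            | {
                "tp": tp, "fp": fp, "tn": tn, "fn": fn,
                "ppv": tp / (tp + fp) if tp + fp else float("nan"),
                "npv": tn / (tn + fn) if tn + fn else float("nan"),
            }
        )
    return pd.DataFrame(rows)
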