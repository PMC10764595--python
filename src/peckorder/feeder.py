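"""Precision-feeder log summaries, growth metrics, and organ indices.

The feeder station admits one bird at a time and logs every identified visit
with its duration (s) and feed intake (g). Per-hen behavior metrics are period
means: visits/day, intake/day (g), occupation/day (s), and per-visit intake
and occupation. Growth metrics come from the body-weight series (initial/final
weight, average daily gain) and total feed intake (feed conversion ratio).
Organ index defaults to g organ per kg body weight; a percent mode
(organ/body x 100) is available.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "summarize_feeding",
    "growth_metrics",
    "organ_index",
    "performance_table",
]

EVENT_COLUMNS = ["hen", "date", "start", "duration_s", "intake_g"]


def _validate_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"feeder events missing columns: {missing}")
    if (events["duration_s"] <= 0).any():
        bad = events.index[events["duration_s"] <= 0][0]
        raise ValueError(f"non-positive duration at event {bad}")
    if (events["intake_g"] < 0).any():
        bad = events.index[events["intake_g"] < 0][0]
        raise ValueError(f"negative intake at event {bad}")
    return events


def summarize_feeding(events: pd.DataFrame, period: tuple[int, int],
                      hens=None) -> pd.DataFrame:
    """Per-hen feeding-behavior metrics over a day period (inclusive).

    Hens with zero events get zero per-day metrics and NaN per-visit metrics
    with ``no_events=True`` — undefined, flagged, never silently zero. Events
    dated outside the period are rejected by event index.
    """
    events = _validate_events(events)
    lo, hi = period
    if hi < lo:
        raise ValueError(f"empty period {period}")
    outside = events.index[(events["date"] < lo) | (events["date"] > hi)]
    if len(outside):
        raise ValueError(f"events outside period {period}: ids {list(outside[:5])}")
    n_days = hi - lo + 1
    hens = pd.Index(hens) if hens is not None else pd.Index(sorted(events["hen"].unique()))

    agg = events.groupby("hen").agg(n_visits=("intake_g", "size"),
                                    intake_total=("intake_g", "sum"),
                                    occupation_total=("duration_s", "sum"))
    agg = agg.reindex(hens).fillna({"n_visits": 0, "intake_total": 0.0,
                                    "occupation_total": 0.0})
    out = pd.DataFrame(index=hens)
    out.index.name = "hen"
    out["visits_per_day"] = agg["n_visits"] / n_days
    out["intake_per_day"] = agg["intake_total"] / n_days
    out["occupation_per_day"] = agg["occupation_total"] / n_days
    has = agg["n_visits"] > 0
    out["intake_per_visit"] = np.where(has, agg["intake_total"] / agg["n_visits"].where(has), np.nan)
    out["occupation_per_visit"] = np.where(has, agg["occupation_total"] / agg["n_visits"].where(has), np.nan)
    out["intake_total"] = agg["intake_total"]
    out["no_events"] = ~has
    if out["no_events"].any():
        logger.warning("hens with no feeder events (per-visit metrics undefined): %s",
                       list(out.index[out["no_events"]]))
    return out


def growth_metrics(weights: pd.DataFrame, intake_total: pd.Series | None = None
                   ) -> pd.DataFrame:
    """Initial/final body weight, ADG, and FCR per hen.

    ``weights`` is long format (hen, date, weight_g). ADG = gain / elapsed
    days; FCR = total intake / gain. With fewer than two weight records, or
    non-positive gain, the dependent metrics are NaN and flagged.
    """
    need = {"hen", "date", "weight_g"}
    if not need <= set(weights.columns):
        raise ValueError(f"weights table needs columns {sorted(need)}")
    rows = []
    for hen, w in weights.sort_values("date").groupby("hen"):
        rec = {"hen": hen, "initial_bw": w["weight_g"].iloc[0],
               "final_bw": w["weight_g"].iloc[-1],
               "adg": np.nan, "fcr": np.nan, "flag": ""}
        n_days = w["date"].iloc[-1] - w["date"].iloc[0]
        if len(w) < 2 or n_days <= 0:
            rec["flag"] = "single-weight"
            logger.warning("hen %s: <2 weight records; adg/fcr undefined", hen)
        else:
            gain = rec["final_bw"] - rec["initial_bw"]
            rec["adg"] = gain / n_days
            if intake_total is not None and hen in intake_total.index:
                if gain > 0:
                    rec["fcr"] = intake_total[hen] / gain
                else:
                    rec["flag"] = "non-positive-gain"
                    logger.warning("hen %s: gain %.1f g <= 0; fcr undefined", hen, gain)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("hen")


def organ_index(organ_weight_g: float, body_weight_g: float,
                mode: str = "g_per_kg") -> float:
    """Organ index: g/kg by default, or percent (organ/body x 100)."""
    if body_weight_g <= 0:
        raise ValueError(f"body weight must be positive, got {body_weight_g}")
    if organ_weight_g < 0:
        raise ValueError("organ weight must be nonnegative")
    if mode == "g_per_kg":
        return organ_weight_g / (body_weight_g / 1000.0)
    if mode == "percent":
        return organ_weight_g / body_weight_g * 100.0
    raise ValueError("mode must be 'g_per_kg' or 'percent'")


def performance_table(events: pd.DataFrame, weights: pd.DataFrame,
                      period: tuple[int, int], hens=None) -> pd.DataFrame:
    """Join feeding-behavior and growth metrics into one row per hen."""
    feed = summarize_feeding(events, period, hens=hens)
    growth = growth_metrics(weights, intake_total=feed["intake_total"])
    return feed.join(growth, how="left")
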