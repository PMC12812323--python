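"""Exposure construction: encounter scores -> analysis panel.

Groups scored encounters into 182-day intervals anchored at each patient's
index date, computes per-interval mean MOS (carrying the last observed
interval mean forward across visit-free intervals), the one-interval-lagged
cumulative mean MOS (the mean of all encounter-level scores observed strictly
before the interval's start — never using future information), baseline MOS
tertiles, and counting-process (start, stop, event) rows for survival fitting.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_INTERVAL_DAYS = 182
DEFAULT_MAX_INTERVAL = 7


def assign_intervals(
    days_since_index: pd.Series,
    interval_days: int = DEFAULT_INTERVAL_DAYS,
    max_interval: Optional[int] = DEFAULT_MAX_INTERVAL,
) -> pd.Series:
    """Half-open interval index k = floor(days / interval_days).

    The index-date encounter is interval 0; day ``interval_days`` opens
    interval 1. Encounters past ``max_interval`` are marked -1 (dropped with a
    log entry by callers); encounters before the index date are rejected.
    """
    days = pd.Series(days_since_index).astype(float)
    if (days < 0).any():
        raise ValueError("encounter before index date")
    k = np.floor(days / interval_days).astype(int)
    if max_interval is not None:
        dropped = int((k > max_interval).sum())
        if dropped:
            logger.info("dropping %d encounters past interval %d", dropped, max_interval)
        k = k.where(k <= max_interval, -1)
    return k


def interval_mean_mos(scores: pd.DataFrame, interval_col: str = "interval") -> pd.DataFrame:
    """Arithmetic mean MOS per patient-interval (observed intervals only).

    ``scores`` needs columns patient_id, ``interval_col`` and mos.
    """
    out = (
        scores.groupby(["patient_id", interval_col], as_index=False)["mos"]
        .mean()
        .rename(columns={interval_col: "interval", "mos": "mean_mos"})
    )
    return out.sort_values(["patient_id", "interval"]).reset_index(drop=True)


def lagged_cumulative_mos(
    scores: pd.DataFrame,
    intervals: pd.Series,
    interval_days: int = DEFAULT_INTERVAL_DAYS,
) -> pd.DataFrame:
    """Lagged cumulative mean exposure per patient-interval.

    For interval k >= 1: mean of all encounter-level MOS values dated strictly
    before day ``interval_days * k``; for k = 0 the baseline interval's mean
    (baseline MOS serves as the interval-0 exposure). Intervals with no prior
    encounters (possible after gaps) carry the last available value forward.
    """
    per_interval = interval_mean_mos(scores.assign(interval=intervals))
    rows = []
    for pid, grp in scores.groupby("patient_id", sort=False):
        grp = grp.sort_values("day")
        base = per_interval[(per_interval["patient_id"] == pid) & (per_interval["interval"] == 0)]
        last_value = float(base["mean_mos"].iloc[0]) if len(base) else float(grp["mos"].iloc[0])
        max_k = int(intervals.loc[grp.index].max())
        for k in range(0, max_k + 1):
            if k == 0:
                value = last_value
            else:
                prior = grp[grp["day"] < interval_days * k]["mos"]
                value = float(prior.mean()) if len(prior) else last_value
            rows.append({"patient_id": pid, "interval": k, "cum_mos_lag": value})
            last_value = value
    return pd.DataFrame(rows)


def assign_tertiles(baseline_mos: pd.Series) -> tuple[pd.Series, tuple[float, float]]:
    """Baseline tertile labels T1/T2/T3 at the empirical 33rd/67th percentiles.

    Linear-interpolation percentiles; ties at a cut point fall to the lower
    tertile. A degenerate (constant) distribution yields all T1 with a
    warning.
    """
    values = pd.Series(baseline_mos).astype(float)
    if len(values) < 3:
        raise ValueError("tertile assignment needs at least 3 patients")
    p33, p67 = np.percentile(values, [33, 67])
    if p33 == p67 and values.nunique() == 1:
        warnings.warn("degenerate baseline MOS distribution; assigning all patients to T1",
                      stacklevel=2)
        return pd.Series("T1", index=values.index), (float(p33), float(p67))
    labels = pd.Series(
        np.where(values <= p33, "T1", np.where(values <= p67, "T2", "T3")),
        index=values.index,
    )
    return labels, (float(p33), float(p67))


def build_counting_process(
    follow_up: pd.DataFrame,
    interval_days: int = DEFAULT_INTERVAL_DAYS,
) -> pd.DataFrame:
    """Expand follow-up into (start, stop, event) rows per interval.

    ``follow_up`` needs patient_id, time (days to first event or censoring)
    and event (bool). Rows are [182k, min(182(k+1), T)) with the event flag on
    the terminal row only; an event landing exactly on a bin boundary closes
    the earlier row. Total risk time is conserved.
    """
    if follow_up.empty:
        raise ValueError("empty outcomes table")
    if (follow_up["time"] < 0).any():
        raise ValueError("event before index date")
    rows = []
    for rec in follow_up.itertuples(index=False):
        t = float(rec.time)
        k = 0
        while True:
            start = k * interval_days
            stop = min((k + 1) * interval_days, t)
            terminal = stop >= t
            rows.append({
                "patient_id": rec.patient_id,
                "interval": k,
                "start": float(start),
                "stop": float(stop),
                "event": bool(rec.event) and terminal,
            })
            if terminal:
                break
            k += 1
    return pd.DataFrame(rows)


def person_years(counting_process: pd.DataFrame) -> float:
    """Total at-risk time in years (risk days / 365.25)."""
    return float((counting_process["stop"] - counting_process["start"]).sum()) / 365.25


def build_panel(
    scores: pd.DataFrame,
    outcomes: pd.DataFrame,
    interval_days: int = DEFAULT_INTERVAL_DAYS,
    max_interval: int = DEFAULT_MAX_INTERVAL,
) -> pd.DataFrame:
    """Assemble the per-patient per-interval analysis panel.

    ``scores``: patient_id, day (since index), mos (one row per scored
    encounter). ``outcomes``: patient_id, time (days), event (bool). Returns
    counting-process rows augmented with ``mean_mos`` (LOCF over visit-free
    intervals) and ``cum_mos_lag``.
    """
    scores = scores.sort_values(["patient_id", "day"]).reset_index(drop=True)
    intervals = assign_intervals(scores["day"], interval_days, max_interval)
    keep = intervals >= 0
    scores, intervals = scores[keep], intervals[keep]

    cp = build_counting_process(outcomes, interval_days)
    cp = cp[cp["interval"] <= max_interval].reset_index(drop=True)

    means = interval_mean_mos(scores.assign(interval=intervals))
    panel = cp.merge(means, on=["patient_id", "interval"], how="left")
    panel["mean_mos"] = panel.groupby("patient_id")["mean_mos"].ffill()

    # Lagged cumulative exposure per at-risk row (not per encounter interval):
    # every at-risk interval sees all encounters strictly before its start.
    by_patient = {pid: grp for pid, grp in scores.groupby("patient_id", sort=False)}
    values = []
    last_by_patient: dict = {}
    for row in panel.itertuples(index=False):
        grp = by_patient.get(row.patient_id)
        if grp is None:
            values.append(np.nan)
            continue
        if row.interval == 0:
            value = float(grp[grp["day"] < interval_days]["mos"].mean())
        else:
            prior = grp[grp["day"] < row.start]["mos"]
            value = float(prior.mean()) if len(prior) else last_by_patient[row.patient_id]
        last_by_patient[row.patient_id] = value
        values.append(value)
    panel["cum_mos_lag"] = values
    return panel
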