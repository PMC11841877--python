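"""Accelerometer count preprocessing: wear time, intensity, daily MVPA.

Implements the standard children's cut-point workflow on vertical-axis
counts: 15 s epochs are consolidated to 60 s, non-wear is any run of >= 20
consecutive zero-count minutes, wear minutes are classified as sedentary
(<= 100 counts/min), light (101-2295) or moderate-to-vigorous (> 2295), a
day is valid with >= 8 h (480 min) of wear (not necessarily contiguous),
and a participant is retained with >= 3 valid weekdays plus >= 1 valid
weekend day.  Mean daily MVPA averages MVPA minutes over valid days only.

All functions operate on the tidy count-series DataFrame produced by
:mod:`somprofiler.tracegen` (or loaded from CSV with the same columns).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SEDENTARY_MAX",
    "LIGHT_MAX",
    "NONWEAR_MIN_RUN",
    "MIN_WEAR_MINUTES",
    "DailySummary",
    "aggregate_epochs",
    "detect_nonwear",
    "classify_intensity",
    "summarize_days",
    "participant_valid",
    "mean_daily_mvpa",
    "process_count_series",
]

logger = logging.getLogger(__name__)

SEDENTARY_MAX = 100  # counts/min, inclusive
LIGHT_MAX = 2295  # counts/min, inclusive; above is MVPA
NONWEAR_MIN_RUN = 20  # consecutive zero minutes
MIN_WEAR_MINUTES = 480  # 8 h/day
MIN_VALID_WEEKDAYS = 3
MIN_VALID_WEEKEND_DAYS = 1


@dataclass(frozen=True)
class DailySummary:
    day_index: int
    day_type: str
    wear_minutes: int
    sedentary_minutes: int
    light_minutes: int
    mvpa_minutes: int
    valid_day: bool


def aggregate_epochs(series: pd.DataFrame) -> pd.DataFrame:
    """Consolidate a 15 s epoch series into 60 s minutes.

    Each minute's counts are the sum of its four 15 s epochs; trailing
    epochs that do not complete a minute are dropped within each day.
    A series already at 60 s is passed through unchanged with a notice.
    """
    if series.empty:
        return series.copy()
    epoch_seconds = int(series["epoch_seconds"].iloc[0])
    if epoch_seconds == 60:
        logger.info("series already at 60 s epochs; passing through")
        return series.copy()
    if epoch_seconds != 15:
        raise ValueError(f"unsupported epoch length: {epoch_seconds} s")
    out = []
    for (pid, day), grp in series.groupby(
        ["participant_id", "day_index"], sort=True
    ):
        grp = grp.sort_values("epoch_index")
        counts = grp["counts"].to_numpy()
        n_minutes = len(counts) // 4
        counts = counts[: n_minutes * 4].reshape(n_minutes, 4).sum(axis=1)
        out.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "day_index": day,
                    "day_type": grp["day_type"].iloc[0],
                    "epoch_index": np.arange(n_minutes),
                    "minute_of_day": np.arange(n_minutes),
                    "epoch_seconds": 60,
                    "counts": counts,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def _zero_runs(counts: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of zeros as (start, length) pairs."""
    runs = []
    start = None
    for i, c in enumerate(counts):
        if c == 0 and start is None:
            start = i
        elif c != 0 and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(counts) - start))
    return runs


def detect_nonwear(series: pd.DataFrame) -> pd.DataFrame:
    """Flag non-wear minutes on a 60 s series.

    A minute is non-wear iff it belongs to a maximal run of >= 20
    consecutive zero-count minutes.  Runs are evaluated on each
    participant's concatenated minute stream, so a run may span a day
    boundary.  Returns a copy with a boolean ``wear`` column.
    """
    out = series.copy()
    if out.empty:
        out["wear"] = pd.Series(dtype=bool)
        return out
    if int(out["epoch_seconds"].iloc[0]) != 60:
        raise ValueError("detect_nonwear requires 60 s epochs")
    wear = np.ones(len(out), dtype=bool)
    for _, idx in out.groupby("participant_id", sort=False).groups.items():
        ordered = out.loc[idx].sort_values(["day_index", "epoch_index"]).index
        counts = out.loc[ordered, "counts"].to_numpy()
        flags = np.ones(len(counts), dtype=bool)
        for start, length in _zero_runs(counts):
            if length >= NONWEAR_MIN_RUN:
                flags[start : start + length] = False
        wear[out.index.get_indexer(ordered)] = flags
    out["wear"] = wear
    return out


def classify_intensity(series: pd.DataFrame) -> pd.DataFrame:
    """Assign each minute an intensity class.

    Requires the ``wear`` column from :func:`detect_nonwear`.  Non-wear
    minutes are classed ``nonwear`` regardless of counts; wear minutes are
    ``sedentary`` (<= 100), ``light`` (101-2295) or ``mvpa`` (> 2295).
    """
    if "wear" not in series.columns:
        raise ValueError("run detect_nonwear first (missing 'wear' column)")
    out = series.copy()
    counts = out["counts"].to_numpy()
    cls = np.where(
        counts <= SEDENTARY_MAX,
        "sedentary",
        np.where(counts <= LIGHT_MAX, "light", "mvpa"),
    )
    cls = np.where(out["wear"].to_numpy(), cls, "nonwear")
    out["intensity"] = cls
    return out


def summarize_days(annotated: pd.DataFrame) -> list[DailySummary]:
    """Per-day wear and intensity minute totals with the 8 h validity flag."""
    summaries = []
    if annotated.empty:
        return summaries
    for day, grp in annotated.groupby("day_index", sort=True):
        counts = grp["intensity"].value_counts()
        sed = int(counts.get("sedentary", 0))
        light = int(counts.get("light", 0))
        mvpa = int(counts.get("mvpa", 0))
        wear = sed + light + mvpa
        summaries.append(
            DailySummary(
                day_index=int(day),
                day_type=str(grp["day_type"].iloc[0]),
                wear_minutes=wear,
                sedentary_minutes=sed,
                light_minutes=light,
                mvpa_minutes=mvpa,
                valid_day=wear >= MIN_WEAR_MINUTES,
            )
        )
    return summaries


def participant_valid(summaries: list[DailySummary]) -> bool:
    """True iff >= 3 valid weekdays and >= 1 valid weekend day."""
    weekdays = sum(1 for s in summaries if s.valid_day and s.day_type == "weekday")
    weekends = sum(1 for s in summaries if s.valid_day and s.day_type == "weekend")
    return weekdays >= MIN_VALID_WEEKDAYS and weekends >= MIN_VALID_WEEKEND_DAYS


def mean_daily_mvpa(summaries: list[DailySummary]) -> float:
    """Mean MVPA minutes per day over valid days only.

    Raises if the participant does not meet the validity criterion, which
    signals exclusion from the analysis sample.
    """
    if not participant_valid(summaries):
        raise ValueError(
            "participant does not meet the 3-weekday + 1-weekend-day validity rule"
        )
    valid = [s.mvpa_minutes for s in summaries if s.valid_day]
    return float(np.mean(valid))


def process_count_series(series: pd.DataFrame) -> pd.DataFrame:
    """Full per-participant preprocessing: returns a participant table.

    Columns: participant_id, valid (bool), mvpa_min_day (NaN when invalid),
    valid_weekdays, valid_weekend_days.
    """
    records = []
    for pid, grp in series.groupby("participant_id", sort=True):
        minutes = aggregate_epochs(grp)
        annotated = classify_intensity(detect_nonwear(minutes))
        summaries = summarize_days(annotated)
        valid = participant_valid(summaries)
        records.append(
            {
                "participant_id": pid,
                "valid": valid,
                "mvpa_min_day": mean_daily_mvpa(summaries) if valid else np.nan,
                "valid_weekdays": sum(
                    1 for s in summaries if s.valid_day and s.day_type == "weekday"
                ),
                "valid_weekend_days": sum(
                    1 for s in summaries if s.valid_day and s.day_type == "weekend"
                ),
            }
        )
    return pd.DataFrame.from_records(records)
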