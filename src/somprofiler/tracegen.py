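"""Synthetic accelerometer count traces with scripted activity bouts.

Produces epoch-level vertical-axis count series whose downstream intensity
classification is known by construction: each day is a sequence of bouts,
each bout belonging to one cut-point band (sedentary <= 100 counts/min,
light 101-2295, MVPA > 2295), and non-wear is injected as blocks of exact
zeros.  This makes the wear-time, intensity and validity rules testable
minute by minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Bout", "DaySpec", "CountTraceSpec", "generate_count_trace"]

# Counts-per-minute cut-point bands (closed on the right where applicable).
INTENSITY_BANDS: dict[str, tuple[float, float]] = {
    "sedentary": (0.0, 100.0),
    "light": (101.0, 2295.0),
    "mvpa": (2296.0, 20000.0),
}

WEEKDAY = "weekday"
WEEKEND = "weekend"


@dataclass(frozen=True)
class Bout:
    """A contiguous stretch of minutes in one intensity band."""

    intensity: str
    duration_min: int
    counts_per_min: float

    def __post_init__(self) -> None:
        if self.intensity not in INTENSITY_BANDS:
            raise ValueError(f"unknown intensity {self.intensity!r}")
        lo, hi = INTENSITY_BANDS[self.intensity]
        if not lo <= self.counts_per_min <= hi:
            raise ValueError(
                f"{self.counts_per_min} counts/min outside the "
                f"{self.intensity} band [{lo}, {hi}]"
            )
        if self.duration_min < 0:
            raise ValueError("bout duration must be >= 0")


@dataclass(frozen=True)
class DaySpec:
    day_type: str  # weekday | weekend
    bouts: tuple[Bout, ...]

    def __post_init__(self) -> None:
        if self.day_type not in (WEEKDAY, WEEKEND):
            raise ValueError(f"day_type must be weekday/weekend, got {self.day_type!r}")

    @property
    def minutes(self) -> int:
        return sum(b.duration_min for b in self.bouts)


@dataclass
class CountTraceSpec:
    """Recipe for one participant's multi-day count series."""

    participant_id: str
    days: list[DaySpec]
    epoch_seconds: int = 60
    # (start_minute, length) on the concatenated minute stream, zeroed out.
    nonwear_blocks: list[tuple[int, int]] = field(default_factory=list)
    seed: int = 0
    jitter: float = 0.05  # relative sd of per-minute counts around the bout mean

    def __post_init__(self) -> None:
        if self.epoch_seconds not in (15, 60):
            raise ValueError("epoch_seconds must be 15 or 60")
        blocks = sorted(self.nonwear_blocks)
        for (s, l) in blocks:
            if l < 0 or s < 0:
                raise ValueError("nonwear blocks need start >= 0 and length >= 0")
        for (s1, l1), (s2, _) in zip(blocks, blocks[1:]):
            if s1 + l1 > s2:
                raise ValueError(f"overlapping nonwear blocks at minute {s2}")


def generate_count_trace(spec: CountTraceSpec) -> pd.DataFrame:
    """Realize a CountTraceSpec as an epoch-level count series.

    Returns a DataFrame with columns ``participant_id``, ``day_index``,
    ``day_type``, ``epoch_index`` (within day), ``minute_of_day``,
    ``epoch_seconds`` and ``counts``.  Minutes covered by a non-wear block
    are exactly zero; every other minute's counts fall inside its bout's
    declared intensity band.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[pd.DataFrame] = []
    global_minute = 0
    for day_index, day in enumerate(spec.days):
        minute_counts = np.empty(day.minutes, dtype=np.int64)
        pos = 0
        for bout in day.bouts:
            lo, hi = INTENSITY_BANDS[bout.intensity]
            sd = max(spec.jitter * bout.counts_per_min, 0.0)
            draw = rng.normal(bout.counts_per_min, sd, size=bout.duration_min)
            minute_counts[pos : pos + bout.duration_min] = np.clip(
                np.rint(draw), lo, hi
            )
            pos += bout.duration_min
        # Zero out scheduled non-wear minutes that land in this day.
        day_start = global_minute
        for start, length in spec.nonwear_blocks:
            a = max(start, day_start) - day_start
            b = min(start + length, day_start + day.minutes) - day_start
            if b > a:
                minute_counts[a:b] = 0
        if spec.epoch_seconds == 60:
            counts = minute_counts
            minute_of_day = np.arange(day.minutes)
        else:
            # Split each minute into four 15 s epochs preserving the sum.
            counts = np.concatenate(
                [
                    rng.multinomial(c, [0.25] * 4) if c > 0 else np.zeros(4, int)
                    for c in minute_counts
                ]
            ) if day.minutes else np.empty(0, dtype=np.int64)
            minute_of_day = np.repeat(np.arange(day.minutes), 4)
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": spec.participant_id,
                    "day_index": day_index,
                    "day_type": day.day_type,
                    "epoch_index": np.arange(len(counts)),
                    "minute_of_day": minute_of_day,
                    "epoch_seconds": spec.epoch_seconds,
                    "counts": counts,
                }
            )
        )
        global_minute += day.minutes
    if not rows:
        return pd.DataFrame(
            columns=[
                "participant_id",
                "day_index",
                "day_type",
                "epoch_index",
                "minute_of_day",
                "epoch_seconds",
                "counts",
            ]
        )
    return pd.concat(rows, ignore_index=True)
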