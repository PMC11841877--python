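"""Preprocess a scripted accelerometer trace into daily MVPA.

Constructs four days (three weekdays + one weekend day), each with one
45-minute MVPA bout at 3000 counts/min, injects a 25-minute non-wear
block, and runs the full wear-time/intensity/validity chain.  The
participant should come out valid with exactly 45 MVPA min/day: the
non-wear block removes wear time but never touches the MVPA bout.
"""

import somprofiler as sp
from somprofiler import accelerometry as acc
from somprofiler.tracegen import Bout, CountTraceSpec, DaySpec


def make_day(day_type):
    return DaySpec(
        day_type,
        (
            Bout("sedentary", 300, 50.0),
            Bout("mvpa", 45, 3000.0),
            Bout("light", 255, 1000.0),
        ),
    )


spec = CountTraceSpec(
    participant_id="demo",
    days=[make_day("weekday")] * 3 + [make_day("weekend")],
    nonwear_blocks=[(60, 25)],  # minutes 60-84 of day 1 forced to zero
    seed=7,
)
trace = sp.generate_count_trace(spec)
print(f"trace: {len(trace)} one-minute epochs over {len(spec.days)} days")

summary = acc.process_count_series(trace)
print(summary.to_string(index=False))
print("\nmeaning: valid=True because 3 weekdays + 1 weekend day each have")
print(">= 480 wear minutes; mvpa_min_day is the mean over those valid days.")
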