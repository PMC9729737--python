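"""From 1-min wrist-accelerometry epochs to a daily time-use composition.

Builds a synthetic week of epoch data (with one non-wear gap and one
invalid day), then runs non-wear detection, cut-point classification, the
valid-day rule and valid-week averaging.
"""

from timeuse_coda import generate_epoch_series, process_series
from timeuse_coda.accelerometry import process_day

week = [
    dict(day_type="weekday", sleep=480, sb=600, lpa=240, mvpa=120, nonwear=0),
    dict(day_type="weekday", sleep=450, sb=570, lpa=240, mvpa=120, nonwear=60),
    dict(day_type="weekday", sleep=510, sb=590, lpa=230, mvpa=110, nonwear=0),
    dict(day_type="weekday", sleep=480, sb=60, lpa=0, mvpa=0, nonwear=900),  # mostly unworn
    dict(day_type="weekend", sleep=540, sb=560, lpa=230, mvpa=110, nonwear=0),
]
series = generate_epoch_series(week, seed=4, participant_id="EX01")

for i, day in enumerate(series.days):
    rec = process_day(day)
    status = "valid" if rec.valid else "invalid (<10 waking hours worn)"
    print(f"day {i} ({rec.day_type:7s}): {rec.minutes}  -> {status}")

result = process_series(series)
print()
print("valid week:", result.n_valid_weekdays, "weekdays,",
      result.n_valid_weekend_days, "weekend day(s)")
print("average composition (min/day, closed to 1440):",
      {k: round(float(v), 2) for k, v in zip(("sleep", "sb", "lpa", "mvpa"), result.composition)})
# The invalid day is dropped entirely; day 2's 60 min of non-wear is
# redistributed proportionally over the four behaviours by the closure.
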