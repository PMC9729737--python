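"""Epoch-level wrist accelerometry to daily time-use compositions.

Input is a week of 1-min epoch activity values ("g-min": gravity-scaled
acceleration aggregated per minute) plus diary sleep intervals.  The rules
applied here:

* non-wear: maximal runs of >= 60 consecutive epochs at <= 25 g-min;
* waking intensity cut points: SB <= 48 g-min < LPA <= 93 g-min < MVPA
  (epochs at exactly 48 are SB, at exactly 93 LPA, keeping the bands
  disjoint with MVPA strictly > 93);
* label precedence sleep > non-wear > intensity (diary sleep is trusted);
* a day is valid when waking wear time (1440 - sleep - non-wear) >= 600 min;
* a participant is retained with >= 3 valid weekdays and >= 1 valid weekend
  day; behaviour minutes are averaged over valid days only and the four
  behaviour means are closed to 1440, redistributing mean non-wear
  proportionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .composition import DAY_MINUTES, PARTS, closure

EPOCHS_PER_DAY = 1440

NONWEAR_THRESHOLD = 25.0   # g-min; epochs at or below count toward non-wear runs
NONWEAR_MIN_RUN = 60       # minutes
SB_MAX = 48.0              # g-min; waking epochs <= SB_MAX are sedentary
MVPA_MIN = 93.0            # g-min; waking epochs strictly above are MVPA
MIN_WAKING_WEAR = 600      # minutes; valid-day rule (>= 10 waking hours)

LABELS = ("sleep", "nonwear", "sb", "lpa", "mvpa")

DayType = Literal["weekday", "weekend"]


@dataclass
class EpochDay:
    """One recording day: 1440 epoch values plus diary sleep intervals."""

    day_type: DayType
    epochs: np.ndarray
    sleep_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.shape != (EPOCHS_PER_DAY,):
            raise ValueError(f"a day must have exactly {EPOCHS_PER_DAY} epochs")
        if np.any(self.epochs < 0):
            raise ValueError("epoch values must be nonnegative")
        _check_intervals(self.sleep_intervals)


@dataclass
class EpochSeries:
    """A participant-week of epoch days."""

    participant_id: str
    days: list[EpochDay]


@dataclass
class DayRecord:
    """Per-class minutes for one day and its validity flag."""

    minutes: dict[str, int]
    day_type: DayType
    valid: bool


@dataclass
class DailyTimeUse:
    """Average daily composition over valid days, closed to 1440 min."""

    participant_id: str
    composition: np.ndarray  # (4,) minutes in PARTS order, sums to 1440
    n_valid_weekdays: int
    n_valid_weekend_days: int


def _check_intervals(intervals: Sequence[tuple[int, int]]) -> None:
    prev_end = -1
    for start, end in sorted(intervals):
        if not (0 <= start < end <= EPOCHS_PER_DAY):
            raise ValueError(f"interval [{start}, {end}) out of range")
        if start < prev_end:
            raise ValueError("sleep intervals overlap")
        prev_end = end


def detect_nonwear(epochs: Iterable[float]) -> list[tuple[int, int]]:
    """Maximal runs of >= 60 consecutive epochs at <= 25 g-min, as [start, end)."""
    arr = np.asarray(epochs, dtype=float)
    if arr.shape != (EPOCHS_PER_DAY,):
        raise ValueError(f"expected {EPOCHS_PER_DAY} epochs, got {arr.shape}")
    low = arr <= NONWEAR_THRESHOLD
    edges = np.flatnonzero(np.diff(np.concatenate(([0], low.view(np.int8), [0]))))
    runs = edges.reshape(-1, 2)
    return [(int(s), int(e)) for s, e in runs if e - s >= NONWEAR_MIN_RUN]


def classify_epochs(
    epochs: Iterable[float],
    nonwear_intervals: Sequence[tuple[int, int]],
    sleep_intervals: Sequence[tuple[int, int]],
) -> np.ndarray:
    """Label every epoch sleep/nonwear/sb/lpa/mvpa with sleep > nonwear precedence."""
    arr = np.asarray(epochs, dtype=float)
    if arr.shape != (EPOCHS_PER_DAY,):
        raise ValueError(f"expected {EPOCHS_PER_DAY} epochs, got {arr.shape}")
    _check_intervals(sleep_intervals)
    _check_intervals(nonwear_intervals)
    labels = np.where(arr > MVPA_MIN, "mvpa", np.where(arr > SB_MAX, "lpa", "sb"))
    labels = labels.astype("<U7")
    for start, end in nonwear_intervals:
        labels[start:end] = "nonwear"
    for start, end in sleep_intervals:
        labels[start:end] = "sleep"
    return labels


def summarize_day(labels: Iterable[str], day_type: DayType) -> DayRecord:
    """Count minutes per class; valid iff waking wear (1440 - sleep - nonwear) >= 600."""
    arr = np.asarray(labels)
    if arr.shape != (EPOCHS_PER_DAY,):
        raise ValueError(f"expected {EPOCHS_PER_DAY} labels, got {arr.shape}")
    minutes = {lab: int(np.sum(arr == lab)) for lab in LABELS}
    waking_wear = EPOCHS_PER_DAY - minutes["sleep"] - minutes["nonwear"]
    return DayRecord(minutes=minutes, day_type=day_type, valid=waking_wear >= MIN_WAKING_WEAR)


def process_day(day: EpochDay) -> DayRecord:
    labels = classify_epochs(day.epochs, detect_nonwear(day.epochs), day.sleep_intervals)
    return summarize_day(labels, day.day_type)


def average_valid_days(
    day_records: Sequence[DayRecord], participant_id: str = ""
) -> Optional[DailyTimeUse]:
    """Average behaviour minutes over valid days and close to 1440.

    Returns ``None`` (a typed exclusion, not an exception) when the
    valid-week rule — at least 3 valid weekdays and 1 valid weekend day —
    is not met.  Mean non-wear is redistributed proportionally by the
    closure, so participants with any wear gaps still produce a full-day
    composition.
    """
    if not day_records:
        raise ValueError("no day records supplied")
    valid = [r for r in day_records if r.valid]
    n_wd = sum(r.day_type == "weekday" for r in valid)
    n_we = sum(r.day_type == "weekend" for r in valid)
    if n_wd < 3 or n_we < 1:
        return None
    means = np.array([np.mean([r.minutes[p] for r in valid]) for p in PARTS])
    if np.any(means <= 0):
        return None  # degenerate week (a behaviour never observed) cannot be closed
    return DailyTimeUse(
        participant_id=participant_id,
        composition=closure(means, total=DAY_MINUTES),
        n_valid_weekdays=n_wd,
        n_valid_weekend_days=n_we,
    )


def process_series(series: EpochSeries) -> Optional[DailyTimeUse]:
    """Full per-participant pipeline: detect, classify, summarize, average."""
    return average_valid_days([process_day(d) for d in series.days], series.participant_id)


# ---------------------------------------------------------------------------
# CSV schema (matches the synthetic epoch writer)


def series_from_frame(df: pd.DataFrame) -> list[EpochSeries]:
    """Read epoch records (participant_id, day_index, day_type, epoch_index,
    value, in_sleep_interval) into per-participant :class:`EpochSeries`."""
    required = {"participant_id", "day_index", "day_type", "epoch_index", "value", "in_sleep_interval"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"epoch table missing columns: {sorted(missing)}")
    out = []
    for pid, pdf in df.groupby("participant_id", sort=True):
        days = []
        for _, ddf in pdf.groupby("day_index", sort=True):
            ddf = ddf.sort_values("epoch_index")
            epochs = ddf["value"].to_numpy(dtype=float)
            flags = ddf["in_sleep_interval"].to_numpy().astype(bool)
            edges = np.flatnonzero(np.diff(np.concatenate(([0], flags.view(np.int8), [0]))))
            intervals = [(int(s), int(e)) for s, e in edges.reshape(-1, 2)]
            days.append(EpochDay(day_type=str(ddf["day_type"].iloc[0]), epochs=epochs,
                                 sleep_intervals=intervals))
        out.append(EpochSeries(participant_id=str(pid), days=days))
    return out


def compositions_frame(series_list: Iterable[EpochSeries]) -> pd.DataFrame:
    """Per-participant composition table with valid-week accounting.

    Columns: participant_id, sleep_min, sb_min, lpa_min, mvpa_min,
    n_valid_weekday, n_valid_weekend, included.  Excluded participants keep
    NaN compositions so the eligibility stage can count them.
    """
    rows = []
    for series in series_list:
        records = [process_day(d) for d in series.days]
        dtu = average_valid_days(records, series.participant_id)
        valid = [r for r in records if r.valid]
        row = {
            "participant_id": series.participant_id,
            "n_valid_weekday": sum(r.day_type == "weekday" for r in valid),
            "n_valid_weekend": sum(r.day_type == "weekend" for r in valid),
            "included": dtu is not None,
        }
        comp = dtu.composition if dtu is not None else [np.nan] * 4
        row.update({f"{p}_min": c for p, c in zip(PARTS, comp)})
        rows.append(row)
    cols = ["participant_id", "sleep_min", "sb_min", "lpa_min", "mvpa_min",
            "n_valid_weekday", "n_valid_weekend", "included"]
    return pd.DataFrame(rows, columns=cols)
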