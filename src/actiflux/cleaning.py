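"""Three-step cleaning of classified activity epochs.

1. **Non-wear consolidation** — blocks containing at least one hour of
   classified non-wear time are consolidated: up to 5 minutes of
   embedded activity inside such a block is treated as spurious and
   re-classified as non-wear.  Non-wear runs that cannot be grown into
   an hour-long block are considered very steady sedentary behavior and
   re-classified as sitting.
2. **Wake-window restriction** — only epochs inside the diary-reported
   wake interval ``[wake_time, bed_time)`` of the day are retained.
3. **Valid-day rule** — a day is valid when the device was worn (epochs
   inside the wake window not labeled non-wear) for at least 6 hours.

The consolidation rule, precisely: an epoch interval qualifies for
merging when it starts and ends with non-wear, every embedded activity
burst lasts at most the tolerance, the total embedded activity is at
most the tolerance, and the interval's total non-wear content is at
least the window length.  All epochs inside any qualifying interval
become non-wear.  The rule runs once: merge, then re-classify the
remaining short non-wear runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CleanedEpochs, EpochFlag, LabeledEpochs
from .kinds import ActivityKind

__all__ = [
    "DayWindow", "WearSummary", "consolidate_nonwear", "restrict_to_wake_window",
    "summarize_wear", "build_day_windows", "clean_day",
]

VALID_DAY_HOURS = 6.0

_NW = ActivityKind.non_wear.value
_SIT = ActivityKind.sitting.value


@dataclass(frozen=True)
class DayWindow:
    """The diary-derived wake interval of one child-day."""

    child_id: str
    date: object  # datetime.date
    wake_time: pd.Timestamp
    bed_time: pd.Timestamp


@dataclass(frozen=True)
class WearSummary:
    child_id: str
    date: object
    wear_hours: float
    is_valid_day: bool


def _runs(labels: np.ndarray):
    """(start, length, label) for each maximal run of equal labels."""
    if labels.size == 0:
        return []
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [labels.size]])
    return [(int(s), int(e - s), int(labels[s])) for s, e in zip(starts, ends)]


def consolidate_nonwear(
    epochs: LabeledEpochs, window_min: float = 60.0, tolerance_min: float = 5.0
) -> CleanedEpochs:
    """Consolidate non-wear time on a contiguous epoch grid.

    Epoch count and timing never change; every re-classified epoch is
    flagged.  Applying the procedure twice gives the same result as
    applying it once.
    """
    out = CleanedEpochs.from_labeled(epochs) if not isinstance(epochs, CleanedEpochs) \
        else CleanedEpochs(epochs.child_id, epochs.start_time, epochs.labels.copy(),
                           epochs.epoch_s, epochs.flags.copy())
    labels = out.labels
    n = labels.size
    if n == 0:
        return out
    tol = int(round(tolerance_min * 60.0 / out.epoch_s))
    win = int(round(window_min * 60.0 / out.epoch_s))

    # binary wear / non-wear runs: an activity burst is a maximal run of
    # epochs not labeled non-wear, regardless of which activities it mixes
    bruns = _runs((labels == _NW).astype(np.int8))  # label 1 = non-wear
    r = len(bruns)
    # step (a): union of all qualifying merge intervals.  For a fixed
    # starting non-wear run the qualifying intervals are nested, so it is
    # enough to extend greedily to the farthest feasible non-wear run and
    # test the window condition there (non-wear content is monotone).
    mark = np.zeros(n + 1, dtype=np.int32)  # difference array
    for k0, (s0, L0, is_nw0) in enumerate(bruns):
        if not is_nw0:
            continue
        wear_sum = 0
        end = k0  # last non-wear run included
        j = k0 + 1
        while j < r:
            s, L, is_nw = bruns[j]
            if is_nw:
                end = j
            else:
                if L > tol or wear_sum + L > tol:
                    break
                wear_sum += L
            j += 1
        nw_total = sum(L for (_, L, is_nw) in bruns[k0:end + 1] if is_nw)
        if nw_total >= win:
            mark[bruns[k0][0]] += 1
            mark[bruns[end][0] + bruns[end][1]] -= 1
    merged = np.cumsum(mark[:-1]) > 0
    newly_nw = merged & (labels != _NW)
    labels[newly_nw] = _NW
    out.flags[newly_nw] = EpochFlag.reclassified_to_nonwear

    # step (b): remaining short non-wear runs become sedentary (sitting)
    for s, L, lab in _runs(labels):
        if lab == _NW and L < win:
            labels[s:s + L] = _SIT
            out.flags[s:s + L] = EpochFlag.reclassified_to_sedentary
    return out


def restrict_to_wake_window(
    epochs: CleanedEpochs, window: DayWindow | None
) -> CleanedEpochs:
    """Flag epochs outside ``[wake_time, bed_time)``.

    A missing diary day (``window is None``) flags every epoch, which
    renders the day invalid downstream.
    """
    out = CleanedEpochs(epochs.child_id, epochs.start_time, epochs.labels.copy(),
                        epochs.epoch_s, epochs.flags.copy())
    if window is None:
        out.flags[:] = EpochFlag.outside_wake_window
        return out
    starts = out.epoch_starts()
    outside = (starts < pd.Timestamp(window.wake_time)) | (
        starts >= pd.Timestamp(window.bed_time)
    )
    out.flags[np.asarray(outside)] = EpochFlag.outside_wake_window
    return out


def summarize_wear(epochs: CleanedEpochs, date=None) -> WearSummary:
    """Wear duration (retained epochs not labeled non-wear) and the
    6-hour valid-day verdict for one child-date."""
    retained = epochs.retained
    worn = retained & (epochs.labels != _NW)
    wear_hours = float(worn.sum()) * epochs.epoch_s / 3600.0
    if date is None:
        starts = epochs.epoch_starts()
        idx = np.flatnonzero(retained)
        date = (starts[idx[0]] if idx.size else epochs.start_time).date()
    return WearSummary(
        child_id=epochs.child_id,
        date=date,
        wear_hours=wear_hours,
        is_valid_day=wear_hours >= VALID_DAY_HOURS,
    )


def build_day_windows(sleep_reports: pd.DataFrame) -> list[DayWindow]:
    """Turn morning diary rows into per-day wake windows.

    Each diary row of date *d* reports the wake time of *d* and the bed
    time of the previous night; the wake window of day *d* therefore
    pairs *d*'s wake time with the bed time reported the next morning.
    The last study day, which has no next-morning report, uses the
    child's median bed clock-time.
    """
    windows: list[DayWindow] = []
    df = sleep_reports.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.date
    for child, grp in df.groupby("child_id", sort=True):
        grp = grp.sort_values("date").reset_index(drop=True)
        beds = pd.to_datetime(grp["bed_time"])
        # bed clock-time measured on the evening before each report date
        offsets = [
            b - (pd.Timestamp(d) - pd.Timedelta(days=1))
            for b, d in zip(beds, grp["date"])
        ]
        median_offset = pd.Series(offsets).median()
        for i in range(len(grp)):
            date = grp["date"].iloc[i]
            wake = pd.Timestamp(grp["wake_time"].iloc[i])
            if i + 1 < len(grp) and grp["date"].iloc[i + 1] == date + pd.Timedelta(days=1):
                bed = pd.Timestamp(grp["bed_time"].iloc[i + 1])
            else:
                bed = pd.Timestamp(date) + median_offset
            windows.append(DayWindow(str(child), date, wake, bed))
    return windows


def clean_day(
    epochs: LabeledEpochs,
    window: DayWindow | None,
    window_min: float = 60.0,
    tolerance_min: float = 5.0,
) -> tuple[CleanedEpochs, WearSummary]:
    """Run the three cleaning steps for one child-day."""
    cleaned = consolidate_nonwear(epochs, window_min, tolerance_min)
    cleaned = restrict_to_wake_window(cleaned, window)
    summary = summarize_wear(cleaned, date=window.date if window else None)
    return cleaned, summary
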