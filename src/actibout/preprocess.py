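"""Count-series preprocessing: wear detection, wake/sleep split, re-epoching.

Accelerometer data arrive as vector-magnitude activity counts on a uniform
epoch grid (1 s for the main analysis, 60 s for cut-point summaries).
Preprocessing masks non-wear time (diary-reported removals and runs of
consecutive zero counts of at least 180 minutes), labels each epoch wake or
sleep from diary bed/rise times, and computes conventional cut-point
statistics (sedentary: <=100 counts per minute; moderate-to-vigorous:
>2019 cpm) on worn waking minutes.

Masked epochs are treated as unobserved gaps, never as inactivity: any bout
that touches a gap is censored downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "WAKE",
    "SLEEP",
    "UNKNOWN",
    "CountsSeries",
    "DiaryRecord",
    "vector_magnitude",
    "detect_nonwear",
    "split_states",
    "reepoch",
    "cutpoint_summary",
    "read_counts",
    "write_counts",
    "read_diary",
    "write_diary",
    "NONWEAR_MIN_SECONDS",
    "SB_CPM",
    "MVPA_CPM",
]

WAKE, SLEEP, UNKNOWN = 0, 1, 2

NONWEAR_MIN_SECONDS = 180 * 60  # >= 180 min of consecutive zeros is non-wear
SB_CPM = 100.0       # sedentary behaviour: counts per minute <= 100
MVPA_CPM = 2019.0    # moderate-to-vigorous: counts per minute > 2019


@dataclass
class CountsSeries:
    """Uniformly sampled non-negative activity counts with annotations.

    ``counts`` are counts per epoch (vector magnitude).  ``wear`` marks
    observed epochs; ``state`` is WAKE/SLEEP/UNKNOWN per epoch.
    """

    start_time: pd.Timestamp
    epoch: int
    counts: np.ndarray
    wear: np.ndarray = None
    state: np.ndarray = None
    subject_id: str = "subject"

    def __post_init__(self):
        self.start_time = pd.Timestamp(self.start_time)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        n = self.counts.size
        if self.wear is None:
            self.wear = np.ones(n, dtype=bool)
        else:
            self.wear = np.asarray(self.wear, dtype=bool)
        if self.state is None:
            self.state = np.full(n, WAKE, dtype=np.int8)
        else:
            self.state = np.asarray(self.state, dtype=np.int8)
        if not (self.wear.size == n and self.state.size == n):
            raise ValueError("counts, wear and state must have equal length")

    def __len__(self):
        return self.counts.size

    @property
    def duration_s(self) -> int:
        return len(self) * self.epoch

    def times(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(
            np.arange(len(self)) * self.epoch, unit="s"
        )

    def copy(self) -> "CountsSeries":
        return replace(
            self,
            counts=self.counts.copy(),
            wear=self.wear.copy(),
            state=self.state.copy(),
        )


@dataclass
class DiaryRecord:
    """Self-reported bed/rise times per day plus non-wear intervals.

    ``days`` maps a calendar date to ``(bed_time, rise_time)`` timestamps.
    Bed times after midnight are expressed with full timestamps, so no
    midnight-crossing ambiguity remains after parsing.  Intervals are
    half-open ``[start, end)``.
    """

    days: dict = field(default_factory=dict)
    nonwear_intervals: list = field(default_factory=list)

    def __post_init__(self):
        for date, (bed, rise) in list(self.days.items()):
            bed, rise = pd.Timestamp(bed), pd.Timestamp(rise)
            if rise <= bed:
                raise ValueError(
                    f"diary day {date}: rise time {rise} not after bed time {bed}"
                )
            self.days[date] = (bed.round("s"), rise.round("s"))
        ivs = sorted(
            (pd.Timestamp(a).round("s"), pd.Timestamp(b).round("s"))
            for a, b in self.nonwear_intervals
        )
        for (a, b) in ivs:
            if b <= a:
                raise ValueError(f"empty or inverted non-wear interval [{a}, {b})")
        for (_, b), (a2, _) in zip(ivs, ivs[1:]):
            if a2 < b:
                raise ValueError("overlapping non-wear intervals after normalization")
        self.nonwear_intervals = ivs


def vector_magnitude(x, y, z) -> np.ndarray:
    """Element-wise Euclidean norm of three axis-count series."""
    x, y, z = (np.asarray(a, dtype=float) for a in (x, y, z))
    if not (x.shape == y.shape == z.shape):
        raise ValueError("axis series must have equal length")
    if np.any(x < 0) or np.any(y < 0) or np.any(z < 0):
        raise ValueError("axis counts must be non-negative")
    return np.sqrt(x * x + y * y + z * z)


def _zero_runs(counts: np.ndarray):
    """(start, stop) index pairs of maximal runs of exactly-zero counts."""
    iszero = counts == 0
    if not iszero.any():
        return []
    padded = np.concatenate(([False], iszero, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts, stops))


def detect_nonwear(
    series: CountsSeries,
    diary: DiaryRecord | None = None,
    min_duration_s: int = NONWEAR_MIN_SECONDS,
) -> np.ndarray:
    """Wear mask: False where the device was off.

    Non-wear is any run of consecutive zero counts lasting at least
    ``min_duration_s`` (inclusive boundary), plus any diary-reported
    non-wear interval.  Returns a new mask; it does not mutate the series.
    """
    wear = series.wear.copy()
    for start, stop in _zero_runs(series.counts):
        if (stop - start) * series.epoch >= min_duration_s:
            wear[start:stop] = False
    if diary is not None and diary.nonwear_intervals:
        t0 = series.start_time
        n = len(series)
        for a, b in diary.nonwear_intervals:
            i = int(np.ceil((a - t0).total_seconds() / series.epoch))
            j = int(np.ceil((b - t0).total_seconds() / series.epoch))
            i, j = max(i, 0), min(max(j, 0), n)
            if i < j:
                wear[i:j] = False
    return wear


def split_states(
    series: CountsSeries,
    diary: DiaryRecord,
    missing_diary: str = "exclude",
) -> tuple[CountsSeries, dict]:
    """Label epochs wake/sleep from diary bed and rise times.

    Epochs inside any ``[bed_time, rise_time)`` interval are sleep; all
    other epochs on diary-covered days are wake.  Days without a diary
    entry become UNKNOWN state; with ``missing_diary='exclude'`` (default)
    they are additionally masked out of wear so they enter no analysis.

    Returns the annotated series and a sufficiency report with the
    worn-wake to worn-sleep ratio; subjects with ratio > 3 carry the flag
    ``insufficient_sleep`` and should be analysed for wake data only.
    """
    if missing_diary not in ("exclude", "pooled_only"):
        raise ValueError("missing_diary must be 'exclude' or 'pooled_only'")
    out = series.copy()
    times = out.times()
    n = len(out)
    state = np.full(n, UNKNOWN, dtype=np.int8)

    covered_dates = set()
    for date, (bed, rise) in diary.days.items():
        covered_dates.add(pd.Timestamp(date).date())
    dates = times.date
    covered = np.isin(dates, sorted(covered_dates))
    state[covered] = WAKE
    for _, (bed, rise) in diary.days.items():
        in_bed = (times >= bed) & (times < rise)
        state[np.asarray(in_bed)] = SLEEP

    out.state = state
    if missing_diary == "exclude":
        out.wear = out.wear & (state != UNKNOWN)

    worn = out.wear
    wake_s = int(np.sum(worn & (state == WAKE))) * out.epoch
    sleep_s = int(np.sum(worn & (state == SLEEP))) * out.epoch
    ratio = wake_s / sleep_s if sleep_s > 0 else float("inf")
    report = {
        "worn_wake_s": wake_s,
        "worn_sleep_s": sleep_s,
        "wake_sleep_ratio": ratio,
        "insufficient_sleep": bool(ratio > 3),
        "uncovered_days": bool((~covered).any()),
    }
    return out, report


def reepoch(series: CountsSeries, target_epoch: int) -> CountsSeries:
    """Sum counts into non-overlapping windows of ``target_epoch`` seconds.

    Windows align to the series start; a trailing partial window is
    dropped.  A window containing any non-wear epoch is non-wear; a window
    mixing wake and sleep epochs takes the state of its majority (ties ->
    earlier epoch's state).
    """
    if target_epoch % series.epoch != 0:
        raise ValueError(
            f"target epoch {target_epoch} is not a multiple of {series.epoch}"
        )
    k = target_epoch // series.epoch
    if k == 1:
        return series.copy()
    m = len(series) // k
    c = series.counts[: m * k].reshape(m, k)
    w = series.wear[: m * k].reshape(m, k)
    s = series.state[: m * k].reshape(m, k)
    counts = c.sum(axis=1)
    wear = w.all(axis=1)
    state = np.empty(m, dtype=np.int8)
    for val in (WAKE, SLEEP, UNKNOWN):
        state[(s == val).sum(axis=1) * 2 > k] = val
    # exact ties fall back to the first epoch's state
    tie = ~(
        ((s == WAKE).sum(axis=1) * 2 > k)
        | ((s == SLEEP).sum(axis=1) * 2 > k)
        | ((s == UNKNOWN).sum(axis=1) * 2 > k)
    )
    state[tie] = s[tie, 0]
    return CountsSeries(
        start_time=series.start_time,
        epoch=target_epoch,
        counts=counts,
        wear=wear,
        state=state,
        subject_id=series.subject_id,
    )


def cutpoint_summary(series_cpm: CountsSeries) -> dict:
    """Sedentary and MVPA fractions of worn waking minutes, per day and mean.

    Requires 60-s epochs.  SB: counts <= 100 cpm; MVPA: counts > 2019 cpm.
    """
    if series_cpm.epoch != 60:
        raise ValueError("cutpoint_summary requires 60-second epochs")
    sel = series_cpm.wear & (series_cpm.state == WAKE)
    if not sel.any():
        raise ValueError("no worn waking minutes: cut-point summary undefined")
    days = series_cpm.times().date
    rows = []
    for day in pd.unique(days):
        m = sel & (days == day)
        if not m.any():
            continue
        c = series_cpm.counts[m]
        rows.append(
            {
                "date": str(day),
                "minutes": int(m.sum()),
                "sb_fraction": float(np.mean(c <= SB_CPM)),
                "mvpa_fraction": float(np.mean(c > MVPA_CPM)),
            }
        )
    daily = pd.DataFrame(rows)
    return {
        "daily": daily,
        "sb_fraction": float(daily["sb_fraction"].mean()),
        "mvpa_fraction": float(daily["mvpa_fraction"].mean()),
    }


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_counts(path, epoch: int | None = None, subject_id: str | None = None) -> CountsSeries:
    """Read a delimited counts file.

    Header either ``timestamp,axis1,axis2,axis3`` (vector magnitude taken)
    or ``timestamp,vm``.  Timestamps must be uniformly spaced; the epoch is
    inferred unless given.
    """
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "timestamp" not in cols:
        raise ValueError("counts file needs a 'timestamp' column")
    ts = pd.to_datetime(df["timestamp"])
    if len(ts) < 2 and epoch is None:
        raise ValueError("cannot infer epoch from fewer than two rows")
    if epoch is None:
        steps = ts.diff().dropna().dt.total_seconds()
        epoch = int(steps.iloc[0])
        if not np.allclose(steps, epoch):
            raise ValueError("timestamps are not uniformly spaced")
    if {"axis1", "axis2", "axis3"} <= set(cols):
        vm = vector_magnitude(df["axis1"], df["axis2"], df["axis3"])
    elif "vm" in cols:
        vm = np.asarray(df["vm"], dtype=float)
    else:
        raise ValueError("counts file needs axis1..axis3 or vm columns")
    return CountsSeries(
        start_time=ts.iloc[0],
        epoch=epoch,
        counts=vm,
        subject_id=subject_id or "subject",
    )


def write_counts(series: CountsSeries, path) -> None:
    df = pd.DataFrame({"timestamp": series.times(), "vm": series.counts})
    df.to_csv(path, index=False)


def read_diary(path) -> DiaryRecord:
    """Read a diary file: ``date,bed_time,rise_time,nonwear_start,nonwear_end``.

    One row per day; extra rows with only the non-wear columns add further
    non-wear intervals.  Empty cells are permitted.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    days, intervals = {}, []
    for _, row in df.iterrows():
        date = row.get("date", "").strip()
        bed = row.get("bed_time", "").strip()
        rise = row.get("rise_time", "").strip()
        if date and bed and rise:
            days[date] = (pd.Timestamp(bed), pd.Timestamp(rise))
        a = row.get("nonwear_start", "").strip()
        b = row.get("nonwear_end", "").strip()
        if a and b:
            intervals.append((pd.Timestamp(a), pd.Timestamp(b)))
    return DiaryRecord(days=days, nonwear_intervals=intervals)


def write_diary(diary: DiaryRecord, path) -> None:
    rows = []
    ivs = list(diary.nonwear_intervals)
    day_items = sorted(diary.days.items())
    n = max(len(day_items), len(ivs))
    for i in range(n):
        row = {"date": "", "bed_time": "", "rise_time": "",
               "nonwear_start": "", "nonwear_end": ""}
        if i < len(day_items):
            date, (bed, rise) = day_items[i]
            row.update(date=str(date), bed_time=str(bed), rise_time=str(rise))
        if i < len(ivs):
            row.update(nonwear_start=str(ivs[i][0]), nonwear_end=str(ivs[i][1]))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
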