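"""Active-event and inactive-waiting-time extraction from count series.

The activity threshold is data-driven: the mean of a subject's non-zero
worn counts.  Epochs strictly above the threshold are *active*; epochs at
or below it are *inactive* (equality is classified inactive by convention —
the analysis keeps a single fixed rule, configurable via ``strict_above``).
Maximal same-class runs become durations; runs cut short by the recording
boundary, a non-wear gap, or a wake/sleep transition are censored and
excluded, since their true lengths are unobserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import WAKE, SLEEP, CountsSeries

__all__ = [
    "EventSeries",
    "activity_threshold",
    "extract_events",
    "sweep_thresholds",
    "empirical_ccdf",
    "DEFAULT_SWEEP_FACTORS",
]

DEFAULT_SWEEP_FACTORS = (0.5, 0.75, 1.0, 1.25, 1.5)

_STATE_NAMES = {"pooled": None, "wake": WAKE, "sleep": SLEEP}


@dataclass
class EventSeries:
    """Ordered active durations and inactive waiting times, in seconds."""

    active: np.ndarray
    inactive: np.ndarray
    threshold: float
    threshold_factor: float = 1.0
    state: str = "pooled"
    censored_s: float = 0.0

    def __post_init__(self):
        self.active = np.asarray(self.active, dtype=float)
        self.inactive = np.asarray(self.inactive, dtype=float)

    def durations(self, event_type: str) -> np.ndarray:
        if event_type == "active":
            return self.active
        if event_type == "inactive":
            return self.inactive
        raise ValueError(f"unknown event type {event_type!r}")

    @property
    def total_active_s(self) -> float:
        return float(self.active.sum())

    @property
    def total_inactive_s(self) -> float:
        return float(self.inactive.sum())


def _analysis_mask(series: CountsSeries, state: str) -> np.ndarray:
    try:
        code = _STATE_NAMES[state]
    except KeyError:
        raise ValueError(f"state must be one of {sorted(_STATE_NAMES)}") from None
    mask = series.wear.copy()
    if code is None:
        mask &= (series.state == WAKE) | (series.state == SLEEP)
    else:
        mask &= series.state == code
    return mask


def activity_threshold(series: CountsSeries, state: str = "pooled") -> float:
    """Mean of strictly positive counts over worn epochs in the given state."""
    mask = _analysis_mask(series, state) & (series.counts > 0)
    if not mask.any():
        raise ValueError("activity threshold undefined: no non-zero worn counts")
    return float(series.counts[mask].mean())


def _segments(mask: np.ndarray):
    """(start, stop) of maximal True runs."""
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    return zip(np.flatnonzero(diff == 1), np.flatnonzero(diff == -1))


def extract_events(
    series: CountsSeries,
    threshold: float,
    state: str = "pooled",
    threshold_factor: float = 1.0,
    strict_above: bool = True,
) -> EventSeries:
    """Threshold-crossing event extraction with boundary censoring.

    Within each uninterrupted analysis segment (worn, single state for
    state-specific analyses), maximal runs above the threshold give active
    durations and maximal runs at/below give inactive waiting times; the
    first and last run of every segment are censored.
    """
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    mask = _analysis_mask(series, state)
    above = (series.counts > threshold) if strict_above else (series.counts >= threshold)
    active, inactive = [], []
    censored = 0
    epoch = series.epoch
    for start, stop in _segments(mask):
        seg = above[start:stop]
        # run-length encode the segment
        change = np.flatnonzero(np.diff(seg.astype(np.int8))) + 1
        bounds = np.concatenate(([0], change, [seg.size]))
        lengths = np.diff(bounds)
        kinds = seg[bounds[:-1]]
        if lengths.size <= 2:
            censored += seg.size
            continue
        censored += lengths[0] + lengths[-1]
        for length, kind in zip(lengths[1:-1], kinds[1:-1]):
            (active if kind else inactive).append(length * epoch)
    return EventSeries(
        active=np.array(active, dtype=float),
        inactive=np.array(inactive, dtype=float),
        threshold=float(threshold),
        threshold_factor=float(threshold_factor),
        state=state,
        censored_s=float(censored * epoch),
    )


def sweep_thresholds(
    series: CountsSeries,
    factors=DEFAULT_SWEEP_FACTORS,
    state: str = "pooled",
    base_threshold: float | None = None,
) -> list[EventSeries]:
    """One EventSeries per multiplier of the data-driven threshold."""
    if base_threshold is None:
        base_threshold = activity_threshold(series, state)
    out = []
    for f in factors:
        if not f > 0:
            raise ValueError("threshold factors must be positive")
        out.append(
            extract_events(series, f * base_threshold, state=state, threshold_factor=f)
        )
    return out


def empirical_ccdf(durations) -> tuple[np.ndarray, np.ndarray]:
    """Complementary cumulative distribution P(X >= x) at sorted unique x."""
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("empirical_ccdf needs a non-empty sample")
    x = np.unique(d)
    # number of observations >= each unique value
    n_ge = d.size - np.searchsorted(np.sort(d), x, side="left")
    return x, n_ge / d.size
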