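"""Behavioral event detection and event-triggered calcium averages.

Behavior measures (head x position, per-frame step length of a paw) are
min-max normalized to [0, 1] over the session; an event is a change of the
rolling mean by at least ``delta`` (default 0.1) relative to one window
earlier.  A rearward head-position increase marks the animal falling behind
the belt and hitting the back wall; a step-length increase marks a catch-up
stride.  Calcium traces aligned to these events quantify whether transients
co-occur with them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .photometry import PeriEventAverage, ProcessedTrace, peri_event_average

HEAD_POSITION = "head_position"
STEP_LENGTH = "step_length"

DEFAULT_DELTA = 0.1  # normalized units
DEFAULT_WINDOW = 30  # samples (1 s at 30 samples/s)
DEFAULT_REFRACTORY = 2.0  # s, mirrors the calcium min-separation


@dataclass(frozen=True)
class BehavioralEvent:
    t: float
    measure: str  # head_position | step_length
    direction: str  # increase | decrease
    magnitude: float  # |rolling-mean change| in normalized units


def normalize_unit_range(series: np.ndarray) -> np.ndarray:
    """Min-max scale a behavior measure to [0, 1] over the session."""
    series = np.asarray(series, dtype=float)
    lo, hi = np.min(series), np.max(series)
    if hi == lo:
        raise ValueError("constant series has no dynamic range to normalize")
    return (series - lo) / (hi - lo)


def detect_behavior_events(
    series_01: np.ndarray,
    delta: float = DEFAULT_DELTA,
    window: int = DEFAULT_WINDOW,
    refractory: float = DEFAULT_REFRACTORY,
    rate: float = 30.0,
    measure: str = HEAD_POSITION,
    time: np.ndarray | None = None,
) -> list[BehavioralEvent]:
    """Flag significant changes of the rolling mean of a [0, 1] measure.

    The rolling mean rm over ``window`` samples is compared with itself one
    window earlier; samples where |rm(t) − rm(t − window)| >= ``delta`` are
    flagged, and flags within ``refractory`` seconds of an accepted event
    merge into it (the event sits at the first threshold crossing).
    """
    series_01 = np.asarray(series_01, dtype=float)
    n = len(series_01)
    if window >= n:
        raise ValueError(f"window {window} must be shorter than the series ({n})")
    if time is None:
        time = np.arange(n) / rate

    rm = pd.Series(series_01).rolling(window, min_periods=window).mean().to_numpy()
    change = np.full(n, np.nan)
    change[window:] = rm[window:] - rm[:-window]
    flagged = np.flatnonzero(np.abs(change) >= delta)

    events: list[BehavioralEvent] = []
    last_t = -np.inf
    for i in flagged:
        if time[i] - last_t < refractory:
            continue
        events.append(
            BehavioralEvent(
                t=float(time[i]),
                measure=measure,
                direction="increase" if change[i] > 0 else "decrease",
                magnitude=float(abs(change[i])),
            )
        )
        last_t = time[i]
    return events


def event_triggered_average(
    trace: ProcessedTrace,
    events: list[BehavioralEvent],
    half_window: float = 5.0,
) -> PeriEventAverage:
    """Mean calcium trace aligned to behavioral events."""
    if not events:
        raise ValueError("need at least one behavioral event")
    return peri_event_average(trace, [e.t for e in events], half_window)


def events_frame(events: list[BehavioralEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t_s": [e.t for e in events],
            "measure": [e.measure for e in events],
            "direction": [e.direction for e in events],
            "magnitude": [e.magnitude for e in events],
        }
    )


def peri_event_frame(avg: PeriEventAverage) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lag_s": avg.lags,
            "mean_dff": avg.mean_trace,
            "n_events": avg.n_events,
        }
    )
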