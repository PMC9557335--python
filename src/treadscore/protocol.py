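"""Treadmill session structure: labeled epochs with commanded belt speeds.

A standard training session is a stationary-belt baseline, a staircase of
run epochs with stepped speeds (the belt accelerates instantaneously at each
boundary), and a final stationary-belt baseline.  The schedule is the clock
against which pose frames and photometry samples are labeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PRE_OFF = "pre_off"
RUN = "run"
POST_OFF = "post_off"

#: Epoch labels used in pooled photometry statistics.
ON_TIME = "on_time"
OFF_TIME = "off_time"
HOME_CAGE = "home_cage_baseline"

DEFAULT_SPEEDS = (3.0, 6.0, 8.0, 10.0, 12.0)  # m/min
DEFAULT_STEP_DURATION = 60.0  # s per speed
DEFAULT_OFF_DURATION = 30.0  # s belt-off bookends


@dataclass(frozen=True)
class ScheduleEpoch:
    """One contiguous, half-open interval [t_start, t_end) of the session."""

    label: str
    speed: float  # belt speed in m/min; 0 when the belt is off
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.label not in (PRE_OFF, RUN, POST_OFF):
            raise ValueError(f"unknown epoch label {self.label!r}")
        if not self.t_end > self.t_start:
            raise ValueError(
                f"epoch must have positive duration, got [{self.t_start}, {self.t_end})"
            )
        if self.label == RUN and not self.speed > 0:
            raise ValueError("run epochs require speed > 0")
        if self.label != RUN and self.speed != 0:
            raise ValueError("belt-off epochs require speed == 0")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    def contains(self, t: float) -> bool:
        return self.t_start <= t < self.t_end


class SessionSchedule:
    """Ordered, contiguous epochs covering [0, total_duration)."""

    def __init__(self, epochs: Iterable[ScheduleEpoch]):
        epochs = tuple(epochs)
        if not epochs:
            raise ValueError("schedule requires at least one epoch")
        if epochs[0].t_start != 0:
            raise ValueError("first epoch must start at t=0")
        for prev, nxt in zip(epochs, epochs[1:]):
            if nxt.t_start != prev.t_end:
                raise ValueError(
                    f"epochs must be contiguous: gap between {prev.t_end} and {nxt.t_start}"
                )
        run_speeds = [e.speed for e in epochs if e.label == RUN]
        if any(b < a for a, b in zip(run_speeds, run_speeds[1:])):
            raise ValueError("run-epoch speeds must be non-decreasing in time")
        self.epochs = epochs
        self._starts = np.array([e.t_start for e in epochs])

    @property
    def total_duration(self) -> float:
        return self.epochs[-1].t_end

    def epoch_at(self, t: float) -> ScheduleEpoch:
        if not 0 <= t < self.total_duration:
            raise ValueError(
                f"t={t} outside session [0, {self.total_duration})"
            )
        i = int(np.searchsorted(self._starts, t, side="right")) - 1
        return self.epochs[i]

    def label_time(self, t: float) -> tuple[str, float]:
        """Epoch label and commanded speed at time ``t`` (half-open intervals)."""
        e = self.epoch_at(t)
        return e.label, e.speed

    def label_times(self, t: np.ndarray) -> np.ndarray:
        """Vectorized epoch labels; times outside the session get ``''``."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, "", dtype=object)
        inside = (t >= 0) & (t < self.total_duration)
        idx = np.searchsorted(self._starts, t[inside], side="right") - 1
        labels = np.array([e.label for e in self.epochs], dtype=object)
        out[inside] = labels[idx]
        return out

    def acceleration_times(self) -> list[float]:
        """Times at which the commanded speed strictly increases.

        The belt start (0 -> first run speed) is included; callers that only
        want speed switches may drop the first element.
        """
        times = []
        prev_speed = self.epochs[0].speed
        if self.epochs[0].label == RUN:
            times.append(self.epochs[0].t_start)  # belt moving from t=0
        for e in self.epochs[1:]:
            if e.speed > prev_speed:
                times.append(e.t_start)
            prev_speed = e.speed
        return times

    def intervals_by_label(self) -> dict[str, list[tuple[float, float]]]:
        out: dict[str, list[tuple[float, float]]] = {}
        for e in self.epochs:
            out.setdefault(e.label, []).append((e.t_start, e.t_end))
        return out

    def pooled_intervals(self) -> dict[str, list[tuple[float, float]]]:
        """Intervals pooled into the on-time / off-time epochs used for stats.

        Running epochs at all belt speeds pool into ``on_time``; the belt-off
        bookends pool into ``off_time``.
        """
        by_label = self.intervals_by_label()
        return {
            ON_TIME: by_label.get(RUN, []),
            OFF_TIME: by_label.get(PRE_OFF, []) + by_label.get(POST_OFF, []),
        }

    # -- serialization ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": [e.label for e in self.epochs],
                "speed_m_per_min": [e.speed for e in self.epochs],
                "t_start_s": [e.t_start for e in self.epochs],
                "t_end_s": [e.t_end for e in self.epochs],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SessionSchedule":
        df = pd.read_csv(path, comment="#")
        return cls(
            ScheduleEpoch(
                label=row.label,
                speed=float(row.speed_m_per_min),
                t_start=float(row.t_start_s),
                t_end=float(row.t_end_s),
            )
            for row in df.itertuples()
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, SessionSchedule) and self.epochs == other.epochs

    def __repr__(self) -> str:
        return f"SessionSchedule({len(self.epochs)} epochs, {self.total_duration:g} s)"


def build_standard_schedule(
    speeds: Sequence[float] = DEFAULT_SPEEDS,
    step_duration: float = DEFAULT_STEP_DURATION,
    off_duration: float = DEFAULT_OFF_DURATION,
) -> SessionSchedule:
    """Belt-off baseline, one run epoch per speed, belt-off baseline.

    Defaults reproduce the standard session: 30 s off, five 60 s run epochs
    at 3/6/8/10/12 m/min, 30 s off (total 360 s).
    """
    speeds = [float(s) for s in speeds]
    if not speeds:
        raise ValueError("speeds must be non-empty")
    if any(s <= 0 for s in speeds):
        raise ValueError("all speeds must be > 0")
    if any(b <= a for a, b in zip(speeds, speeds[1:])):
        raise ValueError("speeds must be strictly increasing")
    if step_duration <= 0 or off_duration <= 0:
        raise ValueError("durations must be > 0")

    epochs = [ScheduleEpoch(PRE_OFF, 0.0, 0.0, off_duration)]
    t = off_duration
    for s in speeds:
        epochs.append(ScheduleEpoch(RUN, s, t, t + step_duration))
        t += step_duration
    epochs.append(ScheduleEpoch(POST_OFF, 0.0, t, t + off_duration))
    return SessionSchedule(epochs)


def label_time(schedule: SessionSchedule, t: float) -> tuple[str, float]:
    return schedule.label_time(t)


def acceleration_times(schedule: SessionSchedule) -> list[float]:
    return schedule.acceleration_times()
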