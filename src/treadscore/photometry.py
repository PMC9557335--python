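"""Two-channel fiber-photometry processing and calcium-event statistics.

The pipeline transforms raw 465 nm (calcium-dependent) and 405 nm
(isosbestic) fluorescence into a motion-corrected ΔF/F trace and detects
discrete calcium transients:

1. downsample both channels to 30 samples/s (bin means) to match the
   behavioral frame rate;
2. normalize each channel to ΔF/F = (F − B)/B with B a centered rolling
   mean over 125 samples (≈4.2 s), truncated at the trace edges;
3. subtract the 405 ΔF/F from the 465 ΔF/F — movement artifacts and
   background enter both channels and cancel;
4. detect peaks with topographic prominence > 0.02 ΔF/F that are at least
   60 samples (2 s) apart; among closer candidates the higher-prominence
   peak wins (greedy, highest prominence first, earlier time on ties).

Event counts, rates and mean amplitudes are then pooled per session epoch
(on-time = belt moving at any speed; off-time = the stationary-belt
bookends; home-cage baseline = the separate 5-min recording).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator

TARGET_RATE = 30.0  # samples/s after downsampling
BASELINE_WINDOW = 125  # samples in the rolling ΔF baseline
PROMINENCE_MIN = 0.02  # ΔF/F units, strict floor
MIN_SEPARATION = 60  # samples at TARGET_RATE (2 s)


class SignalQualityError(ValueError):
    """Trace unusable (e.g. non-positive rolling baseline)."""


@dataclass
class PeakParams:
    target_rate: float = TARGET_RATE
    baseline_window: int = BASELINE_WINDOW
    prominence_min: float = PROMINENCE_MIN
    min_separation: int = MIN_SEPARATION  # samples at target_rate

    def __post_init__(self) -> None:
        if min(self.target_rate, self.baseline_window, self.prominence_min,
               self.min_separation) <= 0:
            raise ValueError("all peak parameters must be positive")


@dataclass
class RawPhotometry:
    """Raw traces as acquired: time (s), 465/405 channels, optional 560 nm."""

    time: np.ndarray
    f465: np.ndarray
    f405: np.ndarray
    f560: np.ndarray | None = None
    rate: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.f465 = np.asarray(self.f465, dtype=float)
        self.f405 = np.asarray(self.f405, dtype=float)
        if self.f560 is not None:
            self.f560 = np.asarray(self.f560, dtype=float)
        n = len(self.time)
        for name in ("f465", "f405", "f560"):
            ch = getattr(self, name)
            if ch is not None and len(ch) != n:
                raise ValueError(f"channel {name} length != time length")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.rate is None:
            if n < 2:
                raise ValueError("cannot infer rate from < 2 samples")
            self.rate = float(1.0 / np.median(np.diff(self.time)))
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.time) / self.rate

    def to_csv(self, path) -> None:
        cols = {"time_s": self.time, "f465": self.f465, "f405": self.f405}
        if self.f560 is not None:
            cols["f560"] = self.f560
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, rate: float | None = None) -> "RawPhotometry":
        df = pd.read_csv(path, comment="#")
        return cls(
            time=df["time_s"].to_numpy(),
            f465=df["f465"].to_numpy(),
            f405=df["f405"].to_numpy(),
            f560=df["f560"].to_numpy() if "f560" in df else None,
            rate=rate,
        )


@dataclass
class ProcessedTrace:
    """Corrected ΔF/F at the behavioral rate."""

    time: np.ndarray
    dff: np.ndarray
    params: PeakParams

    @property
    def rate(self) -> float:
        return self.params.target_rate


@dataclass(frozen=True)
class CalciumEvent:
    t_peak: float
    amplitude: float  # ΔF/F value at the peak sample
    prominence: float  # topographic prominence
    index: int = -1  # sample index in the processed trace


@dataclass
class EpochStats:
    epoch_label: str
    n_events: int
    duration_min: float
    rate: float  # events/min
    mean_amplitude: float | None  # None when the pool has no events


@dataclass
class PeriEventAverage:
    lags: np.ndarray  # s, symmetric about 0
    mean_trace: np.ndarray
    n_events: int
    n_excluded: int = 0


# ---------------------------------------------------------------------------
# pipeline stages


def downsample(
    values: np.ndarray,
    rate_in: float,
    target_rate: float = TARGET_RATE,
    time: np.ndarray | None = None,
) -> np.ndarray:
    """Downsample by non-overlapping bin means to exactly ``target_rate``.

    Bins are defined on the time axis (width 1/target_rate), so fractional
    rate ratios are handled; ``time`` defaults to a uniform grid at
    ``rate_in``.  Upsampling is refused.
    """
    values = np.asarray(values, dtype=float)
    if rate_in < target_rate:
        raise ValueError(f"cannot upsample: rate_in {rate_in} < target {target_rate}")
    n = len(values)
    if time is None:
        t_rel = np.arange(n) / rate_in
        duration = n / rate_in
    else:
        time = np.asarray(time, dtype=float)
        t_rel = time - time[0]
        duration = t_rel[-1] + 1.0 / rate_in
    n_out = int(np.floor(duration * target_rate))
    bins = np.floor(t_rel * target_rate).astype(np.int64)
    keep = bins < n_out
    counts = np.bincount(bins[keep], minlength=n_out)
    sums = np.bincount(bins[keep], weights=values[keep], minlength=n_out)
    with np.errstate(invalid="ignore"):
        out = sums / counts
    # empty bins (possible with irregular time stamps): fill from neighbours
    if (counts == 0).any():
        good = counts > 0
        out = np.interp(np.arange(n_out), np.flatnonzero(good), out[good])
    return out


def normalize_dff(series: np.ndarray, baseline_window: int = BASELINE_WINDOW) -> np.ndarray:
    """(F − B)/B with B a centered rolling mean over ``baseline_window`` samples.

    Windows shrink at the trace edges.  A non-positive baseline anywhere is a
    signal-quality error (ΔF/F would be undefined).
    """
    series = np.asarray(series, dtype=float)
    if len(series) <= baseline_window:
        raise ValueError(
            f"series length {len(series)} must exceed baseline window {baseline_window}"
        )
    baseline = (
        pd.Series(series)
        .rolling(baseline_window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    if np.any(baseline <= 0):
        raise SignalQualityError("rolling baseline is non-positive; cannot form ΔF/F")
    return (series - baseline) / baseline


def isosbestic_correct(dff465: np.ndarray, dff405: np.ndarray) -> np.ndarray:
    """Subtract the isosbestic ΔF/F from the calcium-dependent ΔF/F."""
    dff465 = np.asarray(dff465, dtype=float)
    dff405 = np.asarray(dff405, dtype=float)
    if dff465.shape != dff405.shape:
        raise ValueError("channel length mismatch")
    return dff465 - dff405


def detect_events(
    dff: np.ndarray,
    params: PeakParams | None = None,
    time: np.ndarray | None = None,
) -> list[CalciumEvent]:
    """Detect calcium transients on a processed ΔF/F trace.

    Candidates are all local maxima with topographic prominence strictly
    greater than ``prominence_min``.  The minimum-separation rule is applied
    greedily: candidates are visited by decreasing prominence (earlier time
    breaks ties) and accepted only if at least ``min_separation`` samples
    from every already-accepted peak.  Events are returned sorted by time.
    """
    params = params or PeakParams()
    dff = np.asarray(dff, dtype=float)
    if time is None:
        time = np.arange(len(dff)) / params.target_rate
    peaks, props = find_peaks(dff, prominence=0)
    prom = props["prominences"]
    keep = prom > params.prominence_min
    peaks, prom = peaks[keep], prom[keep]

    order = np.lexsort((peaks, -prom))
    accepted: list[int] = []
    accepted_prom: list[float] = []
    for k in order:
        p = peaks[k]
        if all(abs(p - a) >= params.min_separation for a in accepted):
            accepted.append(int(p))
            accepted_prom.append(float(prom[k]))
    events = [
        CalciumEvent(
            t_peak=float(time[p]), amplitude=float(dff[p]), prominence=pr, index=p
        )
        for p, pr in zip(accepted, accepted_prom)
    ]
    events.sort(key=lambda e: e.t_peak)
    return events


def process(
    raw: RawPhotometry,
    params: PeakParams | None = None,
    fit_isosbestic_scale: bool = False,
) -> ProcessedTrace:
    """Raw two-channel photometry -> corrected ΔF/F trace at 30 samples/s.

    Each channel is downsampled and ΔF/F-normalized, then the 405 trace is
    subtracted from the 465 trace.  ``fit_isosbestic_scale`` optionally
    least-squares-scales the 405 ΔF/F before subtraction (off by default:
    plain subtraction is the reference behavior).
    """
    params = params or PeakParams()
    d465 = downsample(raw.f465, raw.rate, params.target_rate, time=raw.time)
    d405 = downsample(raw.f405, raw.rate, params.target_rate, time=raw.time)
    dff465 = normalize_dff(d465, params.baseline_window)
    dff405 = normalize_dff(d405, params.baseline_window)
    if fit_isosbestic_scale:
        denom = float(np.dot(dff405, dff405))
        scale = float(np.dot(dff465, dff405)) / denom if denom > 0 else 1.0
        dff405 = scale * dff405
    dff = isosbestic_correct(dff465, dff405)
    t0 = raw.time[0]
    time = t0 + np.arange(len(dff)) / params.target_rate
    return ProcessedTrace(time=time, dff=dff, params=params)


class PhotometryProcessor(BaseEstimator):
    """Stateless sklearn-style transformer wrapping the ΔF/F pipeline.

    ``transform`` maps :class:`RawPhotometry` to :class:`ProcessedTrace`;
    ``detect`` returns the calcium events of a raw or processed trace.
    ``fit`` is a no-op (the pipeline has no learned state) and exists so the
    processor composes with sklearn pipelines and parameter search.
    """

    def __init__(
        self,
        target_rate: float = TARGET_RATE,
        baseline_window: int = BASELINE_WINDOW,
        prominence_min: float = PROMINENCE_MIN,
        min_separation: int = MIN_SEPARATION,
        fit_isosbestic_scale: bool = False,
    ):
        self.target_rate = target_rate
        self.baseline_window = baseline_window
        self.prominence_min = prominence_min
        self.min_separation = min_separation
        self.fit_isosbestic_scale = fit_isosbestic_scale

    @property
    def params_(self) -> PeakParams:
        return PeakParams(
            target_rate=self.target_rate,
            baseline_window=self.baseline_window,
            prominence_min=self.prominence_min,
            min_separation=self.min_separation,
        )

    def fit(self, X=None, y=None) -> "PhotometryProcessor":
        return self

    def transform(self, raw: RawPhotometry) -> ProcessedTrace:
        return process(raw, self.params_, self.fit_isosbestic_scale)

    def detect(self, X: RawPhotometry | ProcessedTrace) -> list[CalciumEvent]:
        trace = self.transform(X) if isinstance(X, RawPhotometry) else X
        return detect_events(trace.dff, self.params_, time=trace.time)


# ---------------------------------------------------------------------------
# epoch statistics and event-triggered averaging


def epoch_stats(
    events: list[CalciumEvent],
    trace: ProcessedTrace,
    intervals: dict[str, list[tuple[float, float]]],
) -> list[EpochStats]:
    """Pooled event count, rate and mean amplitude per epoch label.

    ``intervals`` maps each label to its half-open [t0, t1) windows on the
    trace clock; all windows of a label pool into one statistic.  Empty
    pools report rate 0 and a missing (None) amplitude.
    """
    out = []
    for label, windows in intervals.items():
        total_s = sum(t1 - t0 for t0, t1 in windows)
        if total_s <= 0:
            raise ValueError(f"epoch {label!r} has zero pooled duration")
        pooled = [
            e for e in events if any(t0 <= e.t_peak < t1 for t0, t1 in windows)
        ]
        minutes = total_s / 60.0
        amps = [e.amplitude for e in pooled]
        out.append(
            EpochStats(
                epoch_label=label,
                n_events=len(pooled),
                duration_min=minutes,
                rate=len(pooled) / minutes,
                mean_amplitude=float(np.mean(amps)) if amps else None,
            )
        )
    return out


def epoch_stats_frame(stats: list[EpochStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "epoch_label": [s.epoch_label for s in stats],
            "n_events": [s.n_events for s in stats],
            "duration_min": [s.duration_min for s in stats],
            "rate_per_min": [s.rate for s in stats],
            "mean_amplitude": [s.mean_amplitude for s in stats],
        }
    )


def peri_event_average(
    trace: ProcessedTrace, event_times, half_window: float
) -> PeriEventAverage:
    """Mean of trace windows aligned to ``event_times`` on a common lag grid.

    Windows are ±``half_window`` s around each event, aligned to the nearest
    trace sample; events whose window is not fully inside the trace are
    excluded and counted in ``n_excluded``.
    """
    event_times = np.asarray(list(event_times), dtype=float)
    if event_times.size == 0:
        raise ValueError("need at least one event time")
    rate = trace.rate
    w = int(round(half_window * rate))
    lags = np.arange(-w, w + 1) / rate
    n = len(trace.dff)
    centers = np.rint((event_times - trace.time[0]) * rate).astype(int)
    ok = (centers - w >= 0) & (centers + w < n)
    if not ok.any():
        raise ValueError("no event has a complete window inside the trace")
    windows = np.stack([trace.dff[c - w : c + w + 1] for c in centers[ok]])
    return PeriEventAverage(
        lags=lags,
        mean_trace=windows.mean(axis=0),
        n_events=int(ok.sum()),
        n_excluded=int((~ok).sum()),
    )


def acceleration_triggered_average(
    trace: ProcessedTrace, times, half_window: float = 5.0
) -> PeriEventAverage:
    """Calcium trace averaged around treadmill acceleration times."""
    return peri_event_average(trace, times, half_window)


def events_frame(events: list[CalciumEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t_peak_s": [e.t_peak for e in events],
            "amplitude": [e.amplitude for e in events],
            "prominence": [e.prominence for e in events],
        }
    )
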