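"""Ground-truth-labeled synthetic pose sessions and photometry traces.

The generator emulates the statistical structure the analyses assume, so
every pipeline stage is testable without recordings:

* **Pose.** The head's running-axis (x) position follows an
  Ornstein–Uhlenbeck process whose rearward set point, drift and back-wall
  "catch-up" reset frequency all scale with (1 − skill); lateral (y) jitter
  and per-stride step-length variability scale the same way.  Paw tracks are
  phase-offset stride oscillations riding on the body position, with fixed
  per-paw amplitude biases that widen as skill decreases (driving the paw
  instability component).  Output is in raw pixel coordinates with the box
  geometry attached, so the reader/normalizer path is exercised.
* **Photometry.** Calcium transients are a renewal process (exponential
  intervals plus a 2.5 s dead time, parameterized so the long-run rate
  equals the configured per-epoch rate) of double-exponential kernels
  (GCaMP6f-like, tau_rise 0.1 s / tau_decay 0.6 s) added fractionally to
  the 465 channel only; a shared motion artifact and slow drift enter both
  channels identically so plain isosbestic subtraction cancels them.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .pose import (
    ALL_PARTS,
    HEAD,
    LEFT_FRONT,
    LEFT_HIND,
    PAWS,
    RIGHT_FRONT,
    RIGHT_HIND,
    TAIL_BASE,
    TAIL_TIP,
    BodyPartTrack,
    PoseSession,
)
from .photometry import RawPhotometry
from .protocol import HOME_CAGE, RUN, SessionSchedule, build_standard_schedule

DEFAULT_BOX = (80.0, 560.0, 60.0, 260.0)  # pixels: x_front, x_rear, y_left, y_right


@dataclass
class SyntheticPoseConfig:
    """Skill-dependent pose generator parameters (normalized units)."""

    skill: float = 0.5  # 0 = naive, 1 = expert
    frame_rate: float = 30.0
    rear_drift_rate: float = 0.5  # x/s rearward pull at skill 0
    reset_rate: float = 6.0  # back-wall catch-up events/min at skill 0
    lateral_sd_base: float = 0.12  # extra y SD at skill 0
    lateral_sd_floor: float = 0.03  # expert sessions stay below this
    step_cv_base: float = 0.5  # per-stride length CV at skill 0
    noise_sd: float = 0.003  # tracking jitter, normalized units
    dropout_prob: float = 0.005  # per-frame low-likelihood dropouts
    box: tuple[float, float, float, float] = DEFAULT_BOX
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.skill <= 1:
            raise ValueError("skill must be in [0, 1]")
        for name in ("rear_drift_rate", "reset_rate", "lateral_sd_base",
                     "lateral_sd_floor", "step_cv_base", "noise_sd", "dropout_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SyntheticPhotometryConfig:
    """Transient/artifact model parameters for the two-channel generator."""

    rate_in: float = 120.0  # acquisition samples/s
    event_rate: float | dict = 8.0  # transients/min, scalar or per epoch label
    amp_mean: float | dict = 0.05  # ΔF/F, scalar or per epoch label
    amp_sd: float = 0.01
    amp_min: float = 0.0  # truncation floor for amplitude draws (exclusive)
    tau_rise: float = 0.1  # s
    tau_decay: float = 0.6  # s
    min_spacing: float = 2.5  # s between transient peaks
    artifact_amp: float = 0.05  # shared-channel bump amplitude (fractional)
    artifact_rate: float = 3.0  # bumps/min
    drift_amp: float = 0.02  # slow shared baseline wobble (fractional)
    noise_sd: float = 0.002  # per-channel white noise (fractional)
    edge_margin: float = 1.0  # s; no transient peak closer to the record end
    b465: float = 100.0  # raw baseline fluorescence, arbitrary units
    b405: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_rise <= 0 or self.tau_decay <= self.tau_rise:
            raise ValueError("need 0 < tau_rise < tau_decay")
        rates = (self.event_rate.values() if isinstance(self.event_rate, dict)
                 else [self.event_rate])
        if any(r < 0 for r in rates):
            raise ValueError("event rates must be >= 0")
        if any(r > 0 and 60.0 / r <= self.min_spacing for r in rates):
            raise ValueError("event rate too high for the minimum spacing")


# ---------------------------------------------------------------------------
# transient kernel


def _kernel_peak_offset(tau_rise: float, tau_decay: float) -> float:
    return math.log(tau_decay / tau_rise) * tau_rise * tau_decay / (tau_decay - tau_rise)


def transient_train(
    duration: float,
    event_times,
    amplitudes,
    rate: float = 30.0,
    tau_rise: float = 0.1,
    tau_decay: float = 0.6,
) -> np.ndarray:
    """Clean ΔF/F-space trace: double-exponential transients peaking at
    ``event_times`` with peak heights ``amplitudes`` (no noise, no baseline).
    """
    n = int(round(duration * rate))
    t_star = _kernel_peak_offset(tau_rise, tau_decay)
    norm = math.exp(-t_star / tau_decay) - math.exp(-t_star / tau_rise)
    out = np.zeros(n)
    support = t_star + 8.0 * tau_decay
    for t_ev, amp in zip(np.atleast_1d(event_times), np.atleast_1d(amplitudes)):
        i0 = max(0, int(math.ceil((t_ev - t_star) * rate)))
        i1 = min(n, int(math.floor((t_ev - t_star + support) * rate)) + 1)
        if i0 >= i1:
            continue
        tau = np.arange(i0, i1) / rate - (t_ev - t_star)
        out[i0:i1] += amp * (np.exp(-tau / tau_decay) - np.exp(-tau / tau_rise)) / norm
    return out


def _renewal_times(
    rng: np.random.Generator,
    t0: float,
    t1: float,
    rate_per_min: float,
    min_spacing: float,
    t_earliest: float,
) -> list[float]:
    """Event times on [t0, t1) with exponential-plus-dead-time intervals.

    Mean interval is exactly 60/rate, so the long-run rate matches the
    configured value despite the dead time.
    """
    if rate_per_min <= 0:
        return []
    mean_interval = 60.0 / rate_per_min
    exp_mean = mean_interval - min_spacing
    if exp_mean <= 0:
        raise ValueError(
            f"rate {rate_per_min}/min incompatible with {min_spacing} s spacing"
        )
    times = []
    t = max(t0, t_earliest)
    while True:
        t = t + min_spacing + rng.exponential(exp_mean)
        if t >= t1:
            break
        times.append(t)
    return times


# ---------------------------------------------------------------------------
# pose


_PAW_GEOMETRY = {
    # (x offset behind head, y side offset, stride phase)
    RIGHT_FRONT: (0.06, +0.12, 0.0),
    LEFT_FRONT: (0.06, -0.12, math.pi),
    RIGHT_HIND: (0.22, +0.14, math.pi / 2),
    LEFT_HIND: (0.22, -0.14, 3 * math.pi / 2),
}


def simulate_pose_session(
    cfg: SyntheticPoseConfig, schedule: SessionSchedule | None = None
) -> tuple[PoseSession, dict]:
    """Simulate one tracked session; returns (session, ground truth).

    The session is in raw pixel coordinates (``normalized=False``) with the
    box attached, ready for the reader→filter→normalize→align path.  Ground
    truth carries the skill, the true back-wall catch-up times, and the
    per-paw stride-amplitude biases.
    """
    schedule = schedule or build_standard_schedule()
    rng = np.random.default_rng(cfg.seed)
    fr = cfg.frame_rate
    dt = 1.0 / fr
    n = int(round(schedule.total_duration * fr))
    times = np.arange(n) / fr

    labels = schedule.label_times(times)
    run = labels == RUN
    speeds = np.zeros(n)
    for e in schedule.epochs:
        if e.label == RUN:
            speeds[(times >= e.t_start) & (times < e.t_end)] = e.speed

    naive = 1.0 - cfg.skill

    # --- back-wall catch-up episodes (run epochs only) -------------------
    back_wall_times: list[float] = []
    last = -np.inf
    for t0, t1 in schedule.intervals_by_label().get(RUN, []):
        back_wall_times += _renewal_times(
            rng, t0 + 1.0, t1 - 0.5, cfg.reset_rate * naive, 4.0, last + 4.0
        )
        last = back_wall_times[-1] if back_wall_times else last

    # --- head x: OU with rearward drift and resets -----------------------
    theta_run, theta_off = 1.5, 0.8
    mu_run = 0.15 + 0.35 * naive
    mu_off = 0.45
    sigma_run = 0.04 + 0.06 * naive
    sigma_off = 0.08
    head_x = np.empty(n)
    x = mu_off
    eta = rng.standard_normal(n)
    bw = np.zeros(n, dtype=bool)
    for t_ev in back_wall_times:
        bw[int(round(t_ev * fr))] = True
    for k in range(n):
        if run[k]:
            theta, mu, sigma = theta_run, mu_run, sigma_run
            drift = cfg.rear_drift_rate * naive
        else:
            theta, mu, sigma = theta_off, mu_off, sigma_off
            drift = 0.0
        x += theta * (mu - x) * dt + drift * dt + sigma * math.sqrt(dt) * eta[k]
        # drift is balanced by mean reversion; excursions beyond the back
        # wall are the catch-up events
        if bw[k]:
            x = 0.96  # nose at the back wall ...
        x = min(max(x, 0.02), 0.97)
        head_x[k] = x
        if bw[k]:
            x = mu  # ... then the catch-up lunge back to the set point

    # --- head y: OU with skill-scaled stationary SD ----------------------
    s_y = cfg.lateral_sd_floor / 2.0 + cfg.lateral_sd_base * naive
    a = math.exp(-2.0 * dt)
    head_y = np.empty(n)
    y = 0.5
    eta_y = rng.standard_normal(n)
    for k in range(n):
        y = 0.5 + a * (y - 0.5) + s_y * math.sqrt(1 - a * a) * eta_y[k]
        head_y[k] = min(max(y, 0.02), 0.98)

    # --- paws: stride oscillations on the body frame ---------------------
    freq = np.where(run, 1.2 + 0.22 * speeds, 0.0)  # strides/s
    phase0 = np.concatenate([[0.0], np.cumsum(2 * math.pi * freq[:-1] * dt)])
    amp0 = np.where(run, 0.02 + 0.004 * speeds, 0.0)
    stride_idx = np.floor(phase0 / (2 * math.pi)).astype(int)

    tracks: dict[str, BodyPartTrack] = {}
    paw_bias = {}
    paw_xy = {}
    for paw, (dx_off, dy_off, ph) in _PAW_GEOMETRY.items():
        bias = 1.0 + 0.35 * naive * rng.standard_normal()
        bias = max(bias, 0.3)
        paw_bias[paw] = bias
        n_strides = stride_idx[-1] + 1
        per_stride = 1.0 + cfg.step_cv_base * naive * rng.standard_normal(n_strides)
        per_stride = np.maximum(per_stride, 0.2)
        amp = amp0 * bias * per_stride[stride_idx]
        px = head_x + dx_off + amp * np.sin(phase0 + ph)
        py = head_y + dy_off + 0.3 * amp * np.cos(phase0 + ph)
        paw_xy[paw] = (px, py)

    paw_xy[HEAD] = (head_x, head_y)
    paw_xy[TAIL_BASE] = (np.clip(head_x + 0.30, 0, 1), head_y)
    paw_xy[TAIL_TIP] = (np.clip(head_x + 0.42, 0, 1), head_y)

    # --- jitter, dropouts, pixel conversion ------------------------------
    x_front, x_rear, y_left, y_right = cfg.box
    for part in ALL_PARTS:
        px, py = paw_xy[part]
        px = px + cfg.noise_sd * rng.standard_normal(n)
        py = py + cfg.noise_sd * rng.standard_normal(n)
        lik = np.clip(rng.normal(0.99, 0.004, n), 0.0, 1.0)
        drop = rng.random(n) < cfg.dropout_prob
        if drop.any():
            lik[drop] = rng.uniform(0.1, 0.6, int(drop.sum()))
            px[drop] += rng.normal(0, 0.2, int(drop.sum()))
            py[drop] += rng.normal(0, 0.2, int(drop.sum()))
        px = np.clip(px, 0.0, 1.0)
        py = np.clip(py, 0.0, 1.0)
        tracks[part] = BodyPartTrack(
            part=part,
            x=x_front + px * (x_rear - x_front),
            y=y_left + py * (y_right - y_left),
            likelihood=lik,
        )

    session = PoseSession(
        frame_rate=fr,
        frame_times=times,
        tracks=tracks,
        box=cfg.box,
        normalized=False,
    )
    truth = {
        "skill": cfg.skill,
        "back_wall_times": list(back_wall_times),
        "paw_bias": paw_bias,
    }
    return session, truth


# ---------------------------------------------------------------------------
# photometry


def _per_label(value: float | dict, label: str) -> float:
    if isinstance(value, dict):
        return float(value.get(label, 0.0))
    return float(value)


def simulate_photometry(
    cfg: SyntheticPhotometryConfig,
    schedule: SessionSchedule | None = None,
    duration: float | None = None,
    label: str = HOME_CAGE,
) -> tuple[RawPhotometry, pd.DataFrame]:
    """Simulate a raw two-channel recording; returns (raw, truth table).

    With a ``schedule``, transients are drawn per epoch label at the
    configured rates; without one, a single ``duration``-long recording
    under ``label`` (default home-cage baseline) is produced.  Truth rows:
    t (peak time, s), amplitude (ΔF/F), label.
    """
    if schedule is None and duration is None:
        raise ValueError("provide a schedule or an explicit duration")
    rng = np.random.default_rng(cfg.seed)
    if schedule is not None:
        total = schedule.total_duration
        intervals = [(e.t_start, e.t_end, e.label) for e in schedule.epochs]
    else:
        total = float(duration)
        intervals = [(0.0, total, label)]

    n = int(round(total * cfg.rate_in))
    time = np.arange(n) / cfg.rate_in

    # transient times per epoch, respecting spacing across boundaries
    ev_times: list[float] = []
    ev_amps: list[float] = []
    ev_labels: list[str] = []
    last = -np.inf
    for t0, t1, lab in intervals:
        rate = _per_label(cfg.event_rate, lab)
        amp_mean = _per_label(cfg.amp_mean, lab)
        # a peak truncated by the end of the recording is not a usable
        # ground-truth event; keep full peaks inside the record
        t1_eff = min(t1, total - cfg.edge_margin)
        for t_ev in _renewal_times(rng, t0, t1_eff, rate, cfg.min_spacing,
                                   last + cfg.min_spacing):
            amp = rng.normal(amp_mean, cfg.amp_sd)
            while amp <= max(cfg.amp_min, 0.0):
                amp = rng.normal(amp_mean, cfg.amp_sd)
            ev_times.append(t_ev)
            ev_amps.append(float(amp))
            ev_labels.append(lab)
            last = t_ev

    signal = transient_train(
        total, ev_times, ev_amps, rate=cfg.rate_in,
        tau_rise=cfg.tau_rise, tau_decay=cfg.tau_decay,
    )

    # shared (common-mode) components: motion bumps + slow drift
    common = np.zeros(n)
    n_bumps = rng.poisson(cfg.artifact_rate * total / 60.0)
    for _ in range(n_bumps):
        center = rng.uniform(0, total)
        width = rng.uniform(0.1, 0.4)
        amp = cfg.artifact_amp * rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
        lo = max(0, int((center - 4 * width) * cfg.rate_in))
        hi = min(n, int((center + 4 * width) * cfg.rate_in))
        tt = time[lo:hi] - center
        common[lo:hi] += amp * np.exp(-0.5 * (tt / width) ** 2)
    if cfg.drift_amp > 0:
        common += cfg.drift_amp * np.sin(2 * math.pi * time / 90.0 + rng.uniform(0, 2 * math.pi))

    f465 = cfg.b465 * (1.0 + signal + common + cfg.noise_sd * rng.standard_normal(n))
    f405 = cfg.b405 * (1.0 + common + cfg.noise_sd * rng.standard_normal(n))

    raw = RawPhotometry(time=time, f465=f465, f405=f405, rate=cfg.rate_in)
    truth = pd.DataFrame({"t": ev_times, "amplitude": ev_amps, "label": ev_labels})
    return raw, truth


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortRecord:
    animal: int
    day: int  # 1-based
    skill: float
    pose: PoseSession
    pose_truth: dict
    photometry: RawPhotometry | None
    photometry_truth: pd.DataFrame | None


def _child_seed(seed: int, animal: int, day: int, stream: int) -> int:
    return int((seed * 1000003 + animal * 10007 + day * 101 + stream) % (2**31 - 1))


def simulate_learning_cohort(
    n_animals: int,
    n_days: int,
    skill_curve,
    dms_amplitude_curve=None,
    pose_cfg: SyntheticPoseConfig | None = None,
    phot_cfg: SyntheticPhotometryConfig | None = None,
    schedule: SessionSchedule | None = None,
    include_photometry: bool = True,
    seed: int = 0,
) -> list[CohortRecord]:
    """Paired pose + photometry for ``n_animals`` over ``n_days``.

    ``skill_curve`` gives the true skill per day (monotone non-decreasing);
    ``dms_amplitude_curve`` optionally gives the on-time (run epoch)
    transient amplitude mean per day, with belt-off amplitudes held at the
    base configuration — the pattern of a region whose activity falls as the
    skill is acquired.  Full ground truth is attached to every record.
    """
    skill_curve = np.asarray(list(skill_curve), dtype=float)
    if len(skill_curve) != n_days:
        raise ValueError("skill_curve length must equal n_days")
    if np.any(np.diff(skill_curve) < 0):
        raise ValueError("skill_curve must be monotone non-decreasing")
    schedule = schedule or build_standard_schedule()
    pose_cfg = pose_cfg or SyntheticPoseConfig()
    phot_cfg = phot_cfg or SyntheticPhotometryConfig()
    if dms_amplitude_curve is not None:
        dms_amplitude_curve = np.asarray(list(dms_amplitude_curve), dtype=float)
        if len(dms_amplitude_curve) != n_days:
            raise ValueError("dms_amplitude_curve length must equal n_days")

    records = []
    for animal in range(n_animals):
        for day in range(1, n_days + 1):
            skill = float(np.clip(skill_curve[day - 1], 0.0, 1.0))
            p_cfg = replace(
                pose_cfg, skill=skill, seed=_child_seed(seed, animal, day, 0)
            )
            session, pose_truth = simulate_pose_session(p_cfg, schedule)
            raw = truth = None
            if include_photometry:
                base_amp = (
                    phot_cfg.amp_mean if not isinstance(phot_cfg.amp_mean, dict)
                    else _per_label(phot_cfg.amp_mean, "pre_off")
                )
                amp_mean: float | dict = base_amp
                if dms_amplitude_curve is not None:
                    amp_mean = {
                        "pre_off": base_amp,
                        "post_off": base_amp,
                        RUN: float(dms_amplitude_curve[day - 1]),
                    }
                f_cfg = replace(
                    phot_cfg, amp_mean=amp_mean,
                    seed=_child_seed(seed, animal, day, 1),
                )
                raw, truth = simulate_photometry(f_cfg, schedule)
            records.append(
                CohortRecord(
                    animal=animal, day=day, skill=skill,
                    pose=session, pose_truth=pose_truth,
                    photometry=raw, photometry_truth=truth,
                )
            )
    return records
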