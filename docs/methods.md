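# Methods

## Session protocol model

A session is an ordered list of contiguous, half-open epochs
`[t_start, t_end)` — `pre_off` (belt stationary), one `run` epoch per
commanded speed, `post_off`. The standard schedule is 30 s off, five 60 s
run epochs at 3/6/8/10/12 m/min, 30 s off (360 s total). Half-open
intervals guarantee every time point gets exactly one label, so boundary
frames are never double-counted. Speed transitions are modeled as
instantaneous steps (the hardware's ramp time is far below the 30
samples/s analysis resolution); speeds are commanded values — decoding a
belt encoder is out of scope. "Acceleration times" are all timestamps
where the commanded speed strictly increases, *including* the belt start;
callers wanting only speed switches drop the first element.

## Pose ingestion and normalization

Tracking tables use the DeepLabCut CSV dialect (scorer / bodyparts /
coords header rows; x, y, likelihood per part per frame). Required parts:
head and the four paws; tail points are carried but unused by the score.

Quality control: frames with likelihood below a threshold (default 0.9, a
standard tracking-QC choice) are gap-filled by linear interpolation
between the nearest confident neighbors, with edge gaps held at the
nearest confident value; the interpolated fraction is reported per part.
Coordinates are then normalized within the running-box dimensions —
`x' = (x − x_front)/(x_rear − x_front)`, y analogous — so `x = 0` is the
front wall and `x = 1` the rear wall, making zone indices a direct binning
of x. Out-of-box points are clipped to [0, 1] (with a warning) rather than
dropped, preserving frame alignment with photometry. Normalizing twice is
rejected rather than silently compounded. The default frame rate is 30
frames/s, matching the photometry target rate.

## Coordination score

Components are computed over run-epoch frames only:

- **Zone expectation**: equal-width bins over [0, 1] (last bin closed, so
  `x = 1` lands in the rearmost zone); `E[z] = Σ z·P(z) ∈ [1, n_zones]`.
- **Lateral SD**: *population* SD of head y — the session is a complete
  enumeration, not a sample.
- **Step lengths**: frame-to-frame Euclidean paw displacements;
  displacements below a noise floor (default 0.005 normalized units,
  roughly one pixel of jitter in a typical setup) are excluded as tracking
  noise. **Paw instability** is the mean absolute deviation of the four
  per-paw mean step lengths from their median; the score uses this
  quantity (lower = more stable) rather than the raw step length, which by
  itself confounds speed with skill.

Scoring orients all three components so larger = better (front zones, less
sway, more even paws), percentile-ranks each across the cohort passed in
one call (midrank ties mapped to [0, 100] via `(rank − 1)/(n − 1)·100`),
averages with percentage weights 20 (paw stability) / 40 (zone
expectation) / 40 (lateral SD), and maps the percentile of the weighted
average linearly onto [1, 5]. Consequences worth knowing: an all-tied
cohort scores exactly 3.0; in a two-session cohort a dominating session
scores (5, 1); scores are permutation-invariant and monotone under
componentwise dominance. The percentile reference population is the set of
sessions in the call — the CLI pools all animal-days of a cohort. Scores
are *relative within that pool*, so scores from different pools are not
comparable; `CoordinationScorer.transform` scores new sessions against a
fitted pool by interpolation when a fixed reference is needed. Because the
reference set defines the ranks, adding a session to a pool can in corner
cases reorder two other sessions' weighted averages (rank gaps rescale
non-uniformly per component); only within-pool properties are guaranteed.

## Photometry pipeline

Order of operations: downsample → per-channel ΔF/F → isosbestic
subtraction → peak detection.

- **Downsampling** to 30 samples/s uses non-overlapping bin means on the
  time axis (fractional rate ratios handled; upsampling refused). Bin
  means attenuate a 0.2 Hz component by < 0.1%.
- **ΔF/F** is `(F − B)/B` with `B` a centered 125-sample (≈4.17 s) rolling
  mean, truncated (shrinking window) at the edges. The window length is
  interpreted in samples at the 30 samples/s analysis rate. A non-positive
  baseline anywhere is a signal-quality error. ΔF/F is invariant to any
  positive channel gain, so the whole pipeline is scale-invariant.
- **Isosbestic correction** is plain elementwise subtraction of the 405 nm
  ΔF/F from the 465 nm ΔF/F. Normalizing each channel *before*
  subtraction puts both on the same (unitless) scale, so artifacts that
  enter both channels fractionally cancel. A least-squares scaling of the
  405 channel is available (`fit_isosbestic_scale`) but off by default.
- **Event detection**: candidate peaks are all local maxima with
  topographic prominence (height above the highest saddle toward higher
  ground) strictly greater than 0.02 ΔF/F; the 60-sample (2 s) minimum
  separation is enforced greedily — candidates visited by decreasing
  prominence, earlier time on ties — so a large transient suppresses a
  smaller one riding within its dead time. Event *amplitude* is the ΔF/F
  value at the peak sample and is reported separately from prominence.

Epoch statistics pool all intervals of a label (on-time = all run epochs,
off-time = both belt-off bookends, home-cage baseline = a separate
recording): count, rate = count / pooled minutes, mean amplitude (absent
for an empty pool; rate 0 is reported). Event-triggered averages align
±half-window windows on the nearest sample and exclude (but report)
windows truncated by the trace edge.

## Behavioral events

Behavior measures (head x, per-frame step length of a chosen paw) are
min-max normalized to [0, 1] over the session. The rolling mean over 30
samples (1 s) is compared with itself one window earlier; a change of
≥ 0.1 flags an event at the first crossing, and flags within a 2 s
refractory period merge into it. The window and lag are the package's
choice (the change rule needs both, and 1 s matches the stride timescale);
the refractory period mirrors the calcium event dead time so behavior and
calcium event streams are comparable. A rearward head-position increase is
a "back-wall" (catch-up) event. Peri-event averages are plain aligned
means; no significance statistic is attached.

## Synthetic data generator

**Pose.** Head x follows an Ornstein–Uhlenbeck process whose set point
(0.15 at skill 1 → 0.50 at skill 0 plus a drift-induced shift), rearward
drift (0.5 x/s at skill 0) and volatility scale with (1 − skill); on top,
back-wall catch-up episodes occur as a renewal process (6/min at skill 0,
0 at skill 1): the head touches the back wall and lunges back to the set
point, and these times are ground truth. Head y is OU with stationary SD
`floor/2 + 0.12·(1 − skill)`. Paw tracks are stride oscillations riding on
the head position: frequency 1.2 + 0.22·speed strides/s, amplitude
0.02 + 0.004·speed with a per-stride multiplier of CV `0.5·(1 − skill)`
and a *fixed per-paw bias* of SD `0.35·(1 − skill)` — the bias spread is
what drives paw instability. Tracking jitter (SD 0.003), occasional
low-likelihood dropouts (0.5% of frames), and raw-pixel output with the
box geometry exercise the full QC path. Skill maps linearly to these
parameters; only ordinal claims (better/worse, rising/plateau) are
asserted from it.

**Photometry.** Transients are a renewal process with interval =
2.5 s dead time + Exponential(mean 60/rate − 2.5 s), so the long-run rate
equals the configured per-epoch rate exactly (plain thinning would
undershoot it); rates must stay below 24/min. Each transient is a
double-exponential kernel (tau_rise 0.1 s, tau_decay 0.6 s — a standard
fast-indicator stand-in; no kinetics are fitted anywhere) whose peak
height is Normal(amp_mean 0.05, amp_sd 0.01) truncated positive
(optionally truncated at `amp_min` to study the guaranteed-recovery
regime), added fractionally to the 465 channel only. Transient peaks are
not placed within 1 s of the record end: a transient truncated by the end
of a recording is not a well-defined detection target under a centered
4 s baseline. Motion artifacts (Gaussian bumps, 3/min, width 0.1–0.4 s,
amplitude ±0.05 by default) and a slow sinusoidal drift enter *both*
channels identically in fractional units, matching the correction model;
per-channel white noise (SD 0.002) does not cancel. Acquisition is 120
samples/s by default (an integer multiple of the 30 samples/s analysis
rate, on the order of commercial consoles).

**Cohorts.** `simulate_learning_cohort` pairs pose and photometry per
animal-day, with a monotone skill curve over days and, optionally, a
per-day on-time transient amplitude curve with belt-off amplitudes held
fixed — the pattern of a region whose activity falls as a skill is
acquired. Child seeds are derived deterministically from the master seed,
animal and day, so cohorts are bit-reproducible.

**What passing on synthetic data does and does not show.** The generator
reproduces the *statistical structure* the analyses assume — skill-ordered
components, Poisson-like well-separated transients, fractional
common-mode artifacts — but not real-data failure modes: tracking identity
swaps, photobleaching trends, hemodynamic or spectral crosstalk,
non-fractional artifacts, overlapping transients closer than the dead
time, or gait phases beyond a sinusoid. Passing tests certify the
pipeline's contracts, not the biology.

## Numerical choices and degenerate inputs

- Percentile ties use midranks: deterministic and permutation-invariant.
- Peak suppression ties (equal prominence) resolve to the earlier peak.
- `x = 1.0` falls in the last zone bin (closed right edge).
- Empty step sets give mean step length 0; empty event pools give rate 0
  and a missing mean amplitude; single-frame series give SD 0.
- Constant behavior series cannot be min-max normalized and are rejected.
- A part with no confident frames, a degenerate (zero-extent) box, a
  session wholly outside the schedule window, and a non-positive rolling
  baseline are all hard errors, not warnings.
- Float round-trips: pose CSVs are written with `%.17g` and read with
  pandas' round-trip parser so writer→reader is bit-exact.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data at
session scale: 360 s sessions at 30 frames/s (10,800 frames), photometry
at 120 samples/s, cohorts up to 10 animals × 12 days for skill recovery,
500 random cohorts for the score contract, 200 random traces for the
detector-oracle equivalence, and 50 seeds for transient recovery. The
acceptance script's scored cohort is 100 sessions.

## Known limitations

- The score is cohort-relative; absolute cross-cohort comparisons require
  a fixed reference pool (`CoordinationScorer.transform`).
- No photobleaching detrending; slow trends are absorbed by the rolling
  baseline only up to its ~4 s window.
- Straightness/speed gait metrics, stance/swing segmentation, spike
  inference and any inferential statistics (ANOVA etc.) are out of scope;
  tidy tables are exported for external statistics.
- The behavior-event "significance" is a fixed-threshold rule, not a
  shuffle test; peri-event averages carry no confidence bands.
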