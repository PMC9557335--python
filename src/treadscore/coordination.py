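"""Motor-coordination components and the percentile-weighted 1-5 score.

Three session-level components summarize running coordination:

* **zone expectation** — the box is divided into ``n_zones`` equal-width
  zones along the running (x) axis, zone 1 frontmost and zone ``n_zones``
  rearmost; the expected zone index of the head, E[z] = sum(z * P(z)),
  rises as the animal falls behind the belt.
* **lateral SD** — population standard deviation of the head's normalized
  y position; sideways running inflates it.
* **paw stability** — per-paw mean step length is computed from
  supra-threshold frame-to-frame paw displacements; the mean absolute
  deviation of the four per-paw means from their median ("paw instability",
  lower = more stable).

A cohort score orients each component so larger = better, percentile-ranks
them across the cohort, takes the 20/40/40-weighted average (paw stability /
zone expectation / lateral SD), and maps the percentile of that average
linearly onto [1, 5].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .pose import PAWS, HEAD, BodyPartTrack, PoseSession
from .protocol import RUN, SessionSchedule

DEFAULT_MIN_DISPLACEMENT = 0.005  # normalized units; below = tracking jitter


@dataclass
class ScoreConfig:
    n_zones: int = 5
    #: percentage weights for (paw_stability, zone_expectation, lateral_sd)
    weights: tuple[float, float, float] = (20.0, 40.0, 40.0)
    score_range: tuple[float, float] = (1.0, 5.0)
    min_displacement: float = DEFAULT_MIN_DISPLACEMENT

    def __post_init__(self) -> None:
        if self.n_zones < 2:
            raise ValueError("n_zones must be >= 2")
        if abs(sum(self.weights) - 100.0) > 1e-9:
            raise ValueError("weights must sum to 100")


@dataclass
class CoordinationComponents:
    zone_expectation: float
    lateral_sd: float
    step_length_means: dict[str, float] = field(default_factory=dict)
    paw_instability: float = 0.0

    @property
    def mean_step_length(self) -> float:
        """Across-paw mean of the per-paw mean step lengths."""
        if not self.step_length_means:
            return 0.0
        return float(np.mean(list(self.step_length_means.values())))

    def as_triple(self) -> tuple[float, float, float]:
        return (self.zone_expectation, self.lateral_sd, self.paw_instability)


def zone_probabilities(head_x: np.ndarray, n_zones: int = 5) -> np.ndarray:
    """Probability of the head occupying each of ``n_zones`` equal-width zones.

    Bins partition [0, 1]; the last bin is closed so x = 1 falls in the
    rearmost zone.
    """
    head_x = np.asarray(head_x, dtype=float)
    if head_x.size == 0:
        raise ValueError("empty head-position series")
    counts, _ = np.histogram(head_x, bins=n_zones, range=(0.0, 1.0))
    return counts / head_x.size


def zone_expectation(probabilities: np.ndarray) -> float:
    """Expected zone index, sum(z * p(z)), in [1, n_zones]."""
    p = np.asarray(probabilities, dtype=float)
    return float(np.sum(np.arange(1, p.size + 1) * p))


def lateral_sd(head_y: np.ndarray) -> float:
    """Population SD of the head's lateral (y) position."""
    head_y = np.asarray(head_y, dtype=float)
    if head_y.size == 0:
        raise ValueError("empty head-position series")
    return float(np.std(head_y))


def step_lengths(
    paw_track: BodyPartTrack | tuple[np.ndarray, np.ndarray],
    min_displacement: float = DEFAULT_MIN_DISPLACEMENT,
) -> tuple[np.ndarray, float]:
    """Per-step lengths of one paw and their mean.

    A "step" is a frame-to-frame Euclidean displacement at or above
    ``min_displacement``; smaller displacements are tracking jitter and are
    excluded.  Returns (retained step lengths, their mean — 0 if none).
    """
    if isinstance(paw_track, BodyPartTrack):
        x, y = paw_track.x, paw_track.y
    else:
        x, y = (np.asarray(a, dtype=float) for a in paw_track)
    d = np.hypot(np.diff(x), np.diff(y))
    steps = d[d >= min_displacement]
    mean = float(steps.mean()) if steps.size else 0.0
    return steps, mean


def paw_instability(per_paw_means) -> float:
    """Mean absolute deviation of per-paw mean step lengths from their median.

    Lower values mean the four paws take similar-length steps ("paw
    stability" enters the score with this sign flipped).
    """
    m = np.asarray(list(per_paw_means), dtype=float)
    if m.size != 4:
        raise ValueError(f"expected 4 per-paw means, got {m.size}")
    return float(np.mean(np.abs(m - np.median(m))))


def compute_components(
    session: PoseSession,
    schedule: SessionSchedule,
    config: ScoreConfig | None = None,
) -> CoordinationComponents:
    """Session components over run-epoch frames only (belt on)."""
    config = config or ScoreConfig()
    if not session.normalized:
        raise ValueError("session must be normalized to the box first")
    labels = schedule.label_times(session.frame_times)
    run_mask = labels == RUN
    if not run_mask.any():
        raise ValueError("session has no frames during run epochs")

    head = session[HEAD]
    probs = zone_probabilities(head.x[run_mask], config.n_zones)
    means = {}
    for paw in PAWS:
        tr = session[paw]
        _, means[paw] = step_lengths(
            (tr.x[run_mask], tr.y[run_mask]), config.min_displacement
        )
    return CoordinationComponents(
        zone_expectation=zone_expectation(probs),
        lateral_sd=lateral_sd(head.y[run_mask]),
        step_length_means=means,
        paw_instability=paw_instability(list(means.values())),
    )


def _percentile_ranks(values: np.ndarray) -> np.ndarray:
    """Midrank percentiles mapped onto [0, 100] (lowest -> 0, highest -> 100)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    ranks = rankdata(values, method="average")
    if n == 1:
        return np.full(1, 50.0)
    return (ranks - 1.0) / (n - 1.0) * 100.0


class CoordinationScorer(BaseEstimator):
    """Cohort-referenced 1-5 motor-coordination score.

    Fit on a cohort of component triples (zone_expectation, lateral_sd,
    paw_instability), one row per session.  Fitting (i) orients each
    component so larger = better coordination (all three are negated),
    (ii) percentile-ranks each oriented component across the cohort with
    midrank ties, (iii) forms the weighted average with percentage weights
    (paw stability, zone expectation, lateral SD), and (iv) maps the
    percentile rank of the weighted average linearly onto ``score_range``.

    Attributes (after ``fit``)
    --------------------------
    components_ : ndarray (n_sessions, 3)
    percentiles_ : ndarray (n_sessions, 3)
        Oriented per-component percentile ranks in [0, 100].
    weighted_average_ : ndarray (n_sessions,)
    scores_ : ndarray (n_sessions,)
        Final scores in ``score_range``.
    """

    _COLUMNS = ("zone_expectation", "lateral_sd", "paw_instability")

    def __init__(
        self,
        weights: tuple[float, float, float] = (20.0, 40.0, 40.0),
        score_range: tuple[float, float] = (1.0, 5.0),
    ):
        self.weights = weights
        self.score_range = score_range

    def _validate(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self._COLUMNS)].to_numpy()
        elif len(X) and isinstance(X[0], CoordinationComponents):
            X = np.array([c.as_triple() for c in X])
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("expected a (n_sessions, 3) component matrix")
        if not np.isfinite(X).all():
            raise ValueError("components must be finite")
        return X

    def fit(self, X, y=None) -> "CoordinationScorer":
        X = self._validate(X)
        if X.shape[0] < 2:
            raise ValueError(
                "scoring needs >= 2 sessions: pool a cohort (all animal-days) "
                "into one call so percentiles have a reference set"
            )
        if abs(sum(self.weights) - 100.0) > 1e-9:
            raise ValueError("weights must sum to 100")
        w_paw, w_zone, w_lat = (w / 100.0 for w in self.weights)
        oriented = -X  # lower zone index / lateral SD / instability = better
        pct = np.column_stack([_percentile_ranks(oriented[:, j]) for j in range(3)])
        wavg = w_zone * pct[:, 0] + w_lat * pct[:, 1] + w_paw * pct[:, 2]
        lo, hi = self.score_range
        scores = lo + (hi - lo) * _percentile_ranks(wavg) / 100.0

        self.components_ = X
        self.oriented_ = oriented
        self.percentiles_ = pct
        self.weighted_average_ = wavg
        self.scores_ = scores
        self.n_features_in_ = 3
        return self

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).scores_

    def transform(self, X) -> np.ndarray:
        """Score new sessions against the fitted cohort's reference distribution.

        Each oriented component is mapped to a percentile by interpolating
        into the fitted cohort's (value -> percentile) relation; the weighted
        average is mapped onto the fitted weighted-average distribution the
        same way.  Results are clipped to ``score_range``.
        """
        if not hasattr(self, "scores_"):
            raise ValueError("CoordinationScorer is not fitted")
        X = self._validate(X)
        w_paw, w_zone, w_lat = (w / 100.0 for w in self.weights)
        oriented = -X
        pct = np.empty_like(oriented)
        for j in range(3):
            order = np.argsort(self.oriented_[:, j])
            pct[:, j] = np.interp(
                oriented[:, j],
                self.oriented_[order, j],
                self.percentiles_[order, j],
            )
        wavg = w_zone * pct[:, 0] + w_lat * pct[:, 1] + w_paw * pct[:, 2]
        order = np.argsort(self.weighted_average_)
        ref_pct = _percentile_ranks(self.weighted_average_)
        out_pct = np.interp(wavg, self.weighted_average_[order], ref_pct[order])
        lo, hi = self.score_range
        return np.clip(lo + (hi - lo) * out_pct / 100.0, lo, hi)


def score_cohort(
    components_list, config: ScoreConfig | None = None
) -> pd.DataFrame:
    """Score a cohort of sessions; returns one tidy row per session.

    Columns: the three raw components, per-paw step-length means (when
    available), oriented percentile ranks, the weighted average and the
    final 1-5 score.  Scores are permutation-invariant to session order.
    """
    config = config or ScoreConfig()
    scorer = CoordinationScorer(weights=config.weights, score_range=config.score_range)
    scorer.fit(components_list)

    rows = pd.DataFrame(scorer.components_, columns=list(CoordinationScorer._COLUMNS))
    if len(components_list) and isinstance(components_list[0], CoordinationComponents):
        for paw in PAWS:
            rows[f"step_mean_{paw}"] = [
                c.step_length_means.get(paw, np.nan) for c in components_list
            ]
    rows["pct_zone_expectation"] = scorer.percentiles_[:, 0]
    rows["pct_lateral_sd"] = scorer.percentiles_[:, 1]
    rows["pct_paw_stability"] = scorer.percentiles_[:, 2]
    rows["weighted_avg"] = scorer.weighted_average_
    rows["score"] = scorer.scores_
    return rows
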