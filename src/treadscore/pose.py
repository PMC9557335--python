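"""Read, quality-filter, normalize and time-align pose-tracking tables.

Input is the DeepLabCut CSV dialect: three header rows (scorer, bodyparts,
coords) and one row per video frame with an (x, y, likelihood) triplet per
body part.  The canonical in-memory container is :class:`PoseSession`, whose
coordinates are normalized to the running-box geometry so that x = 0 is the
front wall and x = 1 the rear wall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .protocol import SessionSchedule

HEAD = "head"
RIGHT_FRONT = "right_front_paw"
LEFT_FRONT = "left_front_paw"
RIGHT_HIND = "right_hind_paw"
LEFT_HIND = "left_hind_paw"
TAIL_BASE = "tail_base"
TAIL_TIP = "tail_tip"

PAWS = (RIGHT_FRONT, LEFT_FRONT, RIGHT_HIND, LEFT_HIND)
REQUIRED_PARTS = (HEAD,) + PAWS
ALL_PARTS = REQUIRED_PARTS + (TAIL_BASE, TAIL_TIP)

DEFAULT_FRAME_RATE = 30.0  # frames/s, matching the photometry target rate
DEFAULT_LIKELIHOOD_THRESHOLD = 0.9


class PoseFormatError(ValueError):
    """Tracking table malformed or missing a required body part."""


class DataQualityError(ValueError):
    """A track has no usable (confident) frames."""


class InvalidGeometryError(ValueError):
    """Degenerate box geometry."""


class AlignmentError(ValueError):
    """Session cannot be placed on the schedule clock."""


@dataclass
class BodyPartTrack:
    part: str
    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if not (len(self.x) == len(self.y) == len(self.likelihood)):
            raise ValueError(f"track {self.part}: x/y/likelihood length mismatch")
        lk = self.likelihood
        if lk.size and (np.nanmin(lk) < 0 or np.nanmax(lk) > 1):
            raise ValueError(f"track {self.part}: likelihood outside [0, 1]")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class PoseSession:
    """Time-aligned per-bodypart tracks plus running-box geometry.

    ``box`` is (x_front, x_rear, y_left, y_right) in raw (pixel) coordinates;
    after :func:`normalize_to_box` every retained coordinate lies in [0, 1].
    ``in_schedule`` flags frames inside [0, total_duration) after alignment.
    """

    frame_rate: float
    frame_times: np.ndarray
    tracks: dict[str, BodyPartTrack]
    box: tuple[float, float, float, float] | None = None
    normalized: bool = False
    in_schedule: np.ndarray | None = None
    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        n = len(self.frame_times)
        for t in self.tracks.values():
            if len(t) != n:
                raise ValueError(
                    f"track {t.part} has {len(t)} frames, expected {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)

    def __getitem__(self, part: str) -> BodyPartTrack:
        return self.tracks[part]

    def to_tidy_frame(self) -> pd.DataFrame:
        """Long-format export: time_s, part, x, y, likelihood."""
        rows = []
        for part, tr in self.tracks.items():
            rows.append(
                pd.DataFrame(
                    {
                        "time_s": self.frame_times,
                        "part": part,
                        "x": tr.x,
                        "y": tr.y,
                        "likelihood": tr.likelihood,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def read_tracking_table(
    path,
    frame_rate: float = DEFAULT_FRAME_RATE,
    box: tuple[float, float, float, float] | None = None,
) -> PoseSession:
    """Read a DeepLabCut-dialect CSV into a :class:`PoseSession`.

    The file carries three header rows (scorer / bodyparts / coords); unknown
    extra parts are kept in ``tracks`` but ignored by downstream metrics.
    Raises :class:`PoseFormatError` if the head or any paw is missing, and a
    parse error naming the row on any non-numeric cell.
    """
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise PoseFormatError(f"{path}: cannot parse tracking table: {exc}") from exc

    parts_in_file = list(dict.fromkeys(df.columns.get_level_values(1)))
    for required in REQUIRED_PARTS:
        if required not in parts_in_file:
            raise PoseFormatError(f"{path}: missing required body part {required!r}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy())[0, 0])
        # +4: 3 header rows + 1-based counting
        raise PoseFormatError(f"{path}: non-numeric cell at data row {row} (file line {row + 4})")

    tracks = {}
    scorer = df.columns.get_level_values(0)[0]
    for part in parts_in_file:
        sub = numeric[scorer][part]
        try:
            tracks[part] = BodyPartTrack(
                part=part,
                x=sub["x"].to_numpy(),
                y=sub["y"].to_numpy(),
                likelihood=sub["likelihood"].to_numpy(),
            )
        except KeyError as exc:
            raise PoseFormatError(f"{path}: part {part!r} lacks column {exc}") from exc

    n = len(df)
    return PoseSession(
        frame_rate=frame_rate,
        frame_times=np.arange(n) / frame_rate,
        tracks=tracks,
        box=box,
    )


def write_tracking_table(session: PoseSession, path, scorer: str = "treadscore") -> None:
    """Write a session back out in the DeepLabCut CSV dialect (round-trip safe)."""
    cols = {}
    for part, tr in session.tracks.items():
        cols[(scorer, part, "x")] = tr.x
        cols[(scorer, part, "y")] = tr.y
        cols[(scorer, part, "likelihood")] = tr.likelihood
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["scorer", "bodyparts", "coords"])
    df.index.name = None
    df.to_csv(path, float_format="%.17g")  # round-trip exact


def filter_likelihood(
    session: PoseSession, threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD
) -> PoseSession:
    """Gap-fill low-confidence frames by linear interpolation.

    Frames with likelihood below ``threshold`` are replaced by linear
    interpolation between the nearest confident neighbours; leading/trailing
    gaps are held at the nearest confident value.  The fraction of frames
    interpolated per part is recorded in ``session.qc['interpolated_fraction']``.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    new_tracks = {}
    fractions = {}
    idx = np.arange(session.n_frames)
    for part, tr in session.tracks.items():
        good = tr.likelihood >= threshold
        if not good.any():
            raise DataQualityError(
                f"part {part!r}: no frames at or above likelihood {threshold}"
            )
        x = np.interp(idx, idx[good], tr.x[good])
        y = np.interp(idx, idx[good], tr.y[good])
        new_tracks[part] = BodyPartTrack(part, x, y, tr.likelihood.copy())
        fractions[part] = float((~good).mean())
    qc = dict(session.qc)
    qc["interpolated_fraction"] = fractions
    return replace(session, tracks=new_tracks, qc=qc)


def normalize_to_box(session: PoseSession) -> PoseSession:
    """Normalize coordinates within the running-box dimensions.

    x' = (x - x_front) / (x_rear - x_front), y' analogously; values are
    clipped to [0, 1] (a warning is emitted when clipping occurs) so frame
    alignment with photometry is preserved.  Applying twice is rejected.
    """
    if session.normalized:
        raise ValueError("session is already normalized; refusing to compound")
    if session.box is None:
        raise InvalidGeometryError("session has no box geometry")
    x_front, x_rear, y_left, y_right = session.box
    if x_rear == x_front or y_right == y_left:
        raise InvalidGeometryError(f"degenerate box {session.box}")

    new_tracks = {}
    clipped = 0
    for part, tr in session.tracks.items():
        x = (tr.x - x_front) / (x_rear - x_front)
        y = (tr.y - y_left) / (y_right - y_left)
        clipped += int(((x < 0) | (x > 1) | (y < 0) | (y > 1)).sum())
        new_tracks[part] = BodyPartTrack(
            part, np.clip(x, 0.0, 1.0), np.clip(y, 0.0, 1.0), tr.likelihood.copy()
        )
    if clipped:
        warnings.warn(f"clipped {clipped} out-of-box coordinates to [0, 1]", stacklevel=2)
    return replace(session, tracks=new_tracks, normalized=True)


def align_to_schedule(
    session: PoseSession, schedule: SessionSchedule, sync_offset: float = 0.0
) -> PoseSession:
    """Shift frame times onto the schedule clock (frame 0 -> ``sync_offset``)."""
    times = session.frame_times - session.frame_times[0] + sync_offset
    inside = (times >= 0) & (times < schedule.total_duration)
    if not inside.any():
        raise AlignmentError(
            f"no frame falls inside the schedule window [0, {schedule.total_duration})"
        )
    return replace(session, frame_times=times, in_schedule=inside)
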