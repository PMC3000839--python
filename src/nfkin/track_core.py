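"""Data model and I/O for neurofilament end-tracking data.

Coordinates are one-dimensional: the signed axial position of a tracked
filament end along the axon, in micrometres, with anterograde (cell body to
axon tip) mapped to increasing position.  Time is in seconds from the start
of the movie.  Projection of 2-D image coordinates onto the axon axis is the
tracking step's job and happens upstream of this package.

A movie is a fixed-length time-lapse recording (default 15 min at 4-s frame
intervals) of one axonal gap; each filament that moves through the gap yields
one :class:`Track`.  Occasional missing frames (e.g. refocusing) are allowed
as gaps in a track's time series; analysis stages leave intervals spanning a
gap unscored rather than interpolating.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "Movie",
    "AnalysisConfig",
    "ParseError",
    "ValidationError",
    "read_tracks",
    "write_tracks",
    "read_movie_metadata",
    "write_movie_metadata",
    "px_to_um",
    "um_to_px",
    "DEFAULT_PIXEL_SIZE_UM",
]

#: camera pixel size implied by the 50 px = 6.55 um and 10 px = 1.31 um pairs
DEFAULT_PIXEL_SIZE_UM = 0.131

TRACK_CSV_COLUMNS = [
    "movie_id",
    "track_id",
    "time_s",
    "position_um",
    "filament_length_um",
    "end_tracked",
]


class ParseError(ValueError):
    """A track file row could not be parsed."""


class ValidationError(ValueError):
    """Data violate a structural invariant (ordering, duplication, range)."""


def px_to_um(pixels: float, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> float:
    """Convert a pixel count to micrometres.

    Parameters
    ----------
    pixels
        Number of pixels; must be non-negative.
    pixel_size_um
        Physical pixel size in um/pixel; must be positive.
    """
    if pixels < 0:
        raise ValueError(f"pixel count must be >= 0, got {pixels}")
    if pixel_size_um <= 0:
        raise ValueError(f"pixel size must be > 0, got {pixel_size_um}")
    return pixels * pixel_size_um


def um_to_px(um: float, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> float:
    """Inverse of :func:`px_to_um`."""
    if um < 0:
        raise ValueError(f"distance must be >= 0, got {um}")
    if pixel_size_um <= 0:
        raise ValueError(f"pixel size must be > 0, got {pixel_size_um}")
    return um / pixel_size_um


@dataclass
class Track:
    """Time-stamped axial positions of one tracked filament end.

    ``end_tracked`` records whether the leading or trailing end of the
    filament was followed (or ``"comet"`` for EB1 comet traces stored in the
    same dialect); no kinetic computation depends on it.
    """

    track_id: str
    times: np.ndarray
    positions: np.ndarray
    filament_length_um: float
    end_tracked: str = "leading"
    movie_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.positions.shape:
            raise ValidationError(
                f"track {self.track_id!r}: times and positions must be "
                f"1-D arrays of equal length"
            )
        if self.times.size < 2:
            raise ValidationError(
                f"track {self.track_id!r}: needs at least 2 frames, "
                f"got {self.times.size}"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"track {self.track_id!r}: times must be strictly increasing"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError(
                f"track {self.track_id!r}: positions must be finite"
            )
        if not self.filament_length_um > 0:
            raise ValidationError(
                f"track {self.track_id!r}: filament length must be > 0 um, "
                f"got {self.filament_length_um}"
            )

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    def path_length_um(self) -> float:
        """Total path length: sum of |frame-to-frame displacement|."""
        return float(np.sum(np.abs(np.diff(self.positions))))


@dataclass
class Movie:
    """One time-lapse recording and the tracks observed in it."""

    movie_id: str
    duration_s: float = 900.0
    frame_interval_s: float = 4.0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    tracks: list[Track] = field(default_factory=list)
    condition: str = ""

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be > 0")
        if self.frame_interval_s <= 0:
            raise ValidationError("frame_interval_s must be > 0")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be > 0")
        for tr in self.tracks:
            self._check_track(tr)

    def _check_track(self, tr: Track) -> None:
        if tr.times[0] < -1e-9 or tr.times[-1] > self.duration_s + 1e-9:
            raise ValidationError(
                f"track {tr.track_id!r}: times outside [0, {self.duration_s}] s"
            )
        # frames sit on the movie grid; gaps (integer multiples) are allowed
        dt = np.diff(tr.times)
        mult = dt / self.frame_interval_s
        if np.any(np.abs(mult - np.round(mult)) > 1e-6) or np.any(
            np.round(mult) < 1
        ):
            raise ValidationError(
                f"track {tr.track_id!r}: times not spaced at multiples of the "
                f"{self.frame_interval_s}-s frame interval"
            )

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds of the motion analysis.

    min_length_px
        Minimum filament length for an object to be analyzed (10 px = 1.31 um).
    min_total_distance_px
        Minimum total path length a filament must move to qualify
        (50 px = 6.55 um).
    min_frames
        Minimum number of successive frames a filament must be trackable for.
    preferred_direction_fraction
        Fraction of moving time in one direction at or above which the
        filament counts as having a preferred direction (0.70).
    pause_epsilon_um
        Frame-to-frame displacement at or below which an interval is a pause;
        default one pixel per interval (0.131 um, i.e. <0.033 um/s at 4-s
        frames), well below reported bout velocities of 0.23-0.40 um/s.
    """

    min_length_px: float = 10.0
    min_total_distance_px: float = 50.0
    min_frames: int = 3
    preferred_direction_fraction: float = 0.70
    pause_epsilon_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.min_length_px <= 0 or self.min_total_distance_px <= 0:
            raise ValidationError("length/distance thresholds must be > 0")
        if self.min_frames <= 0:
            raise ValidationError("min_frames must be > 0")
        if not 0.5 < self.preferred_direction_fraction <= 1.0:
            raise ValidationError(
                "preferred_direction_fraction must lie in (0.5, 1]"
            )
        if self.pause_epsilon_um <= 0:
            raise ValidationError("pause_epsilon_um must be > 0")


# ---------------------------------------------------------------------------
# I/O: plain CSV with a required header, one row per (track, frame)
# ---------------------------------------------------------------------------

def read_tracks(path: str | Path, movie_metadata: Movie | dict | None = None) -> Movie:
    """Read a track CSV into a :class:`Movie`.

    Rows are grouped by ``track_id`` and sorted by time within each track.
    ``movie_metadata`` supplies the recording parameters, either as a template
    :class:`Movie` (its tracks are ignored) or a dict with any of
    ``movie_id, duration_s, frame_interval_s, pixel_size_um, condition``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={"movie_id": str, "track_id": str,
                                      "end_tracked": str})
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in ("track_id", "time_s", "position_um",
                           "filament_length_um") if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")

    for col in ("time_s", "position_um", "filament_length_um"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            # +2: one for the header, one for 0-based indexing
            line = int(bad.idxmax()) + 2
            raise ParseError(
                f"{path}: malformed value in column {col!r} at line {line}"
            )
        df[col] = coerced

    meta: dict = {}
    if isinstance(movie_metadata, Movie):
        meta = {
            "movie_id": movie_metadata.movie_id,
            "duration_s": movie_metadata.duration_s,
            "frame_interval_s": movie_metadata.frame_interval_s,
            "pixel_size_um": movie_metadata.pixel_size_um,
            "condition": movie_metadata.condition,
        }
    elif movie_metadata is not None:
        meta = dict(movie_metadata)

    if "movie_id" in df.columns and len(df):
        ids = df["movie_id"].unique()
        if len(ids) > 1:
            raise ValidationError(
                f"{path}: contains {len(ids)} movie_ids; one movie per file"
            )
        meta.setdefault("movie_id", str(ids[0]))
    meta.setdefault("movie_id", path.stem)

    tracks: list[Track] = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("time_s")
        times = grp["time_s"].to_numpy()
        if np.any(np.diff(times) <= 0):
            raise ValidationError(
                f"{path}: track {tid!r} has duplicated time points"
            )
        lengths = grp["filament_length_um"].unique()
        if len(lengths) > 1:
            raise ValidationError(
                f"{path}: track {tid!r} has inconsistent filament_length_um"
            )
        end = (grp["end_tracked"].iloc[0]
               if "end_tracked" in grp.columns else "leading")
        tracks.append(Track(
            track_id=str(tid),
            times=times,
            positions=grp["position_um"].to_numpy(),
            filament_length_um=float(lengths[0]),
            end_tracked=str(end),
            movie_id=meta["movie_id"],
        ))
    return Movie(
        movie_id=meta["movie_id"],
        duration_s=float(meta.get("duration_s", 900.0)),
        frame_interval_s=float(meta.get("frame_interval_s", 4.0)),
        pixel_size_um=float(meta.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM)),
        tracks=tracks,
        condition=str(meta.get("condition", "")),
    )


def write_tracks(movie: Movie, path: str | Path) -> Path:
    """Write a Movie's tracks as CSV; returns the path written.

    ``read_tracks(write_tracks(m))`` reproduces ``m`` to float-formatting
    tolerance (1e-6 um).
    """
    path = Path(path)
    rows = []
    for tr in movie.tracks:
        for t, x in zip(tr.times, tr.positions):
            rows.append((movie.movie_id, tr.track_id, t, x,
                         tr.filament_length_um, tr.end_tracked))
    df = pd.DataFrame(rows, columns=TRACK_CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.8g")
    return path


def write_movie_metadata(movie: Movie, path: str | Path) -> Path:
    """Write the movie's recording parameters as a JSON sidecar."""
    path = Path(path)
    path.write_text(json.dumps({
        "movie_id": movie.movie_id,
        "duration_s": movie.duration_s,
        "frame_interval_s": movie.frame_interval_s,
        "pixel_size_um": movie.pixel_size_um,
        "condition": movie.condition,
    }, indent=1))
    return path


def read_movie_metadata(path: str | Path) -> dict:
    """Read a JSON metadata sidecar written by :func:`write_movie_metadata`."""
    return json.loads(Path(path).read_text())
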