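"""Qualification, pause/bout segmentation and direction classification.

The unit of analysis is the frame-to-frame interval.  An interval is
anterograde if the displacement exceeds +epsilon, retrograde below -epsilon,
and paused otherwise; intervals spanning missing frames are left unscored.
A *bout* is a maximal run of same-direction moving intervals: it ends at a
pause, at an unscored gap, at a direction flip (a reversal terminates one
bout and starts the next even without an intervening pause), or at the track
boundary.  Bouts touching the track's first or last frame are flagged as
truncated — their true duration cannot be assessed — and are excluded from
bout statistics, although their distance still counts toward flux.

A filament qualifies for analysis if it is at least 10 pixels (1.31 um)
long, moved a total path length of at least 50 pixels (6.55 um), and is
trackable through at least three successive frames.  Qualifying filaments
are classified by preferred direction: anterograde or retrograde if at least
70% of their *moving* time (pauses excluded) is spent in that direction,
otherwise bidirectional ("dual"), in which case the anterograde and
retrograde components are treated as separate moving events downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .track_core import AnalysisConfig, Track, DEFAULT_PIXEL_SIZE_UM, px_to_um

__all__ = [
    "Bout",
    "TrackClass",
    "label_intervals",
    "segment_bouts",
    "qualify_track",
    "classify_direction",
    "ANTERO", "RETRO", "PAUSE", "UNSCORED",
]

# interval labels
ANTERO = "A"
RETRO = "R"
PAUSE = "P"
UNSCORED = "U"


@dataclass
class Bout:
    """One uninterrupted run of same-direction movement."""

    track_id: str
    direction: str            # anterograde | retrograde
    start_s: float
    end_s: float
    distance_um: float        # unsigned path over the run
    duration_s: float
    velocity_um_s: float      # distance / duration
    truncated: str = "none"   # none | start | end

    @property
    def scored(self) -> bool:
        """Whether this bout enters bout statistics (complete bouts only)."""
        return self.truncated == "none"


@dataclass
class TrackClass:
    track_id: str
    qualifies: bool
    direction_class: str      # anterograde | retrograde | dual
    moving_time_fraction_antero: float
    total_path_um: float
    directed_distance_antero_um: float
    directed_distance_retro_um: float


def label_intervals(track: Track, config: AnalysisConfig,
                    frame_interval_s: float | None = None) -> np.ndarray:
    """Label each frame-to-frame interval A/R/P/U.

    ``frame_interval_s`` identifies gaps (missing frames): an interval longer
    than 1.5x the frame interval is unscored.  If omitted, the smallest
    observed interval is taken as the frame interval.
    """
    if track.n_frames < 2:
        raise ValueError("track must have at least 2 frames")
    dx = np.diff(track.positions)
    dt = np.diff(track.times)
    if frame_interval_s is None:
        frame_interval_s = float(dt.min())
    labels = np.full(dx.shape, PAUSE, dtype="<U1")
    eps = config.pause_epsilon_um
    labels[dx > eps] = ANTERO
    labels[dx < -eps] = RETRO
    labels[dt > 1.5 * frame_interval_s] = UNSCORED
    return labels


def segment_bouts(track: Track, config: AnalysisConfig,
                  frame_interval_s: float | None = None) -> list[Bout]:
    """Segment a track into bouts (including truncated ones).

    Returns all bouts in time order; filter on ``Bout.scored`` for bout
    statistics.
    """
    labels = label_intervals(track, config, frame_interval_s)
    dx = np.abs(np.diff(track.positions))
    t = track.times
    n = labels.size

    bouts: list[Bout] = []
    i = 0
    while i < n:
        lab = labels[i]
        if lab not in (ANTERO, RETRO):
            i += 1
            continue
        j = i
        while j + 1 < n and labels[j + 1] == lab:
            j += 1
        start_s, end_s = float(t[i]), float(t[j + 1])
        dist = float(dx[i:j + 1].sum())
        truncated = "none"
        if i == 0:
            truncated = "start"
        elif j == n - 1:
            truncated = "end"
        bouts.append(Bout(
            track_id=track.track_id,
            direction="anterograde" if lab == ANTERO else "retrograde",
            start_s=start_s, end_s=end_s,
            distance_um=dist, duration_s=end_s - start_s,
            velocity_um_s=dist / (end_s - start_s),
            truncated=truncated,
        ))
        i = j + 1
    return bouts


def _moving_path_um(labels: np.ndarray, dx_abs: np.ndarray) -> float:
    moving = (labels == ANTERO) | (labels == RETRO)
    return float(dx_abs[moving].sum())


def _longest_frame_run(labels: np.ndarray) -> int:
    """Longest run of successive frames not interrupted by a gap."""
    best = cur = 1
    for lab in labels:
        cur = cur + 1 if lab != UNSCORED else 1
        best = max(best, cur)
    return best


def qualify_track(track: Track, config: AnalysisConfig,
                  pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                  frame_interval_s: float | None = None) -> bool:
    """Apply the object-qualification filter.

    True iff the filament is long enough, its total path length (sum of
    per-interval |displacement| over moving intervals — not net
    displacement, so out-and-back movers qualify) reaches the distance
    threshold, and it spans enough successive frames.
    """
    if track.filament_length_um < px_to_um(config.min_length_px, pixel_size_um):
        return False
    labels = label_intervals(track, config, frame_interval_s)
    dx_abs = np.abs(np.diff(track.positions))
    if _moving_path_um(labels, dx_abs) < px_to_um(config.min_total_distance_px,
                                                  pixel_size_um):
        return False
    return _longest_frame_run(labels) >= config.min_frames


def classify_direction(track: Track, config: AnalysisConfig,
                       pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
                       frame_interval_s: float | None = None) -> TrackClass:
    """Classify a track's preferred direction from its moving time.

    The moving-time fraction counts scored moving intervals only; a track
    with zero moving intervals cannot be classified and raises ValueError.
    """
    labels = label_intervals(track, config, frame_interval_s)
    dt = np.diff(track.times)
    dx = np.diff(track.positions)
    antero = labels == ANTERO
    retro = labels == RETRO
    t_antero = float(dt[antero].sum())
    t_retro = float(dt[retro].sum())
    if t_antero + t_retro == 0:
        raise ValueError(
            f"track {track.track_id!r} has no moving intervals; "
            "cannot classify a non-mover"
        )
    frac_a = t_antero / (t_antero + t_retro)
    thr = config.preferred_direction_fraction
    if frac_a >= thr:
        direction_class = "anterograde"
    elif (1.0 - frac_a) >= thr:
        direction_class = "retrograde"
    else:
        direction_class = "dual"
    d_a = float(np.abs(dx[antero]).sum())
    d_r = float(np.abs(dx[retro]).sum())
    return TrackClass(
        track_id=track.track_id,
        qualifies=qualify_track(track, config, pixel_size_um, frame_interval_s),
        direction_class=direction_class,
        moving_time_fraction_antero=frac_a,
        total_path_um=d_a + d_r,
        directed_distance_antero_um=d_a,
        directed_distance_retro_um=d_r,
    )
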