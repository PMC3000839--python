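"""End-to-end convenience layer: simulate cohorts and run the full analysis.

Everything here is thin glue over the module-level operations so that the
analysis drivers, the test suite and the acceptance script share one code
path from raw tracks to per-movie summaries and pooled bout statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bout_kinetics import (Bout, TrackClass, classify_direction,
                            qualify_track, segment_bouts)
from .motion_sim import ConditionPreset, SimOutput, simulate_movie
from .track_core import AnalysisConfig, Movie
from .transport_stats import MovieSummary, movie_summary

__all__ = [
    "MovieAnalysis",
    "analyze_movie",
    "movie_seeds",
    "simulate_cohort",
    "analyze_cohort",
    "pooled_bout_stats",
    "bouts_to_frame",
]


@dataclass
class MovieAnalysis:
    movie: Movie
    classes: list[TrackClass]        # qualifying tracks only
    bouts: list[Bout]                # all bouts of qualifying tracks
    summary: MovieSummary


def analyze_movie(movie: Movie,
                  config: AnalysisConfig | None = None) -> MovieAnalysis:
    """Qualify, classify and segment every track; summarize the movie."""
    if config is None:
        config = AnalysisConfig()
    classes: list[TrackClass] = []
    bouts: list[Bout] = []
    for track in movie.tracks:
        if not qualify_track(track, config, movie.pixel_size_um,
                             movie.frame_interval_s):
            continue
        classes.append(classify_direction(track, config, movie.pixel_size_um,
                                          movie.frame_interval_s))
        bouts.extend(segment_bouts(track, config, movie.frame_interval_s))
    return MovieAnalysis(
        movie=movie, classes=classes, bouts=bouts,
        summary=movie_summary(movie, classes, config),
    )


def movie_seeds(base_seed: int, n_movies: int) -> list[int]:
    """Derive ``n_movies`` distinct per-movie seeds (< 2^31) from one seed."""
    a = (1_000_003 * int(base_seed)) % (2 ** 31)
    return [(a + i) % (2 ** 31) for i in range(1, n_movies + 1)]


def simulate_cohort(preset: ConditionPreset, n_movies: int, base_seed: int,
                    duration_s: float = 900.0,
                    frame_interval_s: float = 4.0) -> list[SimOutput]:
    """Simulate one experimental arm of ``n_movies`` movies."""
    return [
        simulate_movie(preset, duration_s, frame_interval_s, seed=s,
                       movie_id=f"{preset.name}-m{i:03d}")
        for i, s in enumerate(movie_seeds(base_seed, n_movies))
    ]


def analyze_cohort(sims: list[SimOutput],
                   config: AnalysisConfig | None = None) -> list[MovieAnalysis]:
    return [analyze_movie(s.movie, config) for s in sims]


def bouts_to_frame(analyses: list[MovieAnalysis]) -> pd.DataFrame:
    rows = []
    for an in analyses:
        for b in an.bouts:
            rows.append({
                "movie_id": an.movie.movie_id, "track_id": b.track_id,
                "direction": b.direction, "start_s": b.start_s,
                "end_s": b.end_s, "distance_um": b.distance_um,
                "duration_s": b.duration_s, "velocity_um_s": b.velocity_um_s,
                "truncated": b.truncated,
            })
    return pd.DataFrame(rows)


def pooled_bout_stats(analyses: list[MovieAnalysis],
                      direction: str) -> dict[str, float]:
    """Pool scored (complete) bouts of one direction across movies.

    Bout metrics are pooled over bouts, not averaged per movie, matching how
    bout histograms count individual bouts.
    """
    scored = [b for an in analyses for b in an.bouts
              if b.scored and b.direction == direction]
    if not scored:
        return {"n_bouts": 0, "mean_velocity_um_s": float("nan"),
                "mean_duration_s": float("nan"),
                "mean_distance_um": float("nan")}
    return {
        "n_bouts": len(scored),
        "mean_velocity_um_s": float(np.mean([b.velocity_um_s for b in scored])),
        "mean_duration_s": float(np.mean([b.duration_s for b in scored])),
        "mean_distance_um": float(np.mean([b.distance_um for b in scored])),
    }
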