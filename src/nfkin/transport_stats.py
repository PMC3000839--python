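"""Per-movie transport statistics and between-condition comparisons.

Frequency: number of qualifying filaments per direction per movie, scaled to
per-hour.  A filament with a preferred direction counts once, in that
direction; a bidirectional ("dual") filament represents separate anterograde
and retrograde moving events and adds one to each direction's count.

Flux: total distance moved in each direction by all qualifying filaments in
a movie, scaled to um/axon/hour (each movie images one axon).  Flux counts
*all* moving distance including truncated bouts; only per-bout statistics
exclude truncated bouts.

Conditions are compared with the Mann-Whitney rank-sum test (two-sided,
midranks for ties): exact enumeration for small tie-free samples, otherwise
the normal approximation with tie and continuity corrections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bout_kinetics import TrackClass
from .track_core import AnalysisConfig, Movie

__all__ = [
    "MovieSummary",
    "GroupComparison",
    "AggregateResult",
    "movie_summary",
    "aggregate",
    "mann_whitney",
    "summaries_to_frame",
]

#: largest combined sample size for which the exact null distribution is used
EXACT_MAX_N = 12


@dataclass
class MovieSummary:
    movie_id: str
    freq_antero_per_hr: float
    freq_retro_per_hr: float
    flux_antero_um_per_hr: float
    flux_retro_um_per_hr: float
    n_qualifying_tracks: int
    condition: str = ""


def movie_summary(movie: Movie, classes: list[TrackClass],
                  config: AnalysisConfig) -> MovieSummary:
    """Per-movie anterograde/retrograde frequency and flux.

    ``classes`` must hold a :class:`TrackClass` for every qualifying track of
    the movie (non-qualifying entries are ignored).
    """
    if movie.duration_s <= 0:
        raise ValueError("movie duration must be > 0")
    per_hr = 3600.0 / movie.duration_s
    qual = [c for c in classes if c.qualifies]
    n_a = sum(c.direction_class == "anterograde" for c in qual)
    n_r = sum(c.direction_class == "retrograde" for c in qual)
    n_d = sum(c.direction_class == "dual" for c in qual)
    flux_a = sum(c.directed_distance_antero_um for c in qual) * per_hr
    flux_r = sum(c.directed_distance_retro_um for c in qual) * per_hr
    return MovieSummary(
        movie_id=movie.movie_id,
        freq_antero_per_hr=(n_a + n_d) * per_hr,
        freq_retro_per_hr=(n_r + n_d) * per_hr,
        flux_antero_um_per_hr=flux_a,
        flux_retro_um_per_hr=flux_r,
        n_qualifying_tracks=len(qual),
        condition=movie.condition,
    )


def summaries_to_frame(summaries: list[MovieSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


@dataclass
class AggregateResult:
    """Cross-movie means plus histogram count tables per metric."""

    n_movies: int
    mean_freq_antero_per_hr: float
    mean_freq_retro_per_hr: float
    mean_flux_antero_um_per_hr: float
    mean_flux_retro_um_per_hr: float
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]  # metric -> (edges, counts)


def _hist(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # right-most bin is closed on both sides so an expanded final bin
    # ([30, 50], [100, 500]) captures its upper edge
    counts, _ = np.histogram(values, bins=edges)
    return counts


def aggregate(summaries: list[MovieSummary],
              freq_bin_edges: np.ndarray | list | None = None,
              flux_bin_edges: np.ndarray | list | None = None) -> AggregateResult:
    """Aggregate per-movie summaries into means and histogram tables.

    Bin edges may be irregular; by convention the right-most bin can be an
    expanded catch-all (e.g. edges ``[0, 1, ..., 30, 50]`` make the last bin
    span 30-50).  Values above the final edge are not counted.
    """
    if not summaries:
        raise ValueError("need at least one movie summary")
    df = summaries_to_frame(summaries)
    if freq_bin_edges is None:
        freq_bin_edges = np.arange(0.0, 21.0, 1.0)
    if flux_bin_edges is None:
        flux_bin_edges = np.concatenate([np.arange(0.0, 501.0, 25.0)])
    freq_bin_edges = np.asarray(freq_bin_edges, float)
    flux_bin_edges = np.asarray(flux_bin_edges, float)

    histograms = {}
    for metric, edges in [
        ("freq_antero_per_hr", freq_bin_edges),
        ("freq_retro_per_hr", freq_bin_edges),
        ("flux_antero_um_per_hr", flux_bin_edges),
        ("flux_retro_um_per_hr", flux_bin_edges),
    ]:
        histograms[metric] = (edges, _hist(df[metric].to_numpy(), edges))

    return AggregateResult(
        n_movies=len(summaries),
        mean_freq_antero_per_hr=float(df["freq_antero_per_hr"].mean()),
        mean_freq_retro_per_hr=float(df["freq_retro_per_hr"].mean()),
        mean_flux_antero_um_per_hr=float(df["flux_antero_um_per_hr"].mean()),
        mean_flux_retro_um_per_hr=float(df["flux_retro_um_per_hr"].mean()),
        histograms=histograms,
    )


@dataclass
class GroupComparison:
    statistic_U: float
    p_two_sided: float
    n1: int
    n2: int
    effect_direction: int  # +1 if x tends larger than y, -1 smaller, 0 tied
    method: str = ""       # exact | asymptotic


def mann_whitney(x, y) -> GroupComparison:
    """Two-sided Mann-Whitney U test of two independent samples.

    U is the rank-sum statistic of ``x`` (midranks for ties).  The p-value is
    computed by exact enumeration when ``n1 + n2 <= 12`` and the pooled data
    are tie-free, otherwise by the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (n1 + n2 <= EXACT_MAX_N) and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    u = float(res.statistic)
    mid = n1 * n2 / 2.0
    direction = 0 if u == mid else (1 if u > mid else -1)
    return GroupComparison(
        statistic_U=u,
        p_two_sided=float(min(1.0, res.pvalue)),
        n1=int(n1), n2=int(n2),
        effect_direction=direction,
        method="exact" if exact else "asymptotic",
    )
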