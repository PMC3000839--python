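"""Stochastic stop-and-go generator for neurofilament transport movies.

Axonal neurofilaments move in a rapid, intermittent, bidirectional fashion:
bouts of directed motion alternate with pauses, with occasional reversals of
direction.  This module generates whole synthetic movies of such motion, with
ground truth, so that every analysis stage downstream (qualification, bout
segmentation, direction classification, frequency/flux statistics) can be
validated by parameter recovery.

Model
-----
Per movie (default 15 min at 4-s frames), the number of filaments whose
preferred direction is anterograde (resp. retrograde) is Poisson with mean
``freq_per_hr x duration/3600``.  Each filament executes an itinerary

    pause, bout, pause, bout, ..., bout, pause

with a Poisson-distributed number of bouts whose mean is calibrated from the
condition's printed frequency, flux, bout velocity and bout duration (see
:func:`calibrate_bouts_per_filament`).  Bout velocities and durations are
independent Gamma variates with condition- and direction-specific means;
pauses are Exponential.  At each bout boundary the travel direction flips
with a small reversal probability, so a minority of filaments endogenously
spend enough time moving both ways to be classified as bidirectional.
Filament lengths are truncated log-normal.

Durations are quantized to the frame grid by stochastic rounding (floor plus
a Bernoulli on the fractional part), which leaves their means unchanged, and
each itinerary is placed uniformly at random among the start frames that let
it finish inside the movie (itineraries longer than the movie start at frame
zero and are truncated at the last frame, with the affected bouts marked).
Starting and ending each itinerary with a pause means a fully observed bout
is never flush against the track boundary, so the analyzer's boundary-bout
exclusion discards only genuinely truncated bouts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import optimize, stats

from .kymo_eb1 import CometTrace
from .track_core import Movie, Track, DEFAULT_PIXEL_SIZE_UM

__all__ = [
    "ConditionPreset",
    "TruthBout",
    "TrackTruth",
    "SimOutput",
    "PRESETS",
    "get_preset",
    "load_preset",
    "save_preset",
    "calibrate_bouts_per_filament",
    "simulate_movie",
    "simulate_comets",
]

ANTEROGRADE = "anterograde"
RETROGRADE = "retrograde"


@dataclass(frozen=True)
class ConditionPreset:
    """Generative kinetic parameters for one experimental condition.

    Frequencies are qualifying filaments per hour per direction; fluxes are
    total directed distance in um per axon per hour; bout velocity and
    duration means are per-direction.  ``velocity_cv``/``duration_cv`` set
    the Gamma shape (CV 0.5 by default); ``reversal_probability`` is the
    per-bout-boundary chance of a direction flip, calibrated so that about
    97% of filaments keep a >= 70% preferred direction.
    """

    name: str
    freq_antero_per_hr: float
    freq_retro_per_hr: float
    bout_velocity_mean_antero: float  # um/s
    bout_velocity_mean_retro: float   # um/s
    bout_duration_mean_antero: float  # s
    bout_duration_mean_retro: float   # s
    flux_antero_um_per_hr: float
    flux_retro_um_per_hr: float
    pause_duration_mean_s: float = 20.0
    reversal_probability: float = 0.01
    filament_length_mean_um: float = 8.6
    filament_length_range_um: tuple[float, float] = (1.3, 44.5)
    velocity_cv: float = 0.5
    duration_cv: float = 0.5

    def __post_init__(self) -> None:
        positive = [
            self.freq_antero_per_hr, self.freq_retro_per_hr,
            self.bout_velocity_mean_antero, self.bout_velocity_mean_retro,
            self.bout_duration_mean_antero, self.bout_duration_mean_retro,
            self.flux_antero_um_per_hr, self.flux_retro_um_per_hr,
            self.pause_duration_mean_s, self.filament_length_mean_um,
            self.velocity_cv, self.duration_cv,
        ]
        if any(not v > 0 for v in positive):
            raise ValueError(f"preset {self.name!r}: rates and means must be > 0")
        if not 0.0 <= self.reversal_probability < 0.3:
            raise ValueError("reversal_probability must lie in [0, 0.3)")
        lo, hi = self.filament_length_range_um
        if not 0 < lo < hi:
            raise ValueError("filament length range bounds must be ordered, > 0")
        if not lo <= self.filament_length_mean_um <= hi:
            raise ValueError("filament length mean must lie within the range")

    def velocity_mean(self, direction: str) -> float:
        return (self.bout_velocity_mean_antero if direction == ANTEROGRADE
                else self.bout_velocity_mean_retro)

    def duration_mean(self, direction: str) -> float:
        return (self.bout_duration_mean_antero if direction == ANTEROGRADE
                else self.bout_duration_mean_retro)


#: Built-in condition presets, calibrated to the published per-direction
#: frequencies (filaments/hr), fluxes (um/axon/hr), bout velocities (um/s)
#: and bout durations (s) for each experimental arm.
PRESETS: dict[str, ConditionPreset] = {
    "control": ConditionPreset(
        name="control",
        freq_antero_per_hr=4.5, freq_retro_per_hr=3.2,
        bout_velocity_mean_antero=0.27, bout_velocity_mean_retro=0.32,
        bout_duration_mean_antero=19.0, bout_duration_mean_retro=11.0,
        flux_antero_um_per_hr=149.0, flux_retro_um_per_hr=116.0,
    ),
    "n256s": ConditionPreset(
        name="n256s",
        freq_antero_per_hr=1.4, freq_retro_per_hr=2.0,
        bout_velocity_mean_antero=0.24, bout_velocity_mean_retro=0.40,
        bout_duration_mean_antero=19.0, bout_duration_mean_retro=15.0,
        flux_antero_um_per_hr=46.0, flux_retro_um_per_hr=90.0,
    ),
    "wt_overexpression": ConditionPreset(
        name="wt_overexpression",
        freq_antero_per_hr=3.7, freq_retro_per_hr=3.1,
        bout_velocity_mean_antero=0.23, bout_velocity_mean_retro=0.30,
        bout_duration_mean_antero=15.0, bout_duration_mean_retro=14.0,
        flux_antero_um_per_hr=109.0, flux_retro_um_per_hr=105.0,
    ),
}


def get_preset(name: str) -> ConditionPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; built-ins: {sorted(PRESETS)}"
        ) from None


def load_preset(path: str | Path) -> ConditionPreset:
    """Load a ConditionPreset from a JSON file."""
    data = json.loads(Path(path).read_text())
    if "filament_length_range_um" in data:
        data["filament_length_range_um"] = tuple(data["filament_length_range_um"])
    return ConditionPreset(**data)


def save_preset(preset: ConditionPreset, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(asdict(preset), indent=1))
    return path


def calibrate_bouts_per_filament(freq_per_hr: float, flux_um_per_hr: float,
                                 v_mean: float, d_mean: float) -> float:
    """Mean bouts per filament that closes a preset's flux.

    With velocity and duration independent, the expected directed distance
    per filament is ``n_bouts x E[V] x E[D]``, so matching the printed flux
    requires ``n_bouts = flux / (freq x v_mean x d_mean)``.
    """
    if any(not v > 0 for v in (freq_per_hr, flux_um_per_hr, v_mean, d_mean)):
        raise ValueError("all calibration arguments must be > 0")
    return flux_um_per_hr / (freq_per_hr * v_mean * d_mean)


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class TruthBout:
    direction: str            # anterograde | retrograde
    start_s: float            # absolute movie time of the bout's first frame
    end_s: float
    distance_um: float        # unsigned, as observed within the movie
    velocity_um_s: float      # the drawn bout velocity
    truncated: bool = False   # clipped by the end of the movie

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class TrackTruth:
    track_id: str
    primary_direction: str
    bouts: list[TruthBout] = field(default_factory=list)


@dataclass
class SimOutput:
    movie: Movie
    truth: dict[str, TrackTruth]


# ---------------------------------------------------------------------------
# Filament length: truncated log-normal
# ---------------------------------------------------------------------------

#: log-sd of the underlying log-normal; sets the right-skew of the length
#: distribution within the fixed (1.3, 44.5) um observation range
FILAMENT_LENGTH_SIGMA = 0.75


@lru_cache(maxsize=None)
def _lognormal_mu(mean: float, lo: float, hi: float, sigma: float) -> float:
    """Solve for the log-normal location so the (lo, hi)-truncated mean is
    ``mean``."""

    def trunc_mean(mu: float) -> float:
        a = (math.log(lo) - mu) / sigma
        b = (math.log(hi) - mu) / sigma
        z = stats.norm.cdf(b) - stats.norm.cdf(a)
        num = (stats.norm.cdf(b - sigma) - stats.norm.cdf(a - sigma))
        return math.exp(mu + sigma ** 2 / 2) * num / z

    return float(optimize.brentq(
        lambda mu: trunc_mean(mu) - mean,
        math.log(lo) - 5 * sigma, math.log(hi) + 5 * sigma, xtol=1e-12))


def _sample_length(rng: np.random.Generator, mean: float,
                   bounds: tuple[float, float],
                   sigma: float = FILAMENT_LENGTH_SIGMA) -> float:
    lo, hi = bounds
    mu = _lognormal_mu(mean, lo, hi, sigma)
    while True:  # rejection; acceptance probability is high
        x = rng.lognormal(mu, sigma)
        if lo < x < hi:
            return float(x)


# ---------------------------------------------------------------------------
# Movie simulation
# ---------------------------------------------------------------------------

def _stochastic_round(x: np.ndarray, rng: np.random.Generator,
                      minimum: int = 1) -> np.ndarray:
    """Round to integers without changing the mean (floor + Bernoulli on the
    fractional part), then clamp below at ``minimum``."""
    f = np.floor(x)
    out = (f + (rng.random(x.shape) < (x - f))).astype(int)
    return np.maximum(out, minimum)


def _gamma(rng: np.random.Generator, mean: float, cv: float, size: int):
    shape = 1.0 / cv ** 2
    return rng.gamma(shape, mean / shape, size)


def simulate_movie(preset: ConditionPreset, duration_s: float = 900.0,
                   frame_interval_s: float = 4.0, seed: int | None = None,
                   movie_id: str | None = None) -> SimOutput:
    """Generate one synthetic movie plus per-track ground truth.

    ``seed`` is mandatory: identical seeds give bit-identical output.
    """
    if seed is None:
        raise ValueError("a seed is required; simulations must be reproducible")
    rng = np.random.default_rng(seed)
    dt = frame_interval_s
    n_mov_int = int(round(duration_s / dt))  # movie intervals (frames - 1)
    if movie_id is None:
        movie_id = f"{preset.name}-s{seed}"

    n_bouts_mean = {
        ANTEROGRADE: calibrate_bouts_per_filament(
            preset.freq_antero_per_hr, preset.flux_antero_um_per_hr,
            preset.bout_velocity_mean_antero, preset.bout_duration_mean_antero),
        RETROGRADE: calibrate_bouts_per_filament(
            preset.freq_retro_per_hr, preset.flux_retro_um_per_hr,
            preset.bout_velocity_mean_retro, preset.bout_duration_mean_retro),
    }
    hours = duration_s / 3600.0
    n_filaments = {
        ANTEROGRADE: rng.poisson(preset.freq_antero_per_hr * hours),
        RETROGRADE: rng.poisson(preset.freq_retro_per_hr * hours),
    }

    tracks: list[Track] = []
    truth: dict[str, TrackTruth] = {}
    idx = 0
    for primary in (ANTEROGRADE, RETROGRADE):
        for _ in range(n_filaments[primary]):
            tid = f"{movie_id}-t{idx:03d}"
            idx += 1
            track, tr_truth = _simulate_filament(
                rng, preset, primary, tid, movie_id,
                n_bouts_mean[primary], n_mov_int, dt)
            tracks.append(track)
            truth[tid] = tr_truth

    movie = Movie(movie_id=movie_id, duration_s=duration_s,
                  frame_interval_s=dt, pixel_size_um=DEFAULT_PIXEL_SIZE_UM,
                  tracks=tracks, condition=preset.name)
    return SimOutput(movie=movie, truth=truth)


def _simulate_filament(rng, preset, primary, track_id, movie_id,
                       n_bouts_mean, n_mov_int, dt):
    sign0 = +1 if primary == ANTEROGRADE else -1
    n_bouts = int(rng.poisson(n_bouts_mean))

    # direction sequence: flip with reversal_probability at each boundary
    signs = np.empty(n_bouts, dtype=int)
    s = sign0
    for k in range(n_bouts):
        if k > 0 and rng.random() < preset.reversal_probability:
            s = -s
        signs[k] = s

    # per-bout velocity (um/s) and duration (frame intervals)
    velocities = np.empty(n_bouts)
    bout_ints = np.empty(n_bouts, dtype=int)
    for k in range(n_bouts):
        direction = ANTEROGRADE if signs[k] > 0 else RETROGRADE
        velocities[k] = _gamma(rng, preset.velocity_mean(direction),
                               preset.velocity_cv, 1)[0]
        dur = _gamma(rng, preset.duration_mean(direction),
                     preset.duration_cv, 1)[0]
        bout_ints[k] = _stochastic_round(np.array([dur / dt]), rng)[0]

    pause_ints = _stochastic_round(
        rng.exponential(preset.pause_duration_mean_s / dt, n_bouts + 1), rng)

    # interleave: pause, bout, pause, ..., bout, pause
    seg_n, seg_dx, bout_of_seg = [], [], []
    for k in range(n_bouts):
        seg_n.append(pause_ints[k]); seg_dx.append(0.0); bout_of_seg.append(-1)
        seg_n.append(bout_ints[k]); seg_dx.append(signs[k] * velocities[k] * dt)
        bout_of_seg.append(k)
    seg_n.append(pause_ints[-1]); seg_dx.append(0.0); bout_of_seg.append(-1)

    per_interval = np.repeat(np.asarray(seg_dx), np.asarray(seg_n))
    total_int = per_interval.size

    if total_int <= n_mov_int:
        start_frame = int(rng.integers(0, n_mov_int - total_int + 1))
        kept = total_int
    else:
        start_frame = 0
        kept = n_mov_int
        per_interval = per_interval[:kept]

    times = (start_frame + np.arange(kept + 1)) * dt
    x0 = float(rng.uniform(-5.0, 5.0))
    positions = x0 + np.concatenate([[0.0], np.cumsum(per_interval)])

    # ground-truth bouts, clipped to the observed window
    bouts: list[TruthBout] = []
    cursor = 0
    for n_i, dx, k in zip(seg_n, seg_dx, bout_of_seg):
        seg_start, seg_end = cursor, cursor + n_i
        cursor = seg_end
        if k < 0:
            continue
        obs_end = min(seg_end, kept)
        if seg_start >= kept:
            continue  # bout entirely beyond the movie
        n_obs = int(obs_end - seg_start)
        direction = ANTEROGRADE if dx > 0 else RETROGRADE
        bouts.append(TruthBout(
            direction=direction,
            start_s=float((start_frame + seg_start) * dt),
            end_s=float((start_frame + obs_end) * dt),
            distance_um=float(abs(dx) * n_obs),
            velocity_um_s=float(abs(dx) / dt),
            truncated=bool(obs_end < seg_end),
        ))

    length = _sample_length(rng, preset.filament_length_mean_um,
                            preset.filament_length_range_um)
    track = Track(track_id=track_id, times=times, positions=positions,
                  filament_length_um=length, end_tracked="leading",
                  movie_id=movie_id)
    return track, TrackTruth(track_id=track_id, primary_direction=primary,
                             bouts=bouts)


# ---------------------------------------------------------------------------
# EB1 comet simulation
# ---------------------------------------------------------------------------

def simulate_comets(n_comets: int, velocity_mean: float = 0.13,
                    retro_fraction: float = 0.0, duration_s: float = 120.0,
                    frame_interval_s: float = 2.0, seed: int | None = None,
                    velocity_cv: float = 0.2,
                    noise_um: float = 0.0) -> list[CometTrace]:
    """Generate EB1 comet traces moving at constant velocity.

    Speeds are Gamma around ``velocity_mean`` (CV ``velocity_cv``); each
    comet is retrograde (negative slope) with probability ``retro_fraction``.
    ``noise_um`` adds i.i.d. Gaussian localization noise to the positions.
    """
    if n_comets <= 0:
        raise ValueError("n_comets must be > 0")
    if not 0.0 <= retro_fraction <= 1.0:
        raise ValueError("retro_fraction must lie in [0, 1]")
    if seed is None:
        raise ValueError("a seed is required; simulations must be reproducible")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_s + frame_interval_s / 2, frame_interval_s)
    traces = []
    for i in range(n_comets):
        speed = _gamma(rng, velocity_mean, velocity_cv, 1)[0]
        sign = -1.0 if rng.random() < retro_fraction else 1.0
        x0 = rng.uniform(0.0, 10.0)
        pos = x0 + sign * speed * times
        if noise_um > 0:
            pos = pos + rng.normal(0.0, noise_um, times.size)
        traces.append(CometTrace(comet_id=f"c{i:03d}", times=times.copy(),
                                 positions=pos))
    return traces
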