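"""EB1 comet analysis: kymographs, comet velocities, microtubule polarity.

EB1 binds the growing plus end of a microtubule, producing a fluorescent
"comet" that travels at the polymer's growth rate.  The sign of a comet's
axial velocity therefore reports microtubule orientation: anterograde
(positive) comets indicate plus-end-distal microtubules.  Comets in this
model move at constant velocity without pausing, so no bout segmentation is
applied; velocity is the slope of the least-squares line of position against
time over the whole trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "CometTrace",
    "Kymograph",
    "PolarityCensus",
    "build_kymograph",
    "comet_velocity",
    "polarity_census",
    "sample_line",
]


@dataclass
class CometTrace:
    """One EB1 comet trajectory: axial position (um, anterograde positive)
    sampled at regular frame times (seconds; 2-s spacing by default)."""

    comet_id: str
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.size < 2:
            raise ValueError(f"comet {self.comet_id!r}: needs >= 2 frames")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"comet {self.comet_id!r}: times must increase")


@dataclass
class Kymograph:
    """Distance-time intensity map: rows are frames (time), columns are
    positions along the sampling path."""

    intensity: np.ndarray  # shape (n_frames, n_path_samples), >= 0
    time_step_s: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("kymograph intensity must be 2-D (time, position)")
        if np.any(self.intensity < 0):
            raise ValueError("kymograph intensities must be non-negative")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        np.savetxt(path, self.intensity, delimiter=",", fmt="%.6g")
        return path


def sample_line(start: tuple[float, float], end: tuple[float, float],
                spacing_px: float = 1.0) -> np.ndarray:
    """Sample points along a straight line in (row, col) pixel coordinates.

    Returns an (n, 2) array with approximately ``spacing_px`` spacing,
    including both endpoints.
    """
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    length = float(np.hypot(*(end - start)))
    n = max(2, int(round(length / spacing_px)) + 1)
    frac = np.linspace(0.0, 1.0, n)
    return start[None, :] + frac[:, None] * (end - start)[None, :]


def build_kymograph(stack: np.ndarray, axon_line: np.ndarray,
                    time_step_s: float = 2.0,
                    pixel_size_um: float = 0.131) -> Kymograph:
    """Resample an image stack along a path to produce a kymograph.

    Parameters
    ----------
    stack
        Array of shape (n_frames, height, width), equally spaced in time.
    axon_line
        (n, 2) array of (row, col) pixel coordinates along the axon, e.g.
        from :func:`sample_line`; row ``t`` of the kymograph is the linearly
        interpolated intensity profile along this path at frame ``t``.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a non-empty (frames, H, W) array")
    pts = np.asarray(axon_line, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("axon_line must be an (n>=2, 2) array of (row, col)")
    h, w = stack.shape[1:]
    if (pts[:, 0].min() < 0 or pts[:, 0].max() > h - 1
            or pts[:, 1].min() < 0 or pts[:, 1].max() > w - 1):
        raise ValueError("axon_line extends outside the image")
    coords = pts.T  # (2, n) for map_coordinates
    rows = [ndimage.map_coordinates(frame, coords, order=1, mode="nearest")
            for frame in stack]
    return Kymograph(np.clip(np.stack(rows), 0.0, None),
                     time_step_s=time_step_s, pixel_size_um=pixel_size_um)


def comet_velocity(trace: CometTrace) -> float:
    """Signed comet velocity (um/s): least-squares slope of position vs time.

    Positive = anterograde (plus-end-distal growth).
    """
    t = trace.times
    x = trace.positions
    if np.ptp(t) == 0:
        raise ValueError("all times identical; slope undefined")
    slope = np.polyfit(t, x, 1)[0]
    return float(slope)


@dataclass(frozen=True)
class PolarityCensus:
    n_anterograde: int
    n_retrograde: int
    n_flagged: int  # zero-velocity traces, reported separately

    @property
    def n_total(self) -> int:
        return self.n_anterograde + self.n_retrograde + self.n_flagged


def polarity_census(traces: list[CometTrace]) -> PolarityCensus:
    """Count comets by direction of travel.

    Traces with exactly zero fitted velocity are excluded from both counts
    and reported in ``n_flagged``.
    """
    if not traces:
        raise ValueError("need at least one comet trace")
    v = np.array([comet_velocity(tr) for tr in traces])
    return PolarityCensus(
        n_anterograde=int(np.sum(v > 0)),
        n_retrograde=int(np.sum(v < 0)),
        n_flagged=int(np.sum(v == 0)),
    )
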