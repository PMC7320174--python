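"""Ring kymograph construction.

The workflow mirrors the semi-manual analysis of FtsZ vortices on
supported bilayers: temporally average the time-lapse, correct lateral
drift, define each ring from two clicked coordinates, sample the
intensity along three concentric circular trajectories (r − 1, r, r + 1
pixels), and average the three resulting kymographs into one
time × arc-position matrix whose stripe slope encodes the treadmilling
velocity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .simulate import ConfigError, MovieStack

__all__ = [
    "RingROI",
    "Kymograph",
    "temporal_average",
    "spatial_mean_filter",
    "drift_correct",
    "circle_from_two_points",
    "sample_trajectory",
    "build_kymograph",
    "write_kymograph",
    "read_rois",
    "write_rois",
]

logger = logging.getLogger(__name__)


@dataclass
class RingROI:
    """A sub-pixel circle defining one ring's sampling geometry.

    ``n_arc_samples`` defaults to round(2π·radius_px): one sample per
    pixel of arc length, so kymograph columns are commensurate with
    pixel-denominated windows (the "r ± 1 pixels" trajectories and
    50-pixel analysis regions).
    """

    center: tuple[float, float]       # (row, col)
    radius_px: float
    n_arc_samples: int | None = None

    def __post_init__(self) -> None:
        if self.radius_px < 2:
            raise ConfigError(
                "radius_px: must be >= 2 px (the r-1 trajectory needs room)"
            )
        if self.n_arc_samples is None:
            self.n_arc_samples = max(8, round(2.0 * math.pi * self.radius_px))
        if self.n_arc_samples < 8:
            raise ConfigError("n_arc_samples: must be >= 8")

    def check_inside(self, shape: tuple[int, int], margin: float = 1.0) -> None:
        """Raise if the circle plus ``margin`` px leaves the image."""
        h, w = shape
        r = self.radius_px + margin
        row, col = self.center
        if row - r < 0 or col - r < 0 or row + r > h - 1 or col + r > w - 1:
            raise ConfigError(
                f"circle (center={self.center}, radius={self.radius_px:.2f} px) "
                f"plus {margin:.0f}-px margin exceeds the {h}x{w} image bounds"
            )

    def sample_points(self, radius_offset: float = 0.0) -> np.ndarray:
        """(2, n) array of (row, col) sample coordinates on the circle."""
        theta = 2.0 * np.pi * np.arange(self.n_arc_samples) / self.n_arc_samples
        rho = self.radius_px + radius_offset
        rows = self.center[0] + rho * np.sin(theta)
        cols = self.center[1] + rho * np.cos(theta)
        return np.stack([rows, cols])


@dataclass
class Kymograph:
    """Time × arc-position intensity matrix with physical calibration.

    Rows are time points (``frame_interval`` s apart); columns are arc
    positions (``arc_step`` nm apart) and wrap cyclically (column N is
    adjacent to column 0).
    """

    data: np.ndarray
    arc_step: float          # nm per column
    frame_interval: float    # s per row

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ConfigError("data: kymograph must be 2-D (time x arc)")
        if self.arc_step <= 0 or self.frame_interval <= 0:
            raise ConfigError("arc_step and frame_interval must be > 0")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def temporal_average(movie: MovieStack, window: int) -> MovieStack:
    """Average non-overlapping blocks of ``window`` frames.

    The trailing partial block is dropped and the frame interval scales by
    ``window``.  ``window=1`` is the identity.
    """
    t = movie.n_frames
    if not 1 <= window <= t:
        raise ConfigError(f"window: must be in [1, {t}], got {window}")
    n_blocks = t // window
    data = movie.data[: n_blocks * window]
    data = data.reshape(n_blocks, window, *movie.data.shape[1:]).mean(axis=1)
    return MovieStack(data, movie.pixel_size, movie.frame_interval * window)


def spatial_mean_filter(movie: MovieStack, size: int = 3) -> MovieStack:
    """Optional per-frame ``size``×``size`` mean filter (off by default
    in the pipeline)."""
    data = ndimage.uniform_filter(movie.data, size=(1, size, size))
    return MovieStack(data, movie.pixel_size, movie.frame_interval)


def drift_correct(
    movie: MovieStack, upsample_factor: int = 20
) -> tuple[MovieStack, np.ndarray]:
    """Register every frame to frame 0 by phase correlation.

    Shifts are estimated to sub-pixel precision and applied by bilinear
    interpolation; regions shifted in from outside the frame are filled
    with that frame's median.  Returns the corrected movie and the applied
    (row, col) shift per frame.
    """
    if movie.n_frames < 2:
        raise ConfigError("drift_correct: need at least 2 frames")
    ref = movie.data[0]
    shifts = np.zeros((movie.n_frames, 2))
    out = np.empty_like(movie.data)
    out[0] = ref
    degenerate = ref.std() == 0
    for t in range(1, movie.n_frames):
        frame = movie.data[t]
        if degenerate or frame.std() == 0:
            logger.warning("drift_correct: constant frame %d, zero shift", t)
            out[t] = frame
            continue
        shift, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=upsample_factor, normalization=None
        )
        shifts[t] = shift
        out[t] = ndimage.shift(
            frame, shift, order=1, mode="constant", cval=float(np.median(frame))
        )
        out[t] = np.clip(out[t], 0.0, None)
    return MovieStack(out, movie.pixel_size, movie.frame_interval), shifts


# ---------------------------------------------------------------------------
# ring geometry and sampling
# ---------------------------------------------------------------------------

def circle_from_two_points(
    p1: tuple[float, float],
    p2: tuple[float, float],
    image_shape: tuple[int, int] | None = None,
    mode: str = "diameter",
) -> RingROI:
    """Build a :class:`RingROI` from two user coordinates.

    In the default ``diameter`` mode the two points are opposite ends of a
    diameter (center = midpoint, radius = half the distance).  In
    ``center_edge`` mode ``p1`` is the center and ``p2`` a point on the
    circumference.
    """
    p1 = (float(p1[0]), float(p1[1]))
    p2 = (float(p2[0]), float(p2[1]))
    if p1 == p2:
        raise ConfigError("p1 and p2 must be distinct points")
    d = math.hypot(p2[0] - p1[0], p2[1] - p1[1])
    if mode == "diameter":
        center = ((p1[0] + p2[0]) / 2.0, (p1[1] + p2[1]) / 2.0)
        radius = d / 2.0
    elif mode == "center_edge":
        center, radius = p1, d
    else:
        raise ConfigError(f"mode: unknown mode {mode!r}")
    roi = RingROI(center=center, radius_px=radius)
    if image_shape is not None:
        roi.check_inside(image_shape)
    return roi


def sample_trajectory(
    frame: np.ndarray, roi: RingROI, radius_offset: float = 0.0
) -> np.ndarray:
    """Bilinearly sample one circular trajectory on a single frame.

    Sample j sits at center + (radius+offset)·(sin θ_j, cos θ_j) with
    θ_j = 2πj/n; bilinear interpolation is exact on affine images, which
    the tests exploit.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ConfigError("frame: expected a 2-D image")
    pts = roi.sample_points(radius_offset)
    h, w = frame.shape
    if (pts[0].min() < 0 or pts[1].min() < 0
            or pts[0].max() > h - 1 or pts[1].max() > w - 1):
        raise ConfigError("trajectory sample points fall outside the image")
    return ndimage.map_coordinates(frame, pts, order=1, mode="nearest")


def build_kymograph(movie: MovieStack, roi: RingROI) -> Kymograph:
    """Average the r−1, r, r+1 px trajectory kymographs into one.

    Row t of the result is the mean over the three concentric trajectories
    of the circular intensity profile of frame t.
    """
    roi.check_inside(movie.data.shape[1:])
    rows = np.empty((movie.n_frames, roi.n_arc_samples))
    offsets = (-1.0, 0.0, 1.0)
    for t in range(movie.n_frames):
        frame = movie.data[t]
        rows[t] = np.mean(
            [sample_trajectory(frame, roi, off) for off in offsets], axis=0
        )
    arc_step = 2.0 * math.pi * roi.radius_px * movie.pixel_size / roi.n_arc_samples
    return Kymograph(rows, arc_step=arc_step, frame_interval=movie.frame_interval)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_kymograph(kymo: Kymograph, path: str | Path) -> Path:
    """Write a kymograph as float TIFF plus a CSV with calibration header."""
    path = Path(path)
    tifffile.imwrite(path.with_suffix(".tif"), kymo.data.astype(np.float32))
    with open(path.with_suffix(".csv"), "w") as fh:
        fh.write(f"# arc_step_nm={kymo.arc_step}\n")
        fh.write(f"# frame_interval_s={kymo.frame_interval}\n")
        pd.DataFrame(kymo.data).to_csv(fh, header=False, index=False)
    return path.with_suffix(".tif")


def read_rois(path: str | Path) -> list[tuple[tuple[float, float], tuple[float, float]]]:
    """Read ring point pairs from CSV (p1_row, p1_col, p2_row, p2_col)."""
    df = pd.read_csv(path)
    required = ["p1_row", "p1_col", "p2_row", "p2_col"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ConfigError(f"ROI CSV missing columns: {missing}")
    return [
        ((r.p1_row, r.p1_col), (r.p2_row, r.p2_col)) for r in df.itertuples()
    ]


def write_rois(pairs, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"p1_row": p1[0], "p1_col": p1[1], "p2_row": p2[0], "p2_col": p2[1]}
        for p1, p2 in pairs
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
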