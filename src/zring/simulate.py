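"""Synthetic data with known ground truth.

Three generators cover the three experimental readouts the package
analyses:

* :func:`simulate_ring_movie` — a TIRF-like time-lapse of a single
  membrane-bound FtsZ ring ("vortex").  The ring is a kinematic rotating
  pattern: an annulus with a radial Gaussian profile whose azimuthal
  intensity is cos²-modulated, rigidly rotated frame to frame.  The image
  model is expectation → Gaussian PSF → photobleaching/drift → Poisson
  shot noise (plus optional Gaussian read noise).  No polymerisation
  kinetics are simulated; treadmilling enters only as the rotation speed.
* :func:`simulate_qcmd_trace` — a QCM-D frequency-shift time series with
  the canonical supported-lipid-bilayer (SLB) formation signature
  (vesicle-adsorption overshoot relaxing to a plateau) followed by a
  protein-binding step.
* :func:`simulate_gtpase_plate` — a colorimetric phosphate-release plate:
  a 1:2 serial-dilution standard curve plus a linear Pi-production time
  course pushed through the same absorbance calibration.

Every generator is deterministic under its ``seed`` and can emit noise-free
expectations for oracle tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
import tifffile

__all__ = [
    "RingSimConfig",
    "MovieStack",
    "QcmdTrace",
    "simulate_ring_movie",
    "ring_expectation_frame",
    "simulate_qcmd_trace",
    "simulate_gtpase_plate",
    "write_movie",
    "read_movie",
]


class ConfigError(ValueError):
    """A simulation/analysis configuration field is invalid."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MovieStack:
    """A T×H×W intensity stack with physical calibration.

    Attributes
    ----------
    data : ndarray, shape (T, H, W)
        Non-negative intensities (photons or camera counts).
    pixel_size : float
        Lateral calibration in nm per pixel.
    frame_interval : float
        Time between frames in seconds.
    """

    data: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ConfigError("data: expected a T×H×W stack with T >= 1")
        if not np.all(np.isfinite(self.data)) or np.any(self.data < 0):
            raise ConfigError("data: intensities must be finite and >= 0")
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size: must be > 0")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval: must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class QcmdTrace:
    """One overtone's frequency-shift time series.

    ``delta_f`` follows the raw-export convention unless ``normalized`` is
    True, in which case values are already divided by the overtone order n
    (the conventional way QCM-D shifts are reported and the scale on which
    the 25 ± 1 Hz SLB criterion is checked).
    """

    time: np.ndarray
    delta_f: np.ndarray
    overtone: int = 9
    normalized: bool = True
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.delta_f = np.asarray(self.delta_f, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.delta_f.shape:
            raise ConfigError("time and delta_f must be 1-D and equally long")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise ConfigError("time: must be strictly increasing")
        if self.overtone < 1 or self.overtone % 2 == 0:
            raise ConfigError("overtone: must be an odd integer >= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "delta_f_hz": self.delta_f})


# ---------------------------------------------------------------------------
# ring movie
# ---------------------------------------------------------------------------

@dataclass
class RingSimConfig:
    """Parameters of the synthetic rotating-ring movie.

    Defaults describe the imaging conditions the analysis is designed for:
    a ~1 µm diameter FtsZ vortex on a supported bilayer imaged by TIRF at
    65 nm/px (6.5 µm sCMOS pixel behind a 100× objective) every 3 s, with a
    diffraction-limited PSF (σ ≈ 110 nm for 488 nm excitation at NA 1.49).

    ``speed`` is the circumferential (treadmilling) velocity in nm/s along
    the ring; positive means counter-clockwise in image coordinates (angle
    measured from the +col axis toward +row).  The ground-truth angular
    speed is ``speed / radius`` rad/s.

    The azimuthal pattern is cos²(π·s/pattern_period) along the arc length
    s, which is non-negative (a valid Poisson mean) and has period
    ``pattern_period``.  The period is adjusted at construction so that an
    integer number of periods fits on the circumference, keeping the
    pattern continuous across the 0/2π seam.
    """

    image_size: tuple[int, int] = (64, 64)
    pixel_size: float = 65.0            # nm/px
    frame_interval: float = 3.0         # s
    n_frames: int = 120
    center: tuple[float, float] = (31.5, 31.5)   # (row, col), sub-pixel
    radius: float = 500.0               # nm
    speed: float = 35.0                 # nm/s, signed
    pattern_period: float = 600.0       # nm along the circumference
    ring_width: float = 100.0           # nm, radial Gaussian sigma
    psf_sigma: float = 110.0            # nm
    peak_photons: float = 200.0         # photons/px at pattern maxima
    background_photons: float = 20.0    # photons/px off-ring
    bleach_rate: float = 5e-4           # 1/s
    drift_velocity: tuple[float, float] = (0.0, 0.0)  # nm/s, (row, col)
    read_noise_sd: float = 0.0          # camera counts, Gaussian
    noise: bool = True                  # False → emit expectation images
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ConfigError("radius: must be > 0")
        if self.pattern_period <= 0:
            raise ConfigError("pattern_period: must be > 0")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval: must be > 0")
        if self.n_frames < 2:
            raise ConfigError("n_frames: must be >= 2")
        if self.pixel_size <= 0:
            raise ConfigError("pixel_size: must be > 0")
        if self.ring_width <= 0:
            raise ConfigError("ring_width: must be > 0")
        if self.psf_sigma < 0:
            raise ConfigError("psf_sigma: must be >= 0")
        if self.bleach_rate < 0:
            raise ConfigError("bleach_rate: must be >= 0")
        if self.read_noise_sd < 0:
            raise ConfigError("read_noise_sd: must be >= 0")
        if not (self.peak_photons > self.background_photons >= 0):
            raise ConfigError(
                "peak_photons: need peak_photons > background_photons >= 0"
            )
        # snap the period so an integer number of periods tiles the circle
        circumference = 2.0 * math.pi * self.radius
        n_periods = max(1, round(circumference / self.pattern_period))
        self.pattern_period = circumference / n_periods

    @property
    def n_pattern_periods(self) -> int:
        return round(2.0 * math.pi * self.radius / self.pattern_period)

    @property
    def angular_speed(self) -> float:
        """Ground-truth rotation rate, rad/s (positive = CCW)."""
        return self.speed / self.radius


def ring_expectation_frame(config: RingSimConfig, t_index: int) -> np.ndarray:
    """Noise-free expected image (photons/px) of frame ``t_index``."""
    h, w = config.image_size
    t = t_index * config.frame_interval
    drift_px = (
        config.drift_velocity[0] * t / config.pixel_size,
        config.drift_velocity[1] * t / config.pixel_size,
    )
    c_row = config.center[0] + drift_px[0]
    c_col = config.center[1] + drift_px[1]

    rows = np.arange(h)[:, None] - c_row
    cols = np.arange(w)[None, :] - c_col
    rho = np.hypot(rows, cols) * config.pixel_size          # nm from center
    theta = np.arctan2(rows, cols)                          # from +col toward +row

    # rigid rotation of the azimuthal pattern
    theta_rel = theta - config.angular_speed * t
    arc = config.radius * theta_rel
    azimuthal = np.cos(np.pi * arc / config.pattern_period) ** 2
    radial = np.exp(-0.5 * ((rho - config.radius) / config.ring_width) ** 2)

    amplitude = config.peak_photons - config.background_photons
    amplitude *= math.exp(-config.bleach_rate * t)
    ring = amplitude * radial * azimuthal

    if config.psf_sigma > 0:
        ring = ndimage.gaussian_filter(ring, config.psf_sigma / config.pixel_size)
    return ring + config.background_photons


def simulate_ring_movie(config: RingSimConfig) -> MovieStack:
    """Render the synthetic rotating-ring movie described by ``config``.

    Returns a :class:`MovieStack`; with ``config.noise`` False the frames
    are the Poisson means themselves (the oracle images).
    """
    frames = np.stack(
        [ring_expectation_frame(config, t) for t in range(config.n_frames)]
    )
    if config.noise:
        rng = np.random.default_rng(config.seed)
        frames = rng.poisson(frames).astype(float)
        if config.read_noise_sd > 0:
            frames = frames + rng.normal(0.0, config.read_noise_sd, frames.shape)
            frames = np.clip(frames, 0.0, None)
    return MovieStack(frames, config.pixel_size, config.frame_interval)


# ---------------------------------------------------------------------------
# movie IO: multi-page 16-bit TIFF + side-car metadata
# ---------------------------------------------------------------------------

def write_movie(movie: MovieStack, path: str | Path,
                ground_truth: dict | None = None) -> Path:
    """Write a movie as 16-bit multi-page TIFF plus a JSON side-car.

    The side-car ``<stem>.meta.json`` carries pixel size and frame
    interval; ``ground_truth``, if given, is stored in a
    ``<stem>.truth.json`` manifest.
    """
    path = Path(path)
    data = np.clip(np.round(movie.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {
        "pixel_size_nm": movie.pixel_size,
        "frame_interval_s": movie.frame_interval,
        "n_frames": movie.n_frames,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))
    if ground_truth is not None:
        path.with_suffix(".truth.json").write_text(
            json.dumps(ground_truth, indent=2, default=float)
        )
    return path


def read_movie(path: str | Path) -> MovieStack:
    """Read a TIFF movie written by :func:`write_movie` (with side-car)."""
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None]
    meta = json.loads(path.with_suffix(".meta.json").read_text())
    return MovieStack(data, meta["pixel_size_nm"], meta["frame_interval_s"])


# ---------------------------------------------------------------------------
# QCM-D trace
# ---------------------------------------------------------------------------

def simulate_qcmd_trace(
    baseline_s: float = 300.0,
    slb_shift_hz: float = 25.0,
    protein_shift_hz: float = 12.0,
    noise_sd_hz: float = 0.2,
    sample_rate: float = 1.0,
    total_s: float | None = None,
    overshoot_hz: float = 10.0,
    tau_s: float = 60.0,
    overtone: int = 9,
    seed: int = 0,
) -> QcmdTrace:
    """Simulate a normalized (Δf/n) QCM-D trace of SLB formation + binding.

    Segments: flat baseline at 0 for ``baseline_s``; vesicle adsorption
    overshooting below −``slb_shift_hz`` by ``overshoot_hz`` and relaxing
    exponentially (time constant ``tau_s``) to the −``slb_shift_hz``
    plateau; protein injection driving an exponential approach to
    −(slb_shift + protein_shift).  Gaussian noise of sd ``noise_sd_hz`` is
    added throughout.  Segment boundaries are recorded in
    ``trace.annotations`` as ground truth.
    """
    if sample_rate <= 0:
        raise ConfigError("sample_rate: must be > 0")
    if noise_sd_hz < 0:
        raise ConfigError("noise_sd_hz: must be >= 0")
    slb_settle = 6.0 * tau_s
    protein_settle = 6.0 * tau_s
    t_vesicle = baseline_s
    t_protein = t_vesicle + slb_settle + baseline_s   # hold SLB plateau a while
    if total_s is None:
        total_s = t_protein + protein_settle + baseline_s

    t = np.arange(0.0, total_s, 1.0 / sample_rate)
    f = np.zeros_like(t)

    seg = t >= t_vesicle
    dt = t[seg] - t_vesicle
    # fast drop to -(slb + overshoot), slow relaxation back up to -slb:
    # the classic vesicle-rupture overshoot
    tau_fast = tau_s / 6.0
    f[seg] = (
        -(slb_shift_hz + overshoot_hz) * (1.0 - np.exp(-dt / tau_fast))
        + overshoot_hz * (1.0 - np.exp(-dt / tau_s))
    )

    seg = t >= t_protein
    dt = t[seg] - t_protein
    f[seg] += -protein_shift_hz * (1.0 - np.exp(-dt / tau_s))

    if noise_sd_hz > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd_hz, f.shape)

    return QcmdTrace(
        time=t,
        delta_f=f,
        overtone=overtone,
        normalized=True,
        annotations={
            "t_vesicle_injection_s": t_vesicle,
            "t_protein_injection_s": t_protein,
            "slb_plateau_hz": -slb_shift_hz,
            "final_plateau_hz": -(slb_shift_hz + protein_shift_hz),
            "protein_shift_hz": -protein_shift_hz,
        },
    )


# ---------------------------------------------------------------------------
# GTPase plate
# ---------------------------------------------------------------------------

def simulate_gtpase_plate(
    rate_uM_per_s: float = 0.05,
    timepoints: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0, 120.0),
    std_top_uM: float = 40.0,
    n_std: int = 7,
    curve_slope: float = 0.02,      # AU/µM
    curve_intercept: float = 0.05,  # AU
    noise_sd: float = 0.0,          # AU
    seed: int = 0,
) -> dict:
    """Simulate a phosphate-release assay plate.

    Standards are a 1:2 serial dilution from ``std_top_uM`` (``n_std``
    points) plus a blank; the sample series is [Pi](t) = rate·t pushed
    through the same linear absorbance calibration.  Returns a dict with
    ``standards`` and ``samples`` DataFrames plus the ground truth.
    """
    timepoints = np.asarray(timepoints, dtype=float)
    if timepoints.size < 2 or not np.all(np.diff(timepoints) > 0):
        raise ConfigError("timepoints: must be strictly increasing")
    if n_std < 4:
        raise ConfigError("n_std: must be >= 4")

    rng = np.random.default_rng(seed)

    conc = std_top_uM * 0.5 ** np.arange(n_std)
    conc = np.append(conc, 0.0)  # blank
    std_abs = curve_slope * conc + curve_intercept
    if noise_sd > 0:
        std_abs = std_abs + rng.normal(0.0, noise_sd, std_abs.shape)
    standards = pd.DataFrame({"conc_uM": conc, "absorbance_AU": std_abs})

    pi = rate_uM_per_s * timepoints
    sample_abs = curve_slope * pi + curve_intercept
    if noise_sd > 0:
        sample_abs = sample_abs + rng.normal(0.0, noise_sd, sample_abs.shape)
    samples = pd.DataFrame({"time_s": timepoints, "absorbance_AU": sample_abs})

    return {
        "standards": standards,
        "samples": samples,
        "truth": {
            "rate_uM_per_s": rate_uM_per_s,
            "curve_slope": curve_slope,
            "curve_intercept": curve_intercept,
            "blank_AU": curve_intercept,
        },
    }
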