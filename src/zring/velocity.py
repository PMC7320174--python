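"""Physical treadmilling velocities and per-ring records.

Converts kymograph stripe slopes (columns/row) into circumferential
velocities (nm/s) using the kymograph calibration, estimates ring
diameters from the radial intensity profile of the time-averaged image,
classifies rings as static or dynamic, and aggregates per-condition
distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .simulate import ConfigError, MovieStack
from .kymo import Kymograph, RingROI
from .slope import SlopeEstimate

__all__ = [
    "VelocityRecord",
    "slope_to_velocity",
    "estimate_ring_diameter",
    "classify_static",
    "make_record",
    "aggregate_records",
    "STATIC_THRESHOLD_NM_S",
]

# Below this circumferential speed a ring is reported as static; the truly
# static phenotype is normally caught earlier by window rejection (no
# reliable slope), this gate covers near-zero fitted slopes.
STATIC_THRESHOLD_NM_S = 5.0


@dataclass
class VelocityRecord:
    """One ring's aggregate quantities."""

    ring_id: str
    velocity: float            # nm/s, signed (positive = CCW)
    diameter: float            # nm
    static_flag: bool
    n_windows_accepted: int

    @property
    def speed(self) -> float:
        return abs(self.velocity) if np.isfinite(self.velocity) else float("nan")


def slope_to_velocity(estimate: SlopeEstimate, kymo: Kymograph) -> float:
    """velocity [nm/s] = slope [col/row] × arc_step [nm/col] / frame_interval [s/row].

    NaN when the estimate carries no reliable slope.
    """
    if kymo.arc_step <= 0 or kymo.frame_interval <= 0:
        raise ConfigError("kymograph is not calibrated")
    if not estimate.has_slope:
        return float("nan")
    return estimate.mean_slope * kymo.arc_step / kymo.frame_interval


def estimate_ring_diameter(
    movie: MovieStack,
    roi: RingROI,
    search_halfwidth_px: float | None = None,
    radial_step_px: float = 0.25,
) -> float:
    """Ring diameter in nm from the angular-averaged radial profile.

    The center is refined by the intensity-weighted centroid of the
    background-subtracted time-average in a window around the ROI; the
    diameter is twice the radius of the profile maximum, located with
    parabolic sub-pixel refinement.
    """
    roi.check_inside(movie.data.shape[1:])
    mean_img = movie.data.mean(axis=0)
    h, w = mean_img.shape
    if search_halfwidth_px is None:
        search_halfwidth_px = roi.radius_px + 2.0

    r0 = int(round(roi.center[0]))
    c0 = int(round(roi.center[1]))
    half = int(math.ceil(search_halfwidth_px))
    rlo, rhi = max(0, r0 - half), min(h, r0 + half + 1)
    clo, chi = max(0, c0 - half), min(w, c0 + half + 1)
    patch = mean_img[rlo:rhi, clo:chi]
    weights = np.clip(patch - patch.min(), 0.0, None)
    if weights.sum() == 0:
        center = roi.center
    else:
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        center = (
            float((rr * weights).sum() / weights.sum()),
            float((cc * weights).sum() / weights.sum()),
        )

    max_radius = min(roi.radius_px * 1.8, roi.radius_px + 6.0)
    radii = np.arange(radial_step_px, max_radius, radial_step_px)
    theta = 2.0 * np.pi * np.arange(max(64, roi.n_arc_samples)) / max(64, roi.n_arc_samples)
    profile = np.empty(radii.size)
    for i, rho in enumerate(radii):
        rows = center[0] + rho * np.sin(theta)
        cols = center[1] + rho * np.cos(theta)
        rows = np.clip(rows, 0, h - 1)
        cols = np.clip(cols, 0, w - 1)
        profile[i] = ndimage.map_coordinates(
            mean_img, np.stack([rows, cols]), order=1
        ).mean()

    k = int(np.argmax(profile))
    if k == 0 or k == radii.size - 1:
        raise ConfigError("radial profile has no interior maximum; not a ring")
    y0, y1, y2 = profile[k - 1:k + 2]
    denom = y0 - 2 * y1 + y2
    delta = 0.5 * (y0 - y2) / denom if denom < 0 else 0.0
    radius_px = radii[k] + delta * radial_step_px
    return 2.0 * radius_px * movie.pixel_size


def classify_static(
    estimate: SlopeEstimate | None,
    velocity_nm_s: float,
    threshold_nm_s: float = STATIC_THRESHOLD_NM_S,
) -> bool:
    """static ⇔ no reliable slope, or |velocity| below the threshold."""
    if threshold_nm_s < 0:
        raise ConfigError("threshold_nm_s: must be >= 0")
    if estimate is not None and not estimate.has_slope:
        return True
    if not np.isfinite(velocity_nm_s):
        return True
    return abs(velocity_nm_s) < threshold_nm_s


def make_record(
    ring_id: str,
    estimate: SlopeEstimate,
    kymo: Kymograph,
    diameter_nm: float,
    threshold_nm_s: float = STATIC_THRESHOLD_NM_S,
) -> VelocityRecord:
    v = slope_to_velocity(estimate, kymo)
    return VelocityRecord(
        ring_id=ring_id,
        velocity=v,
        diameter=diameter_nm,
        static_flag=classify_static(estimate, v, threshold_nm_s),
        n_windows_accepted=int(estimate.accepted_mask.sum()),
    )


def aggregate_records(records: list[VelocityRecord]) -> pd.DataFrame:
    """Per-ring results table (speeds reported unsigned, sign retained
    in the velocity column)."""
    return pd.DataFrame(
        [
            {
                "ring_id": r.ring_id,
                "velocity_nm_s": r.velocity,
                "speed_nm_s": r.speed,
                "diameter_nm": r.diameter,
                "static": r.static_flag,
                "n_windows_accepted": r.n_windows_accepted,
            }
            for r in records
        ]
    )
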