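"""GTPase activity from colorimetric phosphate-release plates.

A malachite-green-type reagent reports inorganic phosphate as absorbance
at 620 nm.  A 1:2 serial-dilution Pi standard curve calibrates absorbance
to concentration; the sample time course (reaction aliquots quenched into
stop solution at fixed intervals) is converted to [Pi](t) and the initial
production rate fitted by ordinary least squares.  Rates are reported for
the stopped well, for the reaction (dilution-corrected), as turnover per
enzyme, and normalized to a reference construct.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ConfigError

__all__ = [
    "StandardCurve",
    "ActivityResult",
    "fit_standard_curve",
    "activity_from_timeseries",
    "DEFAULT_DILUTION_FACTOR",
    "DEFAULT_FTSZ_UM",
    "read_plate_csv",
]

# 13 µL quenched into 37 µL stop solution → 50/13-fold dilution in the well
DEFAULT_DILUTION_FACTOR = 50.0 / 13.0
DEFAULT_FTSZ_UM = 5.0


@dataclass
class StandardCurve:
    slope: float            # AU/µM
    intercept: float        # AU (after blank subtraction)
    r2: float
    concentrations: np.ndarray

    def to_concentration(self, absorbance: np.ndarray, blank: float = 0.0) -> np.ndarray:
        """Invert the calibration: [Pi] = (A − blank − intercept)/slope."""
        if self.slope <= 0:
            raise ConfigError("standard curve slope must be > 0 to invert")
        return (np.asarray(absorbance, dtype=float) - blank - self.intercept) / self.slope


@dataclass
class ActivityResult:
    rate_well: float          # µM Pi/s in the stopped well
    rate_reaction: float      # µM Pi/s in the reaction
    turnover: float           # mol Pi / mol enzyme / min
    normalized: float | None  # fraction of reference rate
    rate_r2: float
    negative_rate_warning: bool


def fit_standard_curve(
    concentrations: np.ndarray,
    absorbances: np.ndarray,
    blank: float = 0.0,
) -> StandardCurve:
    """OLS fit of blank-subtracted absorbance against concentration."""
    conc = np.asarray(concentrations, dtype=float)
    absorb = np.asarray(absorbances, dtype=float) - blank
    if conc.size < 4:
        raise ConfigError("need at least 4 standards")
    if np.unique(conc).size < 2:
        raise ConfigError("standards are degenerate: all concentrations equal")
    fit = stats.linregress(conc, absorb)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        concentrations=conc,
    )


def activity_from_timeseries(
    timepoints: np.ndarray,
    absorbances: np.ndarray,
    curve: StandardCurve,
    blank: float = 0.0,
    dilution_factor: float = DEFAULT_DILUTION_FACTOR,
    ftsz_conc_uM: float = DEFAULT_FTSZ_UM,
    reference_rate_uM_s: float | None = None,
) -> ActivityResult:
    """Pi-production rate from a quenched time series.

    rate_well is the OLS slope of [Pi] versus time in the stopped wells;
    rate_reaction = rate_well × dilution_factor; turnover converts to
    mol Pi per mol enzyme per minute.  A negative fitted rate is returned
    with a warning flag rather than clamped.
    """
    t = np.asarray(timepoints, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if t.size < 3 or not np.all(np.diff(t) > 0):
        raise ConfigError("timepoints: need >= 3 strictly increasing values")
    if t.shape != a.shape:
        raise ConfigError("timepoints and absorbances lengths differ")
    if curve.slope <= 0:
        raise ConfigError("standard curve slope must be > 0")
    pi = curve.to_concentration(a, blank=blank)
    fit = stats.linregress(t, pi)
    rate_well = float(fit.slope)
    rate_reaction = rate_well * dilution_factor
    turnover = rate_reaction * 60.0 / ftsz_conc_uM
    normalized = None
    if reference_rate_uM_s is not None:
        if reference_rate_uM_s == 0:
            raise ConfigError("reference rate is zero; cannot normalize")
        normalized = rate_reaction / reference_rate_uM_s
    return ActivityResult(
        rate_well=rate_well,
        rate_reaction=rate_reaction,
        turnover=turnover,
        normalized=normalized,
        rate_r2=float(fit.rvalue**2) if np.std(pi) > 0 else 1.0,
        negative_rate_warning=rate_well < 0,
    )


def read_plate_csv(path) -> pd.DataFrame:
    """Read a long-format plate CSV (series, conc_or_time, absorbance)."""
    df = pd.read_csv(path, comment="#")
    required = {"series", "conc_or_time", "absorbance"}
    if not required.issubset(df.columns):
        raise ConfigError(f"plate CSV needs columns {sorted(required)}")
    return df
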