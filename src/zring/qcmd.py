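"""QCM-D frequency-trace analysis.

Adsorption of mass to a quartz sensor lowers its resonance frequency; for
a thin rigid film the Sauerbrey relation makes the areal mass density
proportional to the (overtone-normalized) frequency shift,
Δm = −C·Δf/n with C ≈ 17.7 ng cm⁻² Hz⁻¹ for a 5 MHz AT-cut crystal.

This module verifies supported-lipid-bilayer formation from its
characteristic −25 ± 1 Hz plateau, extracts protein-binding shifts as
plateau-minus-baseline medians, converts them to ng/cm² coverages, and
tabulates concentration series with fold changes between constructs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import ConfigError, QcmdTrace

__all__ = [
    "SAUERBREY_SENSITIVITY",
    "sauerbrey_coverage",
    "detect_slb_formation",
    "extract_binding_shift",
    "fold_changes",
    "format_fold",
    "read_trace_csv",
    "write_coverage_table",
]

#: Mass sensitivity of a 5 MHz AT-cut quartz crystal, ng/(cm²·Hz).
SAUERBREY_SENSITIVITY = 17.7


def sauerbrey_coverage(
    delta_f: float | np.ndarray,
    overtone: int = 9,
    mass_sensitivity: float = SAUERBREY_SENSITIVITY,
    normalized: bool = False,
) -> float | np.ndarray:
    """Areal mass coverage (ng/cm²) from a frequency shift.

    ``delta_f`` is the raw overtone shift unless ``normalized`` is True
    (already divided by the overtone order n).  Negative Δf (adsorption)
    gives positive coverage.
    """
    if overtone < 1 or overtone % 2 == 0:
        raise ConfigError("overtone: must be an odd integer >= 1")
    if mass_sensitivity <= 0:
        raise ConfigError("mass_sensitivity: must be > 0")
    n = 1 if normalized else overtone
    result = -mass_sensitivity * np.asarray(delta_f, dtype=float) / n
    return float(result) if np.ndim(delta_f) == 0 else result


def _stable_plateau(
    trace: QcmdTrace,
    window: int = 30,
    baseline_samples: int = 50,
    sd_factor: float = 3.0,
) -> tuple[float, tuple[int, int]]:
    """Median of the last stable rolling window of the trace.

    Stability: rolling sd below ``sd_factor`` times the baseline noise
    estimate (sd of the first ``baseline_samples`` samples, floored to
    avoid a zero threshold on noise-free traces).
    """
    f = trace.delta_f
    if f.size < window:
        raise ConfigError("trace shorter than the stability window")
    base_sd = float(np.std(f[:min(baseline_samples, f.size)]))
    # floor at 0.01 Hz: below instrument resolution, a noise-free tail of an
    # exponential approach still counts as stable
    threshold = max(sd_factor * base_sd, 0.01)
    series = pd.Series(f)
    rolling_sd = series.rolling(window).std(ddof=0).to_numpy()
    stable = np.where(rolling_sd[window - 1:] <= threshold)[0]
    if stable.size == 0:
        raise ConfigError("no stable plateau window found in the trace")
    end = stable[-1] + window - 1
    start = end - window + 1
    return float(np.median(f[start:end + 1])), (start, end)


def detect_slb_formation(
    trace: QcmdTrace,
    expected_shift_hz: float = 25.0,
    tol_hz: float = 1.0,
    window: int = 30,
) -> dict:
    """Check the SLB-formation criterion on a vesicle-injection trace.

    Pass ⇔ the final stable plateau of the normalized shift lies within
    ``tol_hz`` of −``expected_shift_hz``.  Raw-overtone traces are
    normalized by n before the check.
    """
    plateau, (start, end) = _stable_plateau(trace, window=window)
    if not trace.normalized:
        plateau = plateau / trace.overtone
    passed = abs(plateau - (-expected_shift_hz)) <= tol_hz
    return {
        "pass": bool(passed),
        "plateau_hz": plateau,
        "window_samples": (int(start), int(end)),
        "expected_hz": -expected_shift_hz,
        "tol_hz": tol_hz,
    }


def extract_binding_shift(
    trace: QcmdTrace,
    baseline_window: tuple[float, float],
    plateau_window: tuple[float, float],
) -> float:
    """Binding shift (Hz) = median(plateau window) − median(baseline window).

    Windows are (start, end) times in seconds and must not overlap.
    """
    b0, b1 = baseline_window
    p0, p1 = plateau_window
    if max(b0, p0) < min(b1, p1):
        raise ConfigError("baseline and plateau windows overlap")
    base = trace.delta_f[(trace.time >= b0) & (trace.time <= b1)]
    plat = trace.delta_f[(trace.time >= p0) & (trace.time <= p1)]
    if base.size == 0 or plat.size == 0:
        raise ConfigError("empty baseline or plateau window")
    return float(np.median(plat) - np.median(base))


def fold_changes(
    table: pd.DataFrame,
    reference_label: str,
    at_concentration: float,
    nucleotide: str | None = None,
) -> pd.DataFrame:
    """Coverage ratios of each construct to a reference at one concentration.

    ``table`` is a CoverageTable frame with columns
    (label, concentration_uM, nucleotide, coverage_ng_cm2[, coverage_sem]).
    The display string rounds to integers above 10-fold and one decimal
    below ("17-fold", "3.5-fold").
    """
    sub = table[np.isclose(table["concentration_uM"], at_concentration)]
    if nucleotide is not None and "nucleotide" in sub.columns:
        sub = sub[sub["nucleotide"] == nucleotide]
    if reference_label not in set(sub["label"]):
        raise ConfigError(
            f"reference label {reference_label!r} absent at {at_concentration} uM"
        )
    ref = float(sub.loc[sub["label"] == reference_label, "coverage_ng_cm2"].iloc[0])
    if ref == 0:
        raise ConfigError("reference coverage is zero")
    rows = []
    for _, rec in sub.iterrows():
        ratio = float(rec["coverage_ng_cm2"]) / ref
        rows.append(
            {
                "label": rec["label"],
                "coverage_ng_cm2": rec["coverage_ng_cm2"],
                "fold_raw": ratio,
                "fold_display": format_fold(ratio),
            }
        )
    return pd.DataFrame(rows)


def format_fold(ratio: float) -> str:
    """Display rounding: integers above 10-fold, one decimal below."""
    if ratio > 10:
        return f"{round(ratio):d}-fold"
    return f"{round(ratio, 1):g}-fold"


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_trace_csv(
    path, overtone: int = 9, normalized: bool = False
) -> QcmdTrace:
    """Read a QCM-D export CSV with columns time_s and delta_f_hz (or a
    per-overtone column ``f<n>_hz``)."""
    df = pd.read_csv(path, comment="#")
    if "time_s" not in df.columns:
        raise ConfigError("trace CSV needs a time_s column")
    col = "delta_f_hz" if "delta_f_hz" in df.columns else f"f{overtone}_hz"
    if col not in df.columns:
        raise ConfigError(f"trace CSV needs a delta_f_hz or {col} column")
    return QcmdTrace(
        time=df["time_s"].to_numpy(),
        delta_f=df[col].to_numpy(),
        overtone=overtone,
        normalized=normalized,
    )


def write_coverage_table(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# coverage in ng/cm^2, concentration in uM\n")
        table.to_csv(fh, index=False)
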