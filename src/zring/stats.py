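"""Group summaries and two-sample comparisons.

Reproduces the reporting conventions used for treadmilling-velocity and
ring-diameter distributions: five-number summaries with notched-boxplot
notches extending 1.58·IQR/√n from the median (an approximate 95 %
interval for median comparison), and two-sided t-tests — Welch by
default, computable either from raw samples or from printed summary
statistics (mean, SD, n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .simulate import ConfigError

__all__ = [
    "GroupSummary",
    "TestResult",
    "summarize",
    "welch_t_from_summary",
    "welch_t_from_samples",
]


@dataclass
class GroupSummary:
    label: str
    mean: float
    sd: float
    n: int
    median: float
    q1: float
    q3: float
    iqr: float
    notch_low: float
    notch_high: float


@dataclass
class TestResult:
    t: float
    df: float
    p: float
    mean_difference: float
    ci95: tuple[float, float]
    method: str = "welch"


def summarize(values, label: str = "") -> GroupSummary:
    """Five-number summary plus notch interval.

    Quartiles use linear interpolation between order statistics; the
    notch half-width is 1.58·IQR/√n.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ConfigError("summarize: empty input")
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    iqr = q3 - q1
    notch = 1.58 * iqr / math.sqrt(x.size)
    return GroupSummary(
        label=label,
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        n=int(x.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        notch_low=float(med - notch),
        notch_high=float(med + notch),
    )


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    pooled: bool = False,
) -> TestResult:
    """Two-sided t-test from summary statistics.

    Welch by default: t = (m1 − m2)/√(s1²/n1 + s2²/n2) with
    Welch–Satterthwaite degrees of freedom; ``pooled=True`` switches to
    the equal-variance Student form.
    """
    if n1 < 2 or n2 < 2:
        raise ConfigError("need n >= 2 in both groups")
    if sd1 < 0 or sd2 < 0:
        raise ConfigError("standard deviations must be >= 0")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            raise ConfigError("degenerate test: both SDs zero and means equal")
        return TestResult(
            t=math.inf if mean1 > mean2 else -math.inf,
            df=float(n1 + n2 - 2), p=0.0,
            mean_difference=mean1 - mean2,
            ci95=(mean1 - mean2, mean1 - mean2),
            method="pooled" if pooled else "welch",
        )
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if pooled:
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    else:
        se = math.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    t = (mean1 - mean2) / se
    p = float(2.0 * sps.t.sf(abs(t), df=df))
    half = float(sps.t.ppf(0.975, df=df)) * se
    diff = mean1 - mean2
    return TestResult(
        t=float(t), df=float(df), p=p,
        mean_difference=float(diff),
        ci95=(diff - half, diff + half),
        method="pooled" if pooled else "welch",
    )


def welch_t_from_samples(x, y, pooled: bool = False) -> TestResult:
    """Two-sided t-test from raw samples; identical to
    :func:`welch_t_from_summary` applied to the samples' summaries."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ConfigError("need n >= 2 in both groups")
    return welch_t_from_summary(
        float(x.mean()), float(x.std(ddof=1)), int(x.size),
        float(y.mean()), float(y.std(ddof=1)), int(y.size),
        pooled=pooled,
    )
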