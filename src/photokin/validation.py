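"""ICH-style method-validation statistics.

Detection and quantification limits (3.3 sigma/S and 10 sigma/S with sigma
the SD of the calibration intercept), recovery and %RSD arithmetic, the
pooled two-sample t-test used to compare the spectrometric and HPLC
methods, and robustness summaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .assay import CalibrationFit

__all__ = [
    "MethodComparison",
    "ValidationReport",
    "lod_loq",
    "recovery_percent",
    "rsd_percent",
    "compare_methods",
    "robustness_summary",
    "build_validation_report",
]


@dataclass(frozen=True)
class MethodComparison:
    """Pooled-variance two-sample t-test result."""

    t_statistic: float
    degrees_of_freedom: int
    p_value: float


@dataclass(frozen=True)
class ValidationReport:
    linearity: CalibrationFit
    lod: float  # M
    loq: float  # M
    accuracy_mean: float  # %
    precision_rsd: float  # %
    recoveries: list[tuple[float, float, float, float]]  # (added M, found M, recovery %, rsd %)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=float))


def lod_loq(sd_intercept: float, slope: float) -> tuple[float, float]:
    """LOD = 3.3 sigma/S and LOQ = 10 sigma/S (ICH), sigma = SD of intercept.

    The LOQ/LOD ratio is exactly 10/3.3 for every input.
    """
    if not slope > 0:
        raise ValueError("slope must be positive")
    if sd_intercept < 0:
        raise ValueError("sd_intercept must be nonnegative")
    return 3.3 * sd_intercept / slope, 10.0 * sd_intercept / slope


def recovery_percent(added: float, found: float) -> float:
    """100 * found / added."""
    if not added > 0:
        raise ValueError("added amount must be positive")
    return 100.0 * found / added


def rsd_percent(values: Sequence[float]) -> float:
    """Relative standard deviation, % (sample SD, n-1 denominator)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("mean is zero; RSD undefined")
    return 100.0 * values.std(ddof=1) / mean


def compare_methods(
    recoveries_a: Sequence[float], recoveries_b: Sequence[float]
) -> MethodComparison:
    """Pooled (equal-variance) two-sample t-test, two-sided.

    With equal group sizes the pooled statistic coincides with Welch's; the
    pooled df n1 + n2 - 2 is what reproduces the reported method-comparison
    p-values. Two identical groups give t = 0, p = 1 (zero pooled variance
    with equal means is not an error).
    """
    a = np.asarray(recoveries_a, dtype=float)
    b = np.asarray(recoveries_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    df = a.size + b.size - 2
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled_var == 0:
        if a.mean() == b.mean():
            return MethodComparison(0.0, df, 1.0)
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return MethodComparison(float(t), df, float(p))


def robustness_summary(recoveries: Sequence[float]) -> tuple[float, float]:
    """(min %, max %) recovery across deliberate method perturbations."""
    values = np.asarray(recoveries, dtype=float)
    if values.size == 0:
        raise ValueError("robustness table is empty")
    return float(values.min()), float(values.max())


def build_validation_report(
    calibration: CalibrationFit,
    recovery_rows: Sequence[tuple[float, Sequence[float]]],
    sigma: float | None = None,
) -> ValidationReport:
    """Assemble the full ICH summary from a calibration and replicate recoveries.

    ``recovery_rows`` is a list of (added M, replicate found values M).
    ``sigma`` defaults to the calibration SD of intercept; passing the
    residual SD instead is supported as a configuration choice.
    """
    sigma = calibration.sd_intercept if sigma is None else sigma
    lod, loq = lod_loq(sigma, calibration.slope)
    rows = []
    all_recoveries = []
    for added, found_values in recovery_rows:
        found = np.asarray(found_values, dtype=float)
        rec = recovery_percent(added, float(found.mean()))
        rsd = rsd_percent(found) if found.size > 1 else 0.0
        rows.append((float(added), float(found.mean()), rec, rsd))
        all_recoveries.extend(100.0 * found / added)
    all_recoveries = np.asarray(all_recoveries)
    return ValidationReport(
        linearity=calibration,
        lod=lod,
        loq=loq,
        accuracy_mean=float(all_recoveries.mean()) if all_recoveries.size else float("nan"),
        precision_rsd=float(rsd_percent(all_recoveries)) if all_recoveries.size > 1 else 0.0,
        recoveries=rows,
    )
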