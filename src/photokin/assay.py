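"""Quantification of DPZ and RF from spectra, chromatograms and Job's series.

The two-component (Vierordt) assay solves the 2x2 Beer-Lambert system at
325 nm (DPZ maximum) and 445 nm (RF maximum); chromatographic quantitation
inverts per-species calibration lines on peak areas; Job's
continuous-variation analysis locates the mole fraction of maximal
absorbance change to assign complex stoichiometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spectra import Chromatogram, JobDataset

__all__ = [
    "CalibrationFit",
    "CoefficientMatrix",
    "PeakMetrics",
    "JobResult",
    "SingularSystemError",
    "fit_line",
    "default_coefficient_matrix",
    "two_component_solve",
    "quantify_chromatogram",
    "peak_metrics",
    "job_analysis",
]

ASSAY_WAVELENGTHS = (325.0, 445.0)
ASSAY_SPECIES = ("DPZ", "RF")

#: Peak-to-species assignment window, minutes.
DEFAULT_RT_WINDOW_MIN = 0.2


class SingularSystemError(ValueError):
    """The absorptivity matrix is numerically singular."""


@dataclass(frozen=True)
class CalibrationFit:
    """Ordinary-least-squares calibration line with its dispersion statistics.

    ``sd_intercept`` is ``se_intercept * sqrt(n)``: validation tables report
    a separate "SD of intercept" whose printed ratio to the SE is sqrt(n),
    and the detection/quantification limits use that SD.
    """

    slope: float
    intercept: float
    se_slope: float
    se_intercept: float
    sd_intercept: float
    r: float
    n: int
    residual_sd: float = 0.0  # s with n-2 d.f.; direct estimate of response noise


@dataclass(frozen=True)
class CoefficientMatrix:
    """Effective absorptivity * path (per M) at the two assay wavelengths.

    entries[w][s] for wavelength w in {325, 445} nm and species s in
    {DPZ, RF}. DPZ does not absorb in the visible, so the 445/DPZ entry is
    zero by default; RF does absorb at 325 nm, so its cross term is a
    required, configurable input.
    """

    matrix: tuple[tuple[float, float], tuple[float, float]]
    wavelengths: tuple[float, float] = ASSAY_WAVELENGTHS
    species: tuple[str, str] = ASSAY_SPECIES

    def as_array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)


def default_coefficient_matrix(eps_rf_325: float = 3.0e3) -> CoefficientMatrix:
    """Assay matrix with the calibration slopes on the diagonal.

    1.14e4 (DPZ at 325 nm) and 1.15e4 (RF at 445 nm) per M for a 1 cm path;
    eps_DPZ(445) = 0; the RF cross-absorptivity at 325 nm is configurable.
    """
    return CoefficientMatrix(((1.14e4, eps_rf_325), (0.0, 1.15e4)))


def fit_line(x: Sequence[float], y: Sequence[float]) -> CalibrationFit:
    """OLS line with the standard calibration dispersion statistics.

    slope = Sxy/Sxx, se_slope = s/sqrt(Sxx),
    se_intercept = s sqrt(1/n + xbar^2/Sxx), sd_intercept = se_intercept
    sqrt(n), r = Pearson correlation; the residual SD s uses n-2 degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need at least three paired points")
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    if sxx == 0:
        raise ValueError("x values are degenerate (all equal)")
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    syy = float(np.sum((y - ybar) ** 2))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    ss_res = max(syy - slope * sxy, 0.0)
    s = math.sqrt(ss_res / (n - 2))
    se_slope = s / math.sqrt(sxx)
    se_intercept = s * math.sqrt(1.0 / n + xbar**2 / sxx)
    r = sxy / math.sqrt(sxx * syy) if syy > 0 else 1.0
    return CalibrationFit(
        slope=slope,
        intercept=intercept,
        se_slope=se_slope,
        se_intercept=se_intercept,
        sd_intercept=se_intercept * math.sqrt(n),
        r=r,
        n=n,
        residual_sd=s,
    )


def two_component_solve(
    a325: float, a445: float, k: CoefficientMatrix | np.ndarray
) -> tuple[float, float]:
    """Solve the 2x2 Beer-Lambert system A = K C for (C_DPZ, C_RF).

    Exact linear solve; round-trips with the forward model to machine
    precision. A determinant below 1e-12 times the product of the largest
    row norms raises :class:`SingularSystemError`.
    """
    km = k.as_array() if isinstance(k, CoefficientMatrix) else np.asarray(k, dtype=float)
    det = km[0, 0] * km[1, 1] - km[0, 1] * km[1, 0]
    row_norm_product = np.linalg.norm(km[0]) * np.linalg.norm(km[1])
    if abs(det) < 1e-12 * max(row_norm_product, 1.0):
        raise SingularSystemError("absorptivity matrix is singular at 325/445 nm")
    c = np.linalg.solve(km, np.array([a325, a445], dtype=float))
    return float(c[0]), float(c[1])


def quantify_chromatogram(
    chromatogram: Chromatogram | Sequence[tuple[float, float, float]],
    calibrations: dict[str, tuple[CalibrationFit, float]],
    window: float = DEFAULT_RT_WINDOW_MIN,
) -> dict[str, float | None]:
    """Concentrations from peak areas: C = (area - intercept) / slope.

    ``calibrations`` maps species -> (calibration line, expected retention
    time); each species is matched to the nearest peak within ``window``
    minutes. A species with no peak in its window yields None (a missing
    analyte, not an error).
    """
    peaks = chromatogram.peaks if isinstance(chromatogram, Chromatogram) else list(chromatogram)
    out: dict[str, float | None] = {}
    for species, (calib, expected_rt) in calibrations.items():
        if calib.slope == 0:
            raise ValueError(f"calibration slope for {species} is zero")
        best = None
        for t_r, _, area in peaks:
            dist = abs(t_r - expected_rt)
            if dist <= window and (best is None or dist < best[0]):
                best = (dist, area)
        out[species] = None if best is None else (best[1] - calib.intercept) / calib.slope
    return out


@dataclass(frozen=True)
class PeakMetrics:
    retention_time: float  # min
    plates: float  # theoretical plates N
    tailing: float  # USP tailing factor T


def peak_metrics(
    t_r: float,
    half_height_width: float,
    w05_total: float | None = None,
    w05_front: float | None = None,
) -> PeakMetrics:
    """Column-efficiency metrics for one peak.

    Plates via the half-height convention N = 5.54 (t_R / w_1/2)^2. Tailing
    via the USP convention at 5% height, T = W_0.05 / (2 f) with f the front
    half-width; when the 5% widths are not supplied the peak is taken as
    symmetric (Gaussian), giving T = 1.
    """
    if not half_height_width > 0:
        raise ValueError("half-height width must be positive")
    plates = 5.54 * (t_r / half_height_width) ** 2
    if w05_total is None or w05_front is None:
        tailing = 1.0
    else:
        if not (w05_total > 0 and w05_front > 0):
            raise ValueError("5%-height widths must be positive")
        tailing = w05_total / (2.0 * w05_front)
    return PeakMetrics(retention_time=t_r, plates=plates, tailing=tailing)


@dataclass(frozen=True)
class JobResult:
    x_max: float | None  # mole fraction of maximal delta-A
    ratio: float | None  # x / (1 - x)
    label: str  # "1:1" when ratio is in [0.8, 1.25]


def job_analysis(job: JobDataset) -> JobResult:
    """Stoichiometry from the continuous-variation maximum.

    The grid maximum of delta-A is refined by a parabola through the three
    surrounding points; ratio = x*/(1-x*), labelled "1:1" when it falls in
    [0.8, 1.25]. An all-zero series yields an undefined-stoichiometry
    result.
    """
    x = job.mole_fractions
    y = job.delta_absorbance
    interior = (x > 0) & (x < 1)
    if np.count_nonzero(interior) < 3 or x.size < 5:
        raise ValueError("need at least five fractions spanning (0, 1)")
    if np.allclose(y, 0.0):
        return JobResult(None, None, "undefined")
    i = int(np.argmax(y))
    if 0 < i < x.size - 1:
        # parabolic refinement over the three points around the grid max
        x3, y3 = x[i - 1 : i + 2], y[i - 1 : i + 2]
        denom = (x3[0] - x3[1]) * (x3[0] - x3[2]) * (x3[1] - x3[2])
        a = (x3[2] * (y3[1] - y3[0]) + x3[1] * (y3[0] - y3[2]) + x3[0] * (y3[2] - y3[1])) / denom
        b = (
            x3[2] ** 2 * (y3[0] - y3[1])
            + x3[1] ** 2 * (y3[2] - y3[0])
            + x3[0] ** 2 * (y3[1] - y3[2])
        ) / denom
        x_star = float(-b / (2 * a)) if a < 0 else float(x[i])
    else:
        x_star = float(x[i])
    x_star = min(max(x_star, 0.0), 1.0)
    if x_star in (0.0, 1.0):
        return JobResult(x_star, None, "undefined")
    ratio = x_star / (1.0 - x_star)
    label = "1:1" if 0.8 <= ratio <= 1.25 else f"ratio {ratio:.2f}"
    return JobResult(x_star, ratio, label)
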