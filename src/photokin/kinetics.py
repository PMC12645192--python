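"""Photolysis kinetics: rate constants, quantum yields and the k-pH profile.

First-order rate constants k_obs (min^-1) come from OLS on ln C vs t (a
log10 fit differs only by the factor 2.303 and gives the identical k);
second-order sensitization constants k2 (M^-1 min^-1) are the slope of
k_obs against sensitizer concentration. Photolysis quantum yields use the
initial-rate convention: molecules degraded per photon absorbed, where the
absorbed photon rate is the lamp emission overlap integral with the
solution absorbance. Ionization state follows a monoprotic
Henderson-Hasselbalch model (donepezil pKa 8.95: cationic below, neutral
above).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spectra import AbsorbanceSpectrum, LampSpectrum

__all__ = [
    "AVOGADRO",
    "FirstOrderFit",
    "SecondOrderFit",
    "SpeciesFractions",
    "QuantumYieldResult",
    "PhProfile",
    "ProfileFeatures",
    "fit_first_order",
    "choose_order",
    "second_order_constant",
    "species_fractions",
    "absorbed_fraction",
    "quantum_yield",
    "profile_features",
]

AVOGADRO = 6.02214e23

#: Donepezil piperidine pKa.
DPZ_PKA = 8.95


@dataclass(frozen=True)
class FirstOrderFit:
    k_obs: float  # min^-1
    sd_k: float  # min^-1, SE of the fitted slope
    r2: float
    n_points: int


@dataclass(frozen=True)
class SecondOrderFit:
    k2: float  # M^-1 min^-1, slope of k_obs vs sensitizer concentration
    intercept: float  # min^-1, zero-sensitizer extrapolate (estimate of k0)
    r2: float


@dataclass(frozen=True)
class SpeciesFractions:
    ph: float
    pka: float
    f_cationic: float
    f_neutral: float


@dataclass(frozen=True)
class QuantumYieldResult:
    phi: float | None  # None when no light is absorbed
    absorbed_fraction: float
    absorbed_photon_rate: float  # einstein min^-1
    undefined: bool = False


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """slope, intercept, SE of slope, R^2."""
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    syy = float(np.sum((y - ybar) ** 2))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    ss_res = max(syy - slope * sxy, 0.0)
    se_slope = math.sqrt(ss_res / (n - 2) / sxx) if n > 2 else 0.0
    r2 = 1.0 - ss_res / syy if syy > 0 else 1.0
    return slope, intercept, se_slope, r2


def fit_first_order(times: Sequence[float], concentrations: Sequence[float]) -> FirstOrderFit:
    """k_obs from OLS of ln C on t: k_obs = -slope, sd_k = SE of the slope."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size != c.size or t.size < 3:
        raise ValueError("need at least three paired points")
    if np.any(c <= 0):
        raise ValueError(
            "all concentrations must be positive for a log-linear fit; "
            "truncate the series before the first nonpositive value"
        )
    if np.ptp(t) == 0:
        raise ValueError("times are degenerate")
    slope, _, se_slope, r2 = _ols(t, np.log(c))
    return FirstOrderFit(k_obs=-slope, sd_k=se_slope, r2=r2, n_points=t.size)


def choose_order(times: Sequence[float], concentrations: Sequence[float]) -> tuple[str, bool]:
    """Compare zero-order (C vs t) and first-order (ln C vs t) fits by R^2.

    Returns (order, tie_flag); ties within 1e-6 in R^2 go to "first".
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size != c.size or t.size < 3:
        raise ValueError("need at least three paired points")
    if np.any(c <= 0):
        raise ValueError("all concentrations must be positive")
    *_, r2_zero = _ols(t, c)
    *_, r2_first = _ols(t, np.log(c))
    if abs(r2_first - r2_zero) < 1e-6:
        return "first", True
    return ("first", False) if r2_first > r2_zero else ("zero", False)


def second_order_constant(
    k_obs_list: Sequence[float], rf_concs: Sequence[float]
) -> SecondOrderFit:
    """OLS slope of k_obs against sensitizer concentration, in M^-1 min^-1.

    The intercept is reported as the zero-sensitizer extrapolate. The slope
    is the raw least-squares value in natural concentration units; no table
    rescaling is applied.
    """
    k = np.asarray(k_obs_list, dtype=float)
    c = np.asarray(rf_concs, dtype=float)
    if k.size != c.size or k.size < 2:
        raise ValueError("need at least two paired points")
    if np.unique(c).size < 2:
        raise ValueError("sensitizer concentrations are degenerate")
    if k.size == 2:
        slope = (k[1] - k[0]) / (c[1] - c[0])
        return SecondOrderFit(k2=float(slope), intercept=float(k[0] - slope * c[0]), r2=1.0)
    if np.unique(c).size < 3:
        raise ValueError("need at least three distinct concentrations")
    slope, intercept, _, r2 = _ols(c, k)
    return SecondOrderFit(k2=slope, intercept=intercept, r2=r2)


def species_fractions(ph: float, pka: float = DPZ_PKA) -> SpeciesFractions:
    """Henderson-Hasselbalch speciation of a monoprotic base.

    f_cationic = 1 / (1 + 10^(pH - pKa)); fractions sum to 1 exactly.
    """
    if not 0.0 <= ph <= 14.0:
        raise ValueError("pH must lie in [0, 14]")
    f_cat = 1.0 / (1.0 + 10.0 ** (ph - pka))
    return SpeciesFractions(ph=ph, pka=pka, f_cationic=f_cat, f_neutral=1.0 - f_cat)


def absorbed_fraction(lamp: LampSpectrum, absorbance: AbsorbanceSpectrum) -> float:
    """Fraction of emitted photons absorbed by the solution.

    f = integral E(lambda) (1 - 10^-A(lambda)) dlambda / integral E(lambda)
    dlambda with trapezoid weights; the absorbance is interpolated onto the
    lamp grid. Always in [0, 1].
    """
    a = np.interp(lamp.wavelengths, absorbance.wavelengths, absorbance.absorbance)
    total = float(np.trapezoid(lamp.relative_emission, lamp.wavelengths))
    if total <= 0:
        raise ValueError("lamp has zero total emission")
    absorbed = float(np.trapezoid(lamp.relative_emission * (1.0 - 10.0 ** (-a)), lamp.wavelengths))
    return min(max(absorbed / total, 0.0), 1.0)


def quantum_yield(
    k_obs: float,
    c0: float,
    volume_l: float,
    lamp: LampSpectrum,
    absorbance: AbsorbanceSpectrum,
) -> QuantumYieldResult:
    """Photolysis quantum yield via the initial-rate convention.

    Initial degradation rate k_obs c0 V (mol min^-1) divided by the
    absorbed photon rate (photon flux converted to einstein min^-1 times
    the lamp/solution overlap fraction). Values above 1 are permitted
    (chain photochemistry). Zero absorbed fraction yields a flagged
    undefined result rather than a division error.
    """
    if k_obs < 0:
        raise ValueError("k_obs must be nonnegative")
    if not (c0 > 0 and volume_l > 0):
        raise ValueError("c0 and volume must be positive")
    f = absorbed_fraction(lamp, absorbance)
    photon_rate = lamp.photon_flux * 60.0 / AVOGADRO  # einstein min^-1 emitted
    absorbed_rate = photon_rate * f
    if absorbed_rate == 0:
        return QuantumYieldResult(None, f, 0.0, undefined=True)
    rate = k_obs * c0 * volume_l  # mol min^-1 at t = 0
    return QuantumYieldResult(rate / absorbed_rate, f, absorbed_rate)


@dataclass(frozen=True)
class PhProfile:
    """k_obs vs pH for one (condition, lamp) series."""

    entries: tuple[tuple[float, float, str, str], ...]  # (pH, k_obs, condition, lamp)

    def series(self) -> tuple[np.ndarray, np.ndarray]:
        ph = np.array([e[0] for e in self.entries])
        k = np.array([e[1] for e in self.entries])
        order = np.argsort(ph)
        return ph[order], k[order]


@dataclass(frozen=True)
class ProfileFeatures:
    argmax_ph_2_4: float  # pH of maximal rate on the acid bell (pH 2-4)
    argmin_ph: float  # pH of minimal rate overall
    monotone_5_12: bool  # nondecreasing on the sigmoid limb (pH 5-12)


def profile_features(profile: PhProfile | Sequence[tuple[float, float]]) -> ProfileFeatures:
    """Grid-restricted features of the k-pH profile (no interpolation).

    The reported shape is a bell between pH 2 and 4 and a sigmoid rise from
    pH 5 to 12; the features returned are the grid argmax on [2, 4], the
    overall grid argmin, and a nondecreasing flag on [5, 12].
    """
    if isinstance(profile, PhProfile):
        ph, k = profile.series()
    else:
        pairs = sorted(profile)
        ph = np.array([p for p, _ in pairs], dtype=float)
        k = np.array([v for _, v in pairs], dtype=float)
    if ph.size < 4:
        raise ValueError("need at least four pH points")
    if np.unique(ph).size != ph.size:
        raise ValueError("duplicate pH values in one series")

    bell = (ph >= 2.0) & (ph <= 4.0)
    if not np.any(bell):
        raise ValueError("no pH points in [2, 4]")
    argmax_bell = float(ph[bell][np.argmax(k[bell])])
    argmin = float(ph[np.argmin(k)])
    limb = (ph >= 5.0) & (ph <= 12.0)
    monotone = bool(np.all(np.diff(k[limb]) >= 0)) if np.count_nonzero(limb) >= 2 else True
    return ProfileFeatures(argmax_ph_2_4=argmax_bell, argmin_ph=argmin, monotone_5_12=monotone)
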