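"""Synthetic spectral and kinetic data generation.

Everything downstream (the two-component assay, kinetic fitting, quantum
yields, the mechanism simulator) consumes Beer-Lambert absorbance spectra,
calibration series, photolysis time courses, chromatograms, lamp emission
spectra and Job's continuous-variation series. No raw experimental data are
deposited for this system, so this module generates all of them with
controlled noise and explicit seeds.

Conventions (enforced by validation, not a unit system): concentrations in
M, time in minutes, wavelength in nm, path length in cm (default 1 cm).
Absorption bands are Gaussian in wavelength; lamp lines are rendered as
narrow Gaussians (sigma 2 nm) so overlap integrals with absorbance spectra
are well defined on a common grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "BandModel",
    "ChromophoreSpec",
    "AbsorbanceSpectrum",
    "LampSpectrum",
    "TimeCourseDataset",
    "JobDataset",
    "Chromatogram",
    "default_grid",
    "dpz_chromophore",
    "rf_chromophore",
    "build_chromophore_spectrum",
    "absorbance_of_mixture",
    "simulate_calibration",
    "simulate_photolysis",
    "simulate_job_series",
    "simulate_chromatogram",
    "lamp_preset",
    "write_spectrum_csv",
    "write_timecourse_csv",
]

#: Path length of the spectrophotometer cell (cm).
DEFAULT_PATH_CM = 1.0

#: Total photon output of the UV (Philips 30 W TUV) and visible (HPLN 125 W)
#: sources, from ferrioxalate actinometry (quanta per second).
UV_PHOTON_FLUX = 2.31e17
VISIBLE_PHOTON_FLUX = 5.51e18

LAMP_LINE_SIGMA_NM = 2.0


@dataclass(frozen=True)
class BandModel:
    """One Gaussian absorption band: epsilon(lambda) = peak_epsilon * exp(-(lambda-center)^2 / (2 width^2))."""

    center: float  # nm
    width: float  # Gaussian sigma, nm
    peak_epsilon: float  # molar absorptivity at the center, M^-1 cm^-1

    def __post_init__(self) -> None:
        if not self.center > 0:
            raise ValueError(f"band center must be positive, got {self.center}")
        if not self.width > 0:
            raise ValueError(f"band width must be positive, got {self.width}")
        if self.peak_epsilon < 0:
            raise ValueError("peak_epsilon must be nonnegative")


@dataclass(frozen=True)
class ChromophoreSpec:
    """A chromophore as a sum of Gaussian bands plus its nominal absorption maxima."""

    name: str
    bands: tuple[BandModel, ...]
    reference_maxima: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("chromophore needs at least one band")
        centers = {b.center for b in self.bands}
        missing = [m for m in self.reference_maxima if m not in centers]
        if missing:
            raise ValueError(f"reference maxima {missing} have no matching band center")


@dataclass
class AbsorbanceSpectrum:
    """Absorbance vs wavelength (dimensionless, for the stated path length)."""

    wavelengths: np.ndarray  # nm, strictly increasing
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape:
            raise ValueError("wavelengths and absorbance must have equal length")
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise ValueError("need a 1-d grid of at least two wavelengths")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")

    def at(self, wavelength: float) -> float:
        """Linearly interpolated absorbance at one wavelength."""
        return float(np.interp(wavelength, self.wavelengths, self.absorbance))


@dataclass
class LampSpectrum:
    """Relative emission vs wavelength plus total photon output (quanta s^-1)."""

    wavelengths: np.ndarray
    relative_emission: np.ndarray
    photon_flux: float
    name: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.relative_emission = np.asarray(self.relative_emission, dtype=float)
        if self.wavelengths.shape != self.relative_emission.shape:
            raise ValueError("wavelengths and relative_emission must have equal length")
        if np.any(self.relative_emission < 0):
            raise ValueError("relative emission must be nonnegative")
        if not np.trapezoid(self.relative_emission, self.wavelengths) > 0:
            raise ValueError("total emission must be positive")
        if not self.photon_flux > 0:
            raise ValueError("photon_flux must be positive")


@dataclass
class TimeCourseDataset:
    """A photolysis run: true concentrations plus (optionally noisy) observed spectra."""

    times: np.ndarray  # minutes, strictly increasing, starting at 0
    true_concentrations: dict[str, np.ndarray]  # species -> M
    observed_spectra: list[AbsorbanceSpectrum]
    condition: str  # "aerobic" | "anaerobic"
    seed: int
    k_eff: float = 0.0  # effective first-order constant actually applied, min^-1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times[0] != 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing and start at 0")
        for name, c in self.true_concentrations.items():
            if np.any(np.asarray(c) < 0):
                raise ValueError(f"negative concentration for {name}")


@dataclass
class JobDataset:
    """Continuous-variation series at constant total concentration."""

    total_concentration: float  # M
    mole_fractions: np.ndarray  # of the first partner, in [0, 1], strictly increasing
    delta_absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.mole_fractions = np.asarray(self.mole_fractions, dtype=float)
        self.delta_absorbance = np.asarray(self.delta_absorbance, dtype=float)
        if np.any(self.mole_fractions < 0) or np.any(self.mole_fractions > 1):
            raise ValueError("mole fractions must lie in [0, 1]")
        if np.any(np.diff(self.mole_fractions) <= 0):
            raise ValueError("mole fractions must be strictly increasing")


@dataclass
class Chromatogram:
    """Detector signal vs time plus nominal peak parameters (t_R, half-height width, area)."""

    times: np.ndarray  # minutes
    signal: np.ndarray
    peaks: list[tuple[float, float, float]]
    overlapping: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if any(area < 0 for _, _, area in self.peaks):
            raise ValueError("peak areas must be nonnegative")


def default_grid(start: float = 200.0, stop: float = 700.0, step: float = 1.0) -> np.ndarray:
    """The default wavelength grid, 200-700 nm at 1 nm."""
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


def dpz_chromophore() -> ChromophoreSpec:
    """Donepezil: absorption maxima at 209, 225, 269 and 325 nm.

    The 325 nm peak absorptivity equals the calibration slope of the
    two-component assay at that wavelength (1.14e4 M^-1 cm^-1); the UV-band
    absorptivities are typical aryl-ketone magnitudes chosen once for the
    synthetic model.
    """
    return ChromophoreSpec(
        name="DPZ",
        bands=(
            BandModel(209.0, 4.0, 3.8e4),
            BandModel(225.0, 4.0, 2.9e4),
            BandModel(269.0, 10.0, 1.6e4),
            BandModel(325.0, 12.0, 1.14e4),
        ),
        reference_maxima=(209.0, 225.0, 269.0, 325.0),
    )


def rf_chromophore() -> ChromophoreSpec:
    """Riboflavin: absorption maxima at 223, 267, 385 and 445 nm.

    The 445 nm peak absorptivity equals the assay calibration slope at that
    wavelength (1.15e4 M^-1 cm^-1).
    """
    return ChromophoreSpec(
        name="RF",
        bands=(
            BandModel(223.0, 6.0, 3.0e4),
            BandModel(267.0, 8.0, 3.2e4),
            BandModel(385.0, 14.0, 1.0e4),
            BandModel(445.0, 14.0, 1.15e4),
        ),
        reference_maxima=(223.0, 267.0, 385.0, 445.0),
    )


def build_chromophore_spectrum(spec: ChromophoreSpec, grid: np.ndarray) -> np.ndarray:
    """Molar absorptivity epsilon(lambda) on ``grid`` as a sum of Gaussian bands.

    Band centers separated by at least four widths remain local maxima of
    the summed spectrum (to within one grid step).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a nonempty 1-d array")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    eps = np.zeros_like(grid)
    for band in spec.bands:
        eps += band.peak_epsilon * np.exp(-((grid - band.center) ** 2) / (2.0 * band.width**2))
    return eps


def absorbance_of_mixture(
    epsilon_spectra: dict[str, np.ndarray],
    concentrations: dict[str, float],
    grid: np.ndarray,
    path: float = DEFAULT_PATH_CM,
) -> AbsorbanceSpectrum:
    """Beer-Lambert forward model: A(lambda) = sum_s epsilon_s(lambda) C_s path.

    Exactly linear and additive in each concentration.
    """
    grid = np.asarray(grid, dtype=float)
    total = np.zeros_like(grid)
    for name, conc in concentrations.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {name}")
        eps = np.asarray(epsilon_spectra[name], dtype=float)
        if eps.shape != grid.shape:
            raise ValueError(f"epsilon spectrum for {name} does not share the grid")
        total += eps * conc * path
    return AbsorbanceSpectrum(grid, total)


def simulate_calibration(
    concs: Sequence[float],
    coefficient: float,
    noise_sd: float,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear calibration series: response = coefficient * conc + N(0, noise_sd)."""
    concs = np.asarray(concs, dtype=float)
    if concs.size == 0:
        raise ValueError("concs must be nonempty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    responses = coefficient * concs + rng.normal(0.0, noise_sd, size=concs.shape)
    return concs, responses


def simulate_photolysis(
    c0: float,
    k: float,
    times: Sequence[float],
    condition: str = "aerobic",
    anaerobic_factor: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    rf_conc: float = 0.0,
    grid: np.ndarray | None = None,
    physical: bool = False,
) -> TimeCourseDataset:
    """First-order photolysis time course with Beer-Lambert observed spectra.

    The substrate decays as C(t) = c0 exp(-k_eff t) with k_eff = k under
    aerobic conditions and k / anaerobic_factor under anaerobic conditions
    (the ~10x oxygen effect of riboflavin sensitization). The sensitizer
    concentration is held constant at ``rf_conc``. Additive Gaussian noise
    of SD ``noise_sd`` is applied to each observed spectrum; with
    ``physical=True`` noisy absorbances are truncated at zero.
    """
    if not c0 > 0:
        raise ValueError("c0 must be positive")
    if k < 0:
        raise ValueError("k must be nonnegative")
    if not anaerobic_factor > 0:
        raise ValueError("anaerobic_factor must be positive")
    if condition not in ("aerobic", "anaerobic"):
        raise ValueError(f"unknown condition {condition!r}")
    times = np.asarray(times, dtype=float)
    if times[0] != 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing and start at 0")

    k_eff = k if condition == "aerobic" else k / anaerobic_factor
    conc = c0 * np.exp(-k_eff * times)

    if grid is None:
        grid = default_grid()
    eps = {
        "DPZ": build_chromophore_spectrum(dpz_chromophore(), grid),
        "RF": build_chromophore_spectrum(rf_chromophore(), grid),
    }
    rng = np.random.default_rng(seed)
    spectra = []
    for c in conc:
        clean = absorbance_of_mixture(eps, {"DPZ": c, "RF": rf_conc}, grid)
        noisy = clean.absorbance + rng.normal(0.0, noise_sd, size=grid.shape)
        if physical:
            noisy = np.clip(noisy, 0.0, None)
        spectra.append(AbsorbanceSpectrum(grid, noisy))

    return TimeCourseDataset(
        times=times,
        true_concentrations={"DPZ": conc, "RF": np.full_like(times, rf_conc)},
        observed_spectra=spectra,
        condition=condition,
        seed=seed,
        k_eff=k_eff,
    )


def equilibrium_complex(c_a: float, c_b: float, k_assoc: float) -> float:
    """[AB] for A + B <-> AB at association constant k_assoc (M^-1).

    Root of K x^2 - (K(Ca+Cb) + 1) x + K Ca Cb = 0; the physically valid
    (smaller) root is returned. k_assoc = 0 gives no complex.
    """
    if k_assoc < 0:
        raise ValueError("k_assoc must be nonnegative")
    if k_assoc == 0 or c_a <= 0 or c_b <= 0:
        return 0.0
    b = c_a + c_b + 1.0 / k_assoc
    disc = b * b - 4.0 * c_a * c_b
    return 0.5 * (b - np.sqrt(disc))


def simulate_job_series(
    total: float,
    fractions: Sequence[float],
    k_assoc: float,
    delta_epsilon: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> JobDataset:
    """Job's continuous-variation series for a 1:1 complex.

    At each mole fraction x of partner A, C_A = x total and C_B = (1-x)
    total; the 1:1 equilibrium concentration of the complex follows from the
    quadratic mass-action relation and dA = delta_epsilon [complex].
    """
    if not total > 0:
        raise ValueError("total must be positive")
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < 0) or np.any(fractions > 1):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    complexes = np.array(
        [equilibrium_complex(x * total, (1.0 - x) * total, k_assoc) for x in fractions]
    )
    da = delta_epsilon * complexes
    if noise_sd > 0:
        da = da + rng.normal(0.0, noise_sd, size=da.shape)
    return JobDataset(total, fractions, da)


def simulate_chromatogram(
    concs: Sequence[float],
    response_factors: Sequence[float],
    retention_times: Sequence[float],
    widths: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    times: np.ndarray | None = None,
) -> Chromatogram:
    """Sum-of-Gaussians chromatogram with area = response_factor * conc.

    ``widths`` are Gaussian sigmas in minutes; the stored peak width is the
    half-height width 2 sqrt(2 ln 2) sigma. Identical retention times are
    allowed but flagged via ``overlapping``.
    """
    concs = np.asarray(concs, dtype=float)
    rf = np.asarray(response_factors, dtype=float)
    rt = np.asarray(retention_times, dtype=float)
    w = np.asarray(widths, dtype=float)
    if not (concs.shape == rf.shape == rt.shape == w.shape):
        raise ValueError("parameter lists must have equal length")
    if np.any(w <= 0):
        raise ValueError("widths must be positive")
    if times is None:
        # grid fine enough that trapezoid areas hold to 0.1%
        step = float(np.min(w)) / 10.0
        t_max = float(np.max(rt) + 8.0 * np.max(w)) if rt.size else 5.0
        times = np.arange(0.0, t_max + step, step)
    times = np.asarray(times, dtype=float)

    signal = np.zeros_like(times)
    peaks: list[tuple[float, float, float]] = []
    fwhm = 2.0 * np.sqrt(2.0 * np.log(2.0))
    for c, f, t0, sigma in zip(concs, rf, rt, w):
        area = f * c
        signal += area / (sigma * np.sqrt(2.0 * np.pi)) * np.exp(-((times - t0) ** 2) / (2 * sigma**2))
        peaks.append((float(t0), float(fwhm * sigma), float(area)))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    overlapping = len(set(np.round(rt, 12))) < rt.size
    return Chromatogram(times, signal, peaks, overlapping=overlapping)


# (center wavelengths nm, relative weight) of the rendered emission lines
_UV_LINES = [(270.0, 1.0)] + [(w, 0.05) for w in (319.0, 375.0, 405.0, 494.0, 555.0, 578.0)]
_VISIBLE_LINES = [(w, 1.0) for w in (340.0, 360.0, 395.0, 490.0, 555.0, 590.0, 620.0)] + [
    (700.0, 1.0),
    (580.0, 0.2),
]


def lamp_preset(name: str, grid: np.ndarray | None = None) -> LampSpectrum:
    """Emission spectrum of the UV (270 nm dominant) or visible source.

    Lines are narrow Gaussians (sigma 2 nm) on the common wavelength grid;
    photon fluxes are the actinometric constants.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if name == "UV":
        lines, flux = _UV_LINES, UV_PHOTON_FLUX
    elif name == "visible":
        lines, flux = _VISIBLE_LINES, VISIBLE_PHOTON_FLUX
    else:
        raise ValueError(f"unknown lamp preset {name!r}")
    emission = np.zeros_like(grid)
    for center, weight in lines:
        emission += weight * np.exp(-((grid - center) ** 2) / (2.0 * LAMP_LINE_SIGMA_NM**2))
    return LampSpectrum(grid, emission, flux, name=name)


def write_spectrum_csv(spectrum: AbsorbanceSpectrum, path: str | Path, params: dict | None = None) -> None:
    """Write wavelength/absorbance columns; generation parameters go to a JSON sidecar."""
    import pandas as pd

    path = Path(path)
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "absorbance": spectrum.absorbance}
    ).to_csv(path, index=False)
    if params is not None:
        path.with_suffix(".json").write_text(json.dumps(params, indent=2, default=float))


def write_timecourse_csv(dataset: TimeCourseDataset, path: str | Path, params: dict | None = None) -> None:
    """Write time plus one concentration column per species, with a JSON sidecar."""
    import pandas as pd

    path = Path(path)
    cols = {"time_min": dataset.times}
    cols.update({name: c for name, c in dataset.true_concentrations.items()})
    pd.DataFrame(cols).to_csv(path, index=False)
    sidecar = {"condition": dataset.condition, "seed": dataset.seed, "k_eff_per_min": dataset.k_eff}
    if params:
        sidecar.update(params)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=float))
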