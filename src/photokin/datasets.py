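"""Reference datasets for the DPZ/RF photostability system.

The raw time-course measurements behind the kinetic study are not
deposited; what is available are the reported summary tables. This module
ships them as plain CSV (loaded as DataFrames) plus the validation-summary
constants of the two assay methods, so the statistics, fixture properties
and worked examples can be recomputed.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "UV_VALIDATION",
    "HPLC_VALIDATION",
    "load_kinetics_kobs",
    "load_kinetics_blocks",
    "load_mixture_recoveries",
    "load_method_comparison",
    "load_eco_scale_ledger",
    "load_toc_records",
]

#: Two-component spectrophotometric method (pH 7.0): calibration slope
#: (response per M), intercept, SE/SD of intercept (absorbance units) and
#: the quantitation wavelength. SDs of the intercept are n = 10 values.
UV_VALIDATION = {
    "DPZ": {
        "wavelength_nm": 325.0,
        "slope": 1.14e4,
        "intercept": 0.00007,
        "se_slope": 0.59e2,
        "se_intercept": 0.41e-2,
        "sd_intercept": 1.28e-2,
        "r": 0.9998,
        "lod_m": 0.37e-5,
        "loq_m": 1.12e-5,
    },
    "RF": {
        "wavelength_nm": 445.0,
        "slope": 1.15e4,
        "intercept": -0.00411,
        "se_slope": 0.27e2,
        "se_intercept": 0.19e-2,
        "sd_intercept": 0.60e-2,
        "r": 0.9999,
        "lod_m": 0.17e-5,
        "loq_m": 0.52e-5,
    },
}

#: HPLC method (pH 2.5): peak-area calibration (area per M) plus column
#: metrics (retention time min, plates N, tailing T at 264 nm detection).
HPLC_VALIDATION = {
    "DPZ": {
        "retention_time_min": 2.78,
        "plates": 8425.0,
        "tailing": 0.45,
        "slope": 0.85e10,
        "intercept": -2.72e3,
        "se_slope": 0.49e4,
        "se_intercept": 0.34e4,
        "sd_intercept": 1.10e4,
        "r": 0.9998,
        "lod_m": 0.43e-5,
        "loq_m": 1.29e-5,
    },
    "RF": {
        "retention_time_min": 2.06,
        "plates": 9852.0,
        "tailing": 0.65,
        "slope": 2.02e10,
        "intercept": 4.94e3,
        "se_slope": 0.29e4,
        "se_intercept": 0.20e4,
        "sd_intercept": 0.63e4,
        "r": 0.9999,
        "lod_m": 0.10e-5,
        "loq_m": 0.31e-5,
    },
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("photokin.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_kinetics_kobs() -> pd.DataFrame:
    """First-order rate constants k_obs (min^-1) of DPZ photolysis vs
    sensitizer concentration, per pH, lamp and aerobic/anaerobic condition."""
    return _read("kinetics_kobs.csv")


def load_kinetics_blocks() -> pd.DataFrame:
    """Per-(condition, lamp, pH) summary: sensitizer-free k0 (min^-1),
    second-order constant k2 (M^-1 min^-1, as reported) and quantum yield."""
    return _read("kinetics_blocks.csv")


def load_mixture_recoveries() -> pd.DataFrame:
    """Synthetic-mixture recoveries of the two-component assay (added/found M, %, %RSD)."""
    return _read("mixture_recoveries.csv")


def load_method_comparison() -> pd.DataFrame:
    """Paired DPZ recoveries by the UV and HPLC methods over 0.1-1.0e-4 M."""
    return _read("method_comparison.csv")


def load_eco_scale_ledger() -> pd.DataFrame:
    """Eco-scale penalty points per method and item."""
    return _read("eco_scale_ledger.csv")


def load_toc_records() -> pd.DataFrame:
    """TOC/IC/TC (ppb) before and after visible irradiation at pH 7.0."""
    return _read("toc_records.csv")
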