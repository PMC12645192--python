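import numpy as np
import pytest

from photokin import spectra
from photokin.datasets import (
    load_kinetics_blocks,
    load_kinetics_kobs,
    load_method_comparison,
)


@pytest.fixture(scope="session")
def grid():
    return spectra.default_grid()


@pytest.fixture(scope="session")
def epsilon_spectra(grid):
    return {
        "DPZ": spectra.build_chromophore_spectrum(spectra.dpz_chromophore(), grid),
        "RF": spectra.build_chromophore_spectrum(spectra.rf_chromophore(), grid),
    }


@pytest.fixture(scope="session")
def kobs_table():
    return load_kinetics_kobs()


@pytest.fixture(scope="session")
def blocks_table():
    return load_kinetics_blocks()


@pytest.fixture(scope="session")
def comparison_recoveries():
    df = load_method_comparison()
    return (
        df["uv_recovery_percent"].to_numpy(),
        df["hplc_recovery_percent"].to_numpy(),
    )


@pytest.fixture(scope="session")
def rf_grid_m():
    return np.array([0.10e-4, 0.20e-4, 0.30e-4, 0.40e-4, 0.50e-4])
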