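import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photokin import spectra
from photokin.spectra import (
    BandModel,
    ChromophoreSpec,
    absorbance_of_mixture,
    build_chromophore_spectrum,
    default_grid,
    dpz_chromophore,
    equilibrium_complex,
    lamp_preset,
    rf_chromophore,
    simulate_calibration,
    simulate_chromatogram,
    simulate_job_series,
    simulate_photolysis,
)


def local_maxima(values):
    """Brute-force interior local maxima indices."""
    return [
        i
        for i in range(1, len(values) - 1)
        if values[i] >= values[i - 1] and values[i] >= values[i + 1]
    ]


class TestChromophoreSpectrum:
    @pytest.mark.parametrize(
        "chromophore, maxima",
        [
            (dpz_chromophore(), (209.0, 225.0, 269.0, 325.0)),
            (rf_chromophore(), (223.0, 267.0, 385.0, 445.0)),
        ],
        ids=["DPZ", "RF"],
    )
    def test_preset_local_maxima_at_reference_wavelengths(self, grid, chromophore, maxima):
        eps = build_chromophore_spectrum(chromophore, grid)
        peak_wavelengths = grid[local_maxima(eps)]
        step = grid[1] - grid[0]
        for m in maxima:
            assert np.min(np.abs(peak_wavelengths - m)) <= step

    def test_single_band_value_at_center_is_peak_epsilon(self):
        spec = ChromophoreSpec("X", (BandModel(300.0, 5.0, 1.0e4),))
        eps = build_chromophore_spectrum(spec, np.array([300.0]))
        assert eps[0] == pytest.approx(1.0e4, rel=0, abs=0)

    def test_well_separated_bands_argmax_positions(self):
        # two bands > 4 widths apart: argmax within one grid step of each center
        spec = ChromophoreSpec("X", (BandModel(250.0, 5.0, 2.0e4), BandModel(320.0, 8.0, 1.0e4)))
        grid = default_grid(200, 400, 1.0)
        eps = build_chromophore_spectrum(spec, grid)
        peaks = grid[local_maxima(eps)]
        assert np.min(np.abs(peaks - 250.0)) <= 1.0
        assert np.min(np.abs(peaks - 320.0)) <= 1.0

    def test_empty_band_list_rejected(self):
        with pytest.raises(ValueError):
            ChromophoreSpec("empty", ())

    def test_invalid_band_parameters_rejected(self):
        with pytest.raises(ValueError):
            BandModel(-1.0, 5.0, 1.0)
        with pytest.raises(ValueError):
            BandModel(300.0, 0.0, 1.0)


class TestMixtureAbsorbance:
    def test_zero_concentrations_give_zero_spectrum(self, epsilon_spectra, grid):
        a = absorbance_of_mixture(epsilon_spectra, {"DPZ": 0.0, "RF": 0.0}, grid)
        assert np.all(a.absorbance == 0.0)

    def test_linearity_in_each_concentration(self, epsilon_spectra, grid):
        a1 = absorbance_of_mixture(epsilon_spectra, {"DPZ": 1.0e-4, "RF": 0.3e-4}, grid)
        a2 = absorbance_of_mixture(epsilon_spectra, {"DPZ": 2.0e-4, "RF": 0.3e-4}, grid)
        only_dpz = absorbance_of_mixture(epsilon_spectra, {"DPZ": 1.0e-4, "RF": 0.0}, grid)
        np.testing.assert_allclose(a2.absorbance - a1.absorbance, only_dpz.absorbance, rtol=0, atol=1e-15)

    def test_dpz_contribution_at_325_matches_calibration_slope(self, epsilon_spectra, grid):
        # 1.00e-4 M with eps(325) = 1.14e4 per M cm -> A(325) contribution 1.14
        a = absorbance_of_mixture(epsilon_spectra, {"DPZ": 1.00e-4, "RF": 0.0}, grid)
        assert a.at(325.0) == pytest.approx(1.14, rel=1e-3)

    def test_mismatched_grid_rejected(self, epsilon_spectra):
        short = default_grid(200, 400, 1.0)
        with pytest.raises(ValueError):
            absorbance_of_mixture(epsilon_spectra, {"DPZ": 1e-4, "RF": 0.0}, short)


class TestCalibrationSimulation:
    def test_noiseless_responses_exactly_on_line(self):
        concs, resp = simulate_calibration([1e-5, 2e-5, 3e-5], 1.14e4, 0.0, seed=1)
        np.testing.assert_array_equal(resp, 1.14e4 * concs)

    def test_same_seed_reproduces_bit_identical_responses(self):
        _, r1 = simulate_calibration(np.linspace(1e-5, 1e-4, 10), 1.14e4, 0.005, seed=42)
        _, r2 = simulate_calibration(np.linspace(1e-5, 1e-4, 10), 1.14e4, 0.005, seed=42)
        np.testing.assert_array_equal(r1, r2)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_ols_slope_recovers_coefficient_within_three_se(self, seed):
        from photokin.assay import fit_line

        concs, resp = simulate_calibration(np.linspace(0.1e-4, 1.0e-4, 10), 1.14e4, 0.005, seed)
        fit = fit_line(concs, resp)
        assert abs(fit.slope - 1.14e4) <= 3.0 * fit.se_slope

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_calibration([1e-5, 2e-5], 1.0, -0.1, seed=0)


class TestPhotolysisSimulation:
    def test_zero_rate_constant_gives_constant_concentration(self):
        ds = simulate_photolysis(1e-4, 0.0, np.linspace(0, 120, 7))
        assert np.all(ds.true_concentrations["DPZ"] == 1e-4)

    def test_closed_form_exponential(self):
        # k from the reference dataset (pH 2.0, visible, aerobic, RF 0.5e-4)
        ds = simulate_photolysis(1e-4, 1.95e-2, np.array([0.0, 120.0]))
        assert ds.true_concentrations["DPZ"][-1] / 1e-4 == pytest.approx(np.exp(-2.34), rel=1e-12)

    def test_anaerobic_half_life_is_ten_times_aerobic(self):
        times = np.linspace(0, 100, 11)
        aero = simulate_photolysis(1e-4, 0.02, times, condition="aerobic")
        anaero = simulate_photolysis(1e-4, 0.02, times, condition="anaerobic", anaerobic_factor=10.0)
        assert np.log(2) / anaero.k_eff == pytest.approx(10 * np.log(2) / aero.k_eff, rel=1e-12)

    def test_noiseless_log_concentration_is_affine_in_time(self):
        times = np.linspace(0, 200, 21)
        ds = simulate_photolysis(1e-4, 0.015, times)
        lnc = np.log(ds.true_concentrations["DPZ"])
        resid = lnc - (np.log(1e-4) - 0.015 * times)
        assert np.abs(resid).max() < 1e-12

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            simulate_photolysis(1e-4, 0.01, np.array([0.0, 10.0, 5.0]))


class TestJobSeries:
    def test_delta_absorbance_zero_when_one_partner_absent(self):
        ds = simulate_job_series(1e-4, np.linspace(0, 1, 11), 1e5, 1e4)
        assert ds.delta_absorbance[0] == 0.0
        assert ds.delta_absorbance[-1] == 0.0

    def test_strong_binding_maximum_at_half(self):
        fractions = np.linspace(0, 1, 21)
        ds = simulate_job_series(1e-4, fractions, 1e9, 1e4)
        assert fractions[np.argmax(ds.delta_absorbance)] == pytest.approx(0.5)

    def test_complex_matches_quadratic_root_oracle(self):
        # K * total = 1 at x = 0.5
        total, k = 1e-4, 1e4
        ca = cb = 0.5 * total
        # brute-force root of K x^2 - (K(ca+cb)+1) x + K ca cb = 0
        coeffs = [k, -(k * (ca + cb) + 1.0), k * ca * cb]
        roots = np.roots(coeffs)
        oracle = min(r.real for r in roots if 0 <= r.real <= min(ca, cb) + 1e-18)
        assert equilibrium_complex(ca, cb, k) == pytest.approx(oracle, rel=1e-10)

    def test_symmetry_of_delta_absorbance(self):
        fractions = np.linspace(0, 1, 21)
        ds = simulate_job_series(1e-4, fractions, 1e6, 5e3)
        np.testing.assert_allclose(ds.delta_absorbance, ds.delta_absorbance[::-1], rtol=1e-12)

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            simulate_job_series(1e-4, [0.0, 0.5, 1.2], 1e5, 1e4)


class TestChromatogramSimulation:
    def test_zero_concentrations_flat_baseline(self):
        chrom = simulate_chromatogram([0.0, 0.0], [1e10, 1e10], [2.06, 2.78], [0.04, 0.04])
        assert np.all(chrom.signal == 0.0)

    def test_trapezoid_area_within_point_one_percent(self):
        chrom = simulate_chromatogram([1e-4], [0.85e10], [2.78], [0.04])
        area = np.trapezoid(chrom.signal, chrom.times)
        assert area == pytest.approx(0.85e10 * 1e-4, rel=1e-3)

    def test_peak_apexes_at_preset_retention_times(self):
        chrom = simulate_chromatogram(
            [0.5e-4, 1e-4], [2.02e10, 0.85e10], [2.06, 2.78], [0.035, 0.04]
        )
        apex_times = [chrom.times[i] for i in range(1, len(chrom.times) - 1)
                      if chrom.signal[i] >= chrom.signal[i - 1] and chrom.signal[i] >= chrom.signal[i + 1]]
        assert min(abs(t - 2.06) for t in apex_times) < 0.01
        assert min(abs(t - 2.78) for t in apex_times) < 0.01

    def test_identical_retention_times_flagged(self):
        chrom = simulate_chromatogram([1e-4, 1e-4], [1e10, 1e10], [2.5, 2.5], [0.04, 0.04])
        assert chrom.overlapping


class TestLampPresets:
    def test_uv_dominant_line_at_270(self, grid):
        lamp = lamp_preset("UV", grid)
        assert grid[np.argmax(lamp.relative_emission)] == pytest.approx(270.0)

    def test_visible_photon_flux_constant(self):
        assert lamp_preset("visible").photon_flux == pytest.approx(5.51e18)

    def test_uv_photon_flux_constant(self):
        assert lamp_preset("UV").photon_flux == pytest.approx(2.31e17)

    @pytest.mark.parametrize("name", ["UV", "visible"])
    def test_emission_nonnegative(self, name):
        assert np.all(lamp_preset(name).relative_emission >= 0)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            lamp_preset("infrared")


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    c_dpz=st.floats(0, 2e-4),
    c_rf=st.floats(0, 1e-4),
    scale=st.floats(0.1, 5.0),
)
def test_beer_lambert_scaling_property(c_dpz, c_rf, scale):
    """Scaling every concentration scales the whole spectrum (machine precision)."""
    grid = spectra.default_grid(250, 500, 5.0)
    eps = {
        "DPZ": build_chromophore_spectrum(dpz_chromophore(), grid),
        "RF": build_chromophore_spectrum(rf_chromophore(), grid),
    }
    base = absorbance_of_mixture(eps, {"DPZ": c_dpz, "RF": c_rf}, grid)
    scaled = absorbance_of_mixture(eps, {"DPZ": scale * c_dpz, "RF": scale * c_rf}, grid)
    np.testing.assert_allclose(scaled.absorbance, scale * base.absorbance, rtol=1e-12, atol=1e-300)


def test_timecourse_determinism_same_seed_bit_identical():
    times = np.linspace(0, 60, 7)
    grid = spectra.default_grid(300, 500, 5.0)
    a = simulate_photolysis(1e-4, 0.02, times, noise_sd=0.01, seed=7, rf_conc=0.5e-4, grid=grid)
    b = simulate_photolysis(1e-4, 0.02, times, noise_sd=0.01, seed=7, rf_conc=0.5e-4, grid=grid)
    for sa, sb in zip(a.observed_spectra, b.observed_spectra):
        np.testing.assert_array_equal(sa.absorbance, sb.absorbance)


def test_physical_flag_truncates_noisy_absorbance_at_zero():
    times = np.linspace(0, 60, 7)
    grid = spectra.default_grid(600, 700, 5.0)  # region with ~zero absorbance
    ds = simulate_photolysis(1e-6, 0.0, times, noise_sd=0.5, seed=3, grid=grid, physical=True)
    assert all(np.all(s.absorbance >= 0) for s in ds.observed_spectra)
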