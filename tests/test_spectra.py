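"""Spectrum I/O, background subtraction and Lorentzian peak fitting."""

import numpy as np
import pytest

from diracsense.spectra import (G_BAND_WINDOW, SIGMA_FLOOR, TWOD_BAND_WINDOW,
                                DispersionCurve, RamanSpectrum, build_dispersion,
                                fit_band, fit_lorentzian_peak, read_spectrum,
                                subtract_background, write_spectrum)
from diracsense.simulate import ScenarioConfig, make_spectrum, make_sweep


def lorentz(w, center, fwhm, amplitude):
    half = fwhm / 2.0
    return amplitude * half ** 2 / ((w - center) ** 2 + half ** 2)


@pytest.fixture(scope="module")
def grid():
    return np.arange(1450.0, 2951.0, 1.0)


def test_band_windows_match_the_analysis_protocol():
    assert G_BAND_WINDOW == (1550.0, 1680.0)
    assert TWOD_BAND_WINDOW == (2600.0, 2830.0)
    assert SIGMA_FLOOR == 0.4


class TestSpectrumIO:
    def test_round_trip(self, tmp_path, grid):
        spec = RamanSpectrum(grid, lorentz(grid, 1589, 15, 1000) + 100.0, bias=-0.25)
        path = tmp_path / "spec.txt"
        write_spectrum(spec, path)
        back = read_spectrum(path)
        np.testing.assert_allclose(back.wavenumber, spec.wavenumber, atol=1e-6)
        np.testing.assert_allclose(back.intensity, spec.intensity, rtol=1e-7)
        assert back.bias == pytest.approx(-0.25)

    def test_parses_comma_separated_and_comments(self, tmp_path):
        path = tmp_path / "spec.csv"
        rows = "\n".join(f"{1500 + i},{10 + i}" for i in range(20))
        path.write_text("# a comment\n" + rows + "\n")
        spec = read_spectrum(path)
        assert len(spec) == 20

    def test_sorts_rows_by_wavenumber(self, tmp_path):
        path = tmp_path / "rev.txt"
        path.write_text("\n".join(f"{1520 - i} {i}" for i in range(20)))
        spec = read_spectrum(path)
        assert np.all(np.diff(spec.wavenumber) > 0)

    def test_duplicate_wavenumber_rejected(self, tmp_path):
        path = tmp_path / "dup.txt"
        path.write_text("\n".join(f"{1500 + min(i, 10)} {i}" for i in range(20)))
        with pytest.raises(ValueError, match="duplicated"):
            read_spectrum(path)

    def test_malformed_row_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("1500 1\n1501 2\nnot numbers here\n")
        with pytest.raises(ValueError):
            read_spectrum(path)

    def test_too_short_rejected(self, tmp_path):
        path = tmp_path / "short.txt"
        path.write_text("1500 1\n1501 2\n")
        with pytest.raises(ValueError):
            read_spectrum(path)


class TestRamanSpectrumInvariants:
    def test_length_mismatch(self, grid):
        with pytest.raises(ValueError):
            RamanSpectrum(grid, grid[:-1])

    def test_non_monotone(self):
        w = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        with pytest.raises(ValueError):
            RamanSpectrum(w, np.zeros(8))

    def test_non_finite(self, grid):
        y = np.zeros_like(grid)
        y[5] = np.inf
        with pytest.raises(ValueError):
            RamanSpectrum(grid, y)


class TestSubtractBackground:
    def test_pure_polynomial_leaves_nothing(self, grid):
        y = 3.0 + 0.01 * (grid - 2000) + 1e-5 * (grid - 2000) ** 2
        spec = RamanSpectrum(grid, y)
        flat = subtract_background(spec, G_BAND_WINDOW, order=2)
        assert np.max(np.abs(flat.intensity)) < 1e-8 * np.max(np.abs(y))

    def test_recovers_peak_on_quadratic_baseline(self, grid):
        y = lorentz(grid, 1589.0, 15.0, 1000.0) + (
            200 + 0.05 * (grid - 2000) + 2e-5 * (grid - 2000) ** 2)
        flat = subtract_background(RamanSpectrum(grid, y), G_BAND_WINDOW, order=2,
                                   exclusion_half_width=40.0)
        truth = lorentz(flat.wavenumber, 1589.0, 15.0, 1000.0)
        assert np.max(np.abs(flat.intensity - truth)) < 0.01 * 1000.0

    def test_idempotent_on_clean_input(self, grid):
        y = lorentz(grid, 1589.0, 15.0, 1000.0) + 50.0 + 0.02 * (grid - 2000)
        once = subtract_background(RamanSpectrum(grid, y), G_BAND_WINDOW)
        twice = subtract_background(once, G_BAND_WINDOW)
        scale = np.max(np.abs(once.intensity))
        assert np.max(np.abs(twice.intensity - once.intensity)) < 1e-9 * scale * 10

    def test_window_outside_range(self, grid):
        with pytest.raises(ValueError, match="outside"):
            subtract_background(RamanSpectrum(grid, np.ones_like(grid)), (3000, 3100))

    def test_bad_order(self, grid):
        with pytest.raises(ValueError):
            subtract_background(RamanSpectrum(grid, np.ones_like(grid)),
                                G_BAND_WINDOW, order=3)

    def test_overwide_exclusion_rejected(self, grid):
        spec = RamanSpectrum(grid, lorentz(grid, 1589, 15, 100) + 1.0)
        with pytest.raises(ValueError, match="exclusion"):
            subtract_background(spec, G_BAND_WINDOW, exclusion_half_width=500.0)


class TestLorentzianFit:
    def test_noiseless_center_recovery(self, grid):
        spec = RamanSpectrum(grid, lorentz(grid, 1589.0, 15.0, 1000.0))
        fit = fit_lorentzian_peak(spec, G_BAND_WINDOW)
        assert fit.center == pytest.approx(1589.0, abs=0.01)
        assert fit.fwhm == pytest.approx(15.0, abs=0.01)
        assert fit.converged

    def test_off_grid_center(self, grid):
        spec = RamanSpectrum(grid, lorentz(grid, 1590.37, 15.0, 800.0))
        fit = fit_lorentzian_peak(spec, G_BAND_WINDOW)
        assert fit.center == pytest.approx(1590.37, abs=0.01)

    def test_replicate_scatter_matches_instrument_error(self, scenario):
        """Fitted centers of noisy replicates scatter by ≈0.4 cm⁻¹ (1 sd)."""
        rng = np.random.default_rng(42)
        centers = []
        for _ in range(200):
            spec = make_spectrum(scenario, 0.0, rng=rng)
            centers.append(fit_band(spec, "G").center)
        sd = float(np.std(centers))
        assert 0.3 <= sd <= 0.5

    def test_monotone_window_rejected(self, grid):
        spec = RamanSpectrum(grid, 0.1 * grid)
        with pytest.raises(ValueError, match="maximum"):
            fit_lorentzian_peak(spec, G_BAND_WINDOW)

    def test_2d_band_fit(self, scenario):
        spec = make_spectrum(scenario, 0.0, noise_sd=0.0)
        fit = fit_band(spec, "2D")
        shift_g = fit_band(spec, "G").center - 1580.0
        assert fit.center == pytest.approx(2690.0 + 0.7 * shift_g, abs=0.05)


class TestBuildDispersion:
    def test_eleven_point_sweep(self, scenario):
        curve = build_dispersion(make_sweep(scenario, noise_sd=0.0))
        assert len(curve) == 11
        assert np.all(np.diff(curve.bias) > 0)
        assert np.all(curve.sigma == 0.4)  # noiseless fits clip up to the floor

    def test_orders_points_by_bias(self, scenario):
        sweep = make_sweep(scenario, noise_sd=0.0)
        curve = build_dispersion(sweep[::-1])
        assert np.all(np.diff(curve.bias) > 0)

    def test_duplicate_bias_rejected(self, scenario):
        sweep = make_sweep(scenario, noise_sd=0.0)
        sweep[1] = sweep[0]
        with pytest.raises(ValueError, match="same bias"):
            build_dispersion(sweep)

    def test_missing_bias_rejected(self, scenario):
        sweep = make_sweep(scenario, noise_sd=0.0)
        sweep[0].bias = None
        with pytest.raises(ValueError, match="no bias"):
            build_dispersion(sweep)

    def test_failing_member_names_bias(self, scenario):
        w = np.arange(2000.0, 2500.0, 1.0)  # does not cover the G window
        sweep = make_sweep(scenario, noise_sd=0.0)[:5]
        sweep.append(RamanSpectrum(w, np.ones_like(w), bias=-0.4))
        with pytest.raises(RuntimeError, match="-0.400"):
            build_dispersion(sweep)


class TestDispersionCurve:
    def test_too_few_points(self):
        with pytest.raises(ValueError):
            DispersionCurve([0.0, -0.1, -0.2], [1589, 1590, 1591], [0.4] * 3)

    def test_from_table_round_trip_sorted_by_bias(self):
        table = np.array([[0.0, 1589.0, 0.4], [-0.1, 1590.5, 0.4],
                          [-0.2, 1592.0, 0.4], [-0.3, 1593.0, 0.4]])
        curve = DispersionCurve.from_table(table)
        np.testing.assert_allclose(curve.to_table(), table[::-1])
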