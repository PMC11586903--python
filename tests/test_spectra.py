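import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esptools.errors import AxisAlignmentError, DataError
from esptools.spectra import (ABSORBANCE, EMISSION, Spectrum, WAVELENGTH_NM,
                              emission_to_wavenumber_scale, isosbestic_points,
                              nm_to_wavenumber, peak_position,
                              wavenumber_to_nm)
from esptools.synthetic import (BandSpec, gen_titration,
                                isosbestic_amplitude_ratio)


def gaussian_band(center, fwhm, lam):
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    return np.exp(-0.5 * ((lam - center) / sigma) ** 2)


class TestConversions:
    @pytest.mark.parametrize("nm,expected", [
        (346.0, 28901.73), (1e7, 1.0), (489.0, 20449.90)])
    def test_known_values(self, nm, expected):
        assert nm_to_wavenumber(nm) == pytest.approx(expected, abs=0.01)

    @given(st.floats(min_value=100.0, max_value=1e7))
    @settings(derandomize=True, max_examples=50)
    def test_roundtrip_involution(self, nm):
        assert wavenumber_to_nm(nm_to_wavenumber(nm)) == pytest.approx(
            nm, rel=1e-10)

    @pytest.mark.parametrize("bad", [0.0, -5.0])
    def test_non_positive_rejected(self, bad):
        with pytest.raises(DataError):
            nm_to_wavenumber(bad)


class TestSpectrumInvariants:
    def test_rejects_short_or_non_monotone(self):
        with pytest.raises(DataError):
            Spectrum([400.0, 500.0], [1.0, 1.0])
        with pytest.raises(DataError):
            Spectrum([400.0, 450.0, 440.0], [1.0, 1.0, 1.0])

    def test_rejects_non_positive_wavelength(self):
        with pytest.raises(DataError):
            Spectrum([-1.0, 400.0, 500.0], [1.0, 1.0, 1.0])


class TestLambdaSquaredCorrection:
    def test_absorbance_input_rejected(self):
        spec = Spectrum(np.linspace(300, 500, 50), np.ones(50),
                        WAVELENGTH_NM, ABSORBANCE)
        with pytest.raises(DataError):
            emission_to_wavenumber_scale(spec)

    def test_flat_signal_becomes_lambda_squared(self):
        lam = np.linspace(400, 800, 401)
        spec = Spectrum(lam, np.ones_like(lam), WAVELENGTH_NM, EMISSION)
        out = emission_to_wavenumber_scale(spec)
        # I(nu) proportional to lambda^2 = 1e14/nu^2, maximal at the red edge
        assert out.axis[0] < out.axis[-1]
        assert np.argmax(out.signal) == 0
        assert np.allclose(out.signal, (1e7 / out.axis) ** 2)

    def test_corrected_peak_red_shifts(self):
        lam = np.arange(380, 620, 0.5)
        spec = Spectrum(lam, gaussian_band(489, 80, lam), WAVELENGTH_NM,
                        EMISSION)
        nu_peak = peak_position(emission_to_wavenumber_scale(spec))
        assert nu_peak < nm_to_wavenumber(489.0)

    def test_corrected_peak_matches_brute_force(self):
        # oracle: dense maximization of lambda^2 * G(lambda) on a 0.01 nm grid
        dense = np.arange(380.0, 620.0, 0.01)
        oracle_lam = dense[np.argmax(dense**2 * gaussian_band(489, 80, dense))]
        lam = np.arange(380, 620, 0.5)
        spec = Spectrum(lam, gaussian_band(489, 80, lam), WAVELENGTH_NM,
                        EMISSION)
        nu_peak = peak_position(emission_to_wavenumber_scale(spec))
        assert 1e7 / nu_peak == pytest.approx(oracle_lam, abs=0.05)

    def test_jacobian_conserves_band_integral(self):
        # integral of I(nu) dnu must equal 1e7 * integral of I(lambda) dlambda
        lam = np.arange(380.0, 620.0, 0.02)
        spec = Spectrum(lam, gaussian_band(489, 80, lam), WAVELENGTH_NM,
                        EMISSION)
        out = emission_to_wavenumber_scale(spec)
        area_nu = np.trapezoid(out.signal, out.axis)
        area_lam = np.trapezoid(spec.signal, spec.axis)
        assert area_nu == pytest.approx(1e7 * area_lam, rel=1e-3)


class TestPeakPosition:
    def test_exact_parabola_vertex(self):
        lam = np.arange(340, 353, 1.0)
        spec = Spectrum(lam, -(lam - 346.3) ** 2 + 100.0)
        assert peak_position(spec) == pytest.approx(346.3, abs=1e-9)

    def test_gaussian_band_on_nm_grid(self):
        lam = np.arange(250, 450, 1.0)
        spec = Spectrum(lam, gaussian_band(346, 60, lam))
        assert peak_position(spec) == pytest.approx(346.0, abs=0.05)

    def test_matches_dense_argmax_for_asymmetric_band(self):
        lam = np.arange(250.0, 500.0, 1.0)
        sig = gaussian_band(346, 60, lam) + 0.5 * gaussian_band(370, 80, lam)
        dense = np.arange(250.0, 500.0, 0.01)
        dense_sig = (gaussian_band(346, 60, dense)
                     + 0.5 * gaussian_band(370, 80, dense))
        oracle = dense[np.argmax(dense_sig)]
        assert peak_position(Spectrum(lam, sig)) == pytest.approx(oracle,
                                                                  abs=0.05)

    def test_monotone_ramp_warns_and_returns_boundary(self):
        lam = np.linspace(300, 400, 20)
        with pytest.warns(UserWarning, match="boundary"):
            assert peak_position(Spectrum(lam, lam.copy())) == 400.0


class TestIsosbesticPoints:
    def _family(self, ratio_crossing=None, grid_step=1.0, noise=0.0, seed=0):
        amp1 = 2.3e4
        if ratio_crossing is not None:
            amp1 = isosbestic_amplitude_ratio(346., 397., 60.,
                                              ratio_crossing) * 2.5e4
        series, _ = gen_titration(
            [4.49], [[BandSpec(346., 60., amp1)], [BandSpec(397., 60., 2.5e4)]],
            np.linspace(3.2, 5.6, 8), grid=(250., 500., grid_step),
            noise_sigma=noise, seed=seed)
        return [Spectrum(series.axis, row) for row in series.response_matrix]

    def test_constructed_crossing_at_369(self):
        pts = isosbestic_points(self._family(ratio_crossing=369.0), 0.01)
        assert len(pts) == 1
        assert pts[0] == pytest.approx(369.0, abs=1.0)

    def test_two_species_family_crossing(self):
        # equal-width 346/397 bands with amplitudes 2.3/2.5 cross at 370.44
        pts = isosbestic_points(self._family(grid_step=0.25), 0.01)
        assert len(pts) == 1
        assert pts[0] == pytest.approx(370.44, abs=0.5)

    def test_identical_spectra_degenerate(self):
        lam = np.linspace(250, 500, 251)
        sig = gaussian_band(346, 60, lam)
        fam = [Spectrum(lam, sig) for _ in range(4)]
        with pytest.warns(UserWarning, match="degenerate"):
            assert isosbestic_points(fam) == []

    def test_no_common_crossing(self, rng):
        lam = np.linspace(250, 500, 251)
        fam = [Spectrum(lam, rng.uniform(0.5, 1.5, lam.size))
               for _ in range(3)]
        assert isosbestic_points(fam, 0.01) == []

    def test_requires_three_spectra(self):
        fam = self._family()[:2]
        with pytest.raises(DataError):
            isosbestic_points(fam)

    def test_mismatched_axes_rejected(self):
        lam = np.linspace(300, 500, 100)
        fam = [Spectrum(lam, gaussian_band(380, 60, lam)),
               Spectrum(lam + 100, gaussian_band(380, 60, lam)),
               Spectrum(lam, gaussian_band(390, 60, lam))]
        with pytest.raises(AxisAlignmentError):
            isosbestic_points(fam)
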