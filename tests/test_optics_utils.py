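"""Closed-form optics: pulse family, effective medium, Mie, Rayleigh length."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from slabmc.optics_utils import (
    MaterialSpec,
    PulseSpec,
    autocorrelation_fwhm_ratio,
    maxwell_garnett_index,
    mie_anisotropy,
    mie_coefficients,
    mie_efficiencies,
    mie_scattering_mfp,
    mie_transport_mfp,
    pulse_fwhm_from_autocorrelation,
    rayleigh_length,
    sech2_autocorrelation,
    sech2_pulse_intensity,
    sech2_spectrum,
)

PULSE94 = PulseSpec("sech2", 94.0, center_frequency=2.33)


def _fwhm_of(f, peak_t=0.0, halfspan=1000.0):
    peak = f(peak_t)
    right = brentq(lambda t: f(t) - peak / 2, peak_t + 1e-9, peak_t + halfspan)
    left = brentq(lambda t: f(t) - peak / 2, peak_t - halfspan, peak_t - 1e-9)
    return right - left


class TestSech2Pulse:
    def test_unit_energy_and_fwhm(self):
        integral, _ = quad(lambda t: sech2_pulse_intensity(t, PULSE94), -3000, 3000)
        assert integral == pytest.approx(1.0, abs=1e-9)
        assert _fwhm_of(lambda t: sech2_pulse_intensity(t, PULSE94)) == pytest.approx(94.0, abs=1e-6)
        # half maximum sits exactly at ±Δτp/2
        assert sech2_pulse_intensity(47.0, PULSE94) == pytest.approx(
            0.5 * sech2_pulse_intensity(0.0, PULSE94), rel=1e-12)

    def test_rate_constant(self):
        assert PULSE94.gamma_p == pytest.approx(2 * math.log(1 + math.sqrt(2)) / 94.0, rel=1e-12)

    def test_rejects_wrong_shape(self):
        with pytest.raises(ValueError, match="sech2"):
            sech2_pulse_intensity(0.0, PulseSpec("gaussian", 94.0))


class TestAutocorrelation:
    def test_even_and_finite_at_zero(self):
        t = np.linspace(-400, 400, 801)
        ac = sech2_autocorrelation(t, 145.0)
        np.testing.assert_allclose(ac, ac[::-1], rtol=1e-12)
        assert np.isfinite(sech2_autocorrelation(0.0, 145.0))

    def test_matches_numerical_autoconvolution(self):
        # brute-force oracle: FFT autoconvolution of the pulse intensity
        fwhm = 94.0
        n = 2**14
        dt = 0.25
        t = (np.arange(n) - n // 2) * dt
        pulse = sech2_pulse_intensity(t, PulseSpec("sech2", fwhm))
        conv = np.convolve(pulse, pulse) * dt
        t_conv = 2 * t[0] + np.arange(2 * n - 1) * dt
        closed = sech2_autocorrelation(t_conv, fwhm * autocorrelation_fwhm_ratio())
        mask = conv > conv.max() * 1e-8
        assert np.max(np.abs(closed[mask] - conv[mask]) / conv.max()) < 1e-5

    def test_fwhm_mapping_145_to_94(self):
        assert pulse_fwhm_from_autocorrelation(145.0) == pytest.approx(94.0, abs=0.5)

    @pytest.mark.parametrize("ac", [50.0, 145.0, 400.0])
    def test_family_ratio_constant(self, ac):
        assert ac / pulse_fwhm_from_autocorrelation(ac) == pytest.approx(1.5427, abs=2e-4)

    def test_roundtrip(self):
        fwhm = 120.0
        ac = _fwhm_of(lambda t: sech2_autocorrelation(t, fwhm * autocorrelation_fwhm_ratio()),
                      halfspan=2000)
        assert pulse_fwhm_from_autocorrelation(ac) == pytest.approx(fwhm, abs=1e-6)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            pulse_fwhm_from_autocorrelation(-1.0)


class TestSpectrum:
    def test_peak_at_carrier(self):
        w = np.linspace(1.8, 2.9, 4001)
        s = sech2_spectrum(w, PULSE94)
        assert w[np.argmax(s)] == pytest.approx(PULSE94.center_frequency, abs=1e-3)

    def test_matches_field_fourier_transform(self):
        # the spectrum is |FT of the field envelope sech(γt)|²
        g = PULSE94.gamma_p
        n = 2**16
        dt = 0.5
        t = (np.arange(n) - n // 2) * dt
        field = 1.0 / np.cosh(g * t)
        spec = np.abs(np.fft.fftshift(np.fft.fft(np.fft.ifftshift(field)))) ** 2
        w = 2 * np.pi * np.fft.fftshift(np.fft.fftfreq(n, dt))
        spec /= np.trapezoid(spec, w)
        closed = sech2_spectrum(w + PULSE94.center_frequency, PULSE94)
        mask = spec > spec.max() * 1e-3
        assert np.max(np.abs(closed[mask] - spec[mask])) / spec.max() < 1e-4

    def test_time_bandwidth_product(self):
        w = np.linspace(-0.5, 0.5, 400001) + PULSE94.center_frequency
        s = sech2_spectrum(w, PULSE94)
        idx = np.flatnonzero(s >= s.max() / 2)
        dnu = (w[idx[-1]] - w[idx[0]]) / (2 * np.pi)
        assert dnu * 94.0 == pytest.approx(0.315, abs=0.001)

    def test_requires_center_frequency(self):
        with pytest.raises(ValueError, match="center_frequency"):
            sech2_spectrum(0.0, PulseSpec("sech2", 94.0))


class TestMaxwellGarnett:
    COMPOSITE = MaterialSpec(1.509, 2.5, 0.02, 280.0, 1510.0)

    def test_limits(self):
        assert maxwell_garnett_index(MaterialSpec(1.509, 2.5, 0.0)) == pytest.approx(1.509, rel=1e-12)
        assert maxwell_garnett_index(MaterialSpec(1.509, 2.5, 1.0)) == pytest.approx(2.5, rel=1e-12)

    def test_rutile_composite(self):
        assert maxwell_garnett_index(self.COMPOSITE) == pytest.approx(1.526, abs=5e-4)

    def test_monotone_in_fraction(self):
        vals = [maxwell_garnett_index(MaterialSpec(1.509, 2.5, f)) for f in np.linspace(0, 1, 21)]
        assert np.all(np.diff(vals) > 0)

    def test_rejects_bad_fraction(self):
        with pytest.raises(ValueError):
            MaterialSpec(1.509, 2.5, 1.5)


def _mie_g_by_quadrature(x, m):
    """Oracle: ⟨cosθ⟩ by quadrature of the phase function |S1|²+|S2|²."""
    a, b = mie_coefficients(x, m)
    mu = np.linspace(-1, 1, 40001)
    s1 = np.zeros_like(mu, dtype=complex)
    s2 = np.zeros_like(mu, dtype=complex)
    pi_nm1, pi_n = np.zeros_like(mu), np.ones_like(mu)
    for n in range(1, a.size + 1):
        tau_n = n * mu * pi_n - (n + 1) * pi_nm1
        f = (2 * n + 1) / (n * (n + 1))
        s1 += f * (a[n - 1] * pi_n + b[n - 1] * tau_n)
        s2 += f * (a[n - 1] * tau_n + b[n - 1] * pi_n)
        pi_nm1, pi_n = pi_n, ((2 * n + 1) * mu * pi_n - (n + 1) * pi_nm1) / n
    p = np.abs(s1) ** 2 + np.abs(s2) ** 2
    return np.trapezoid(mu * p, mu) / np.trapezoid(p, mu)


class TestMie:
    COMPOSITE = MaterialSpec(1.509, 2.5, 0.02, 280.0, 1510.0)

    def test_rayleigh_limit_isotropic(self):
        tiny = MaterialSpec(1.509, 2.5, 0.02, 2.0, 1510.0)
        assert abs(mie_anisotropy(tiny)) < 1e-3

    def test_rutile_anisotropy(self):
        assert mie_anisotropy(self.COMPOSITE) == pytest.approx(0.165, abs=0.01)

    @pytest.mark.parametrize("x", [0.1, 0.5, 0.879, 2.0, 5.0])
    def test_series_vs_quadrature_oracle(self, x):
        m = 2.5 / 1.509
        a, b = mie_coefficients(x, m)
        n = np.arange(1, a.size + 1)
        qsca = (2 / x**2) * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
        g_series = (4 / x**2 / qsca) * (
            np.sum(n[:-1] * (n[:-1] + 2) / (n[:-1] + 1)
                   * np.real(a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:])))
            + np.sum((2 * n + 1) / (n * (n + 1)) * np.real(a * np.conj(b))))
        assert g_series == pytest.approx(_mie_g_by_quadrature(x, m), abs=1e-4)

    def test_transport_mfp_in_expected_range(self):
        assert 40.0 <= mie_transport_mfp(self.COMPOSITE) <= 50.0

    def test_mfp_scales_inversely_with_fraction(self):
        half = MaterialSpec(1.509, 2.5, 0.01, 280.0, 1510.0)
        assert mie_transport_mfp(half) == pytest.approx(2 * mie_transport_mfp(self.COMPOSITE), rel=1e-9)

    def test_transport_vs_scattering_mfp(self):
        _, g = mie_efficiencies(self.COMPOSITE)
        assert mie_transport_mfp(self.COMPOSITE) * (1 - g) == pytest.approx(
            mie_scattering_mfp(self.COMPOSITE), rel=1e-12)

    def test_zero_fraction_signals_infinite_mfp(self):
        with pytest.raises(ValueError, match="infinite"):
            mie_scattering_mfp(MaterialSpec(1.509, 2.5, 0.0, 280.0, 1510.0))


class TestRayleighLength:
    def test_ten_micron_spot(self):
        assert rayleigh_length(5.0, 1.51) == pytest.approx(50.0, rel=0.10)

    def test_quadratic_scaling_and_identity(self):
        zr = rayleigh_length(5.0, 1.51)
        assert rayleigh_length(10.0, 1.51) == pytest.approx(4 * zr, rel=1e-12)
        assert zr * 1.51 / (math.pi * 25.0) == pytest.approx(1.0, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            rayleigh_length(0.0, 1.51)
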