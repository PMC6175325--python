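"""Fractional moduli, long-tailed spectra, Mittag-Leffler and Prony chains."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import erfcx, rgamma

from rheowave.fractional import (
    FractionalParams,
    HysteresisModulus,
    SpectralCoverageError,
    SpectralDensity,
    creep_from_spectrum,
    discretize_spectrum,
    fit_loglog_slope,
    frac_modulus,
    freq_spectral,
    hysteresis_limit_check,
    hysteresis_modulus,
    mittag_leffler,
    ml_creep,
    time_spectral,
)
from rheowave.viscoelastic import ZenerParams, network_modulus, zener_modulus


class TestFracModulus:
    def test_static_limit_is_equilibrium_modulus(self):
        for a in (0.2, 0.7, 1.0):
            p = FractionalParams(3.0, 1.0, 0.1, a)
            assert frac_modulus(p, 0.0)[0] == pytest.approx(3.0 + 0.0j)

    def test_alpha_one_equals_zener(self, zener_unit):
        p = FractionalParams(1.0, 2.0, 1.0, 1.0)
        w = np.geomspace(1e-4, 1e4, 161)
        np.testing.assert_allclose(
            frac_modulus(p, w), zener_modulus(zener_unit, w), rtol=1e-14
        )
        assert frac_modulus(p, 1.0)[0] == pytest.approx(1.5 + 0.5j)

    def test_springpot_phase_at_high_frequency(self):
        # tau_sig = 0, w tau >> 1: E -> (i w eta)^alpha, arg E -> alpha pi/2
        # (approached as (w tau)^-alpha, so only to ~1e-3 at w tau = 1e12)
        for a in (0.3, 0.6, 0.9):
            p = FractionalParams(1.0, 1.0, 0.0, a)
            E = frac_modulus(p, 1e12)[0]
            assert np.angle(E) == pytest.approx(a * np.pi / 2.0, abs=1e-3)

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            FractionalParams(1.0, 1.0, 0.0, 1.2)
        with pytest.raises(ValueError):
            FractionalParams(1.0, 1.0, 2.0, 0.5)


class TestTimeSpectral:
    def test_value_at_knee_alpha_half(self):
        # sin(pi/2) / (1 + 1 + 0) / (pi tau_eps) = 1/(2 pi tau_eps)
        p = FractionalParams(1.0, 1.0, 0.0, 0.5)
        S = time_spectral(p, [1.0])
        assert S.values[0] == pytest.approx(1.0 / (2.0 * np.pi))

    def test_alpha_one_is_single_relaxation_atom(self):
        p = FractionalParams(1.0, 2.0, 1.0, 1.0)
        S = time_spectral(p, np.geomspace(0.1, 10, 5))
        assert S.atom == 2.0
        assert np.all(S.values == 0.0)

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 0.8])
    def test_asymptote_slopes(self, alpha):
        """Log-log tails fall as alpha-1 (short times) and -alpha-1 (long).

        The sub-leading denominator term decays only as (tau/tau_eps)^alpha,
        so the fit windows sit 10-12 decades from the knee where it is below
        the 0.01 slope tolerance for every order tested.
        """
        p = FractionalParams(1.0, 1.0, 0.0, alpha)
        lo = np.geomspace(1e-12, 1e-10, 41)
        hi = np.geomspace(1e10, 1e12, 41)
        assert fit_loglog_slope(lo, time_spectral(p, lo).values) == pytest.approx(
            alpha - 1.0, abs=0.01
        )
        assert fit_loglog_slope(hi, time_spectral(p, hi).values) == pytest.approx(
            -alpha - 1.0, abs=0.01
        )

    @pytest.mark.parametrize("alpha", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_unit_normalization(self, alpha):
        """The time-spectral density carries unit mass for every order."""
        p = FractionalParams(1.0, 1.0, 0.0, alpha)

        def integrand(u):
            return time_spectral(p, [np.exp(u)]).values[0] * np.exp(u)

        lim = 60.0 / alpha
        total, _ = quad(integrand, -lim, lim, points=[0.0], limit=400)
        assert total == pytest.approx(1.0, abs=1e-6)


class TestFreqSpectral:
    @pytest.mark.parametrize("alpha", [0.1, 0.5, 0.8, 0.9])
    def test_time_frequency_consistency(self, alpha):
        """S(Omega) = a R(1/Omega)/Omega^2 pointwise (algebraic identity)."""
        p = FractionalParams(2.0, 1.0, 1e-3, alpha)
        om = np.geomspace(1e-8, 1e8, 201)
        S = freq_spectral(p, om)
        R = time_spectral(p, 1.0 / om)
        rhs = p.norm_compliance * R.values / om**2
        np.testing.assert_allclose(S.values, rhs, rtol=1e-14)

    def test_small_alpha_approaches_inverse_frequency(self):
        """As alpha -> 0 both tails of the spectrum approach Omega^-1."""
        p = FractionalParams(1.0, 1.0, 0.0, 0.01)
        lo = np.geomspace(1e-6, 1e-4, 41)
        hi = np.geomspace(1e4, 1e6, 41)
        assert fit_loglog_slope(lo, freq_spectral(p, lo).values) == pytest.approx(
            -1.0, abs=0.02
        )
        assert fit_loglog_slope(hi, freq_spectral(p, hi).values) == pytest.approx(
            -1.0, abs=0.02
        )

    def test_densities_are_nonnegative(self):
        p = FractionalParams(1.0, 1.0, 1e-2, 0.6)
        om = np.geomspace(1e-9, 1e9, 301)
        assert np.all(freq_spectral(p, om).values >= 0.0)
        assert np.all(time_spectral(p, 1.0 / om).values >= 0.0)


class TestMittagLeffler:
    def test_at_zero_is_one(self):
        for a in (0.1, 0.5, 0.9, 1.0):
            assert mittag_leffler(a, 0.0) == pytest.approx(1.0)

    def test_order_one_is_exponential(self):
        assert mittag_leffler(1.0, -1.0) == pytest.approx(np.exp(-1.0), rel=1e-14)

    @pytest.mark.parametrize("x", [1e-3, 0.1, 0.5, 1.0, 2.0, 10.0, 1e2, 1e4])
    def test_half_order_erfc_identity(self, x):
        """E_{1/2}(-x) = exp(x^2) erfc(x), stable via erfcx."""
        assert mittag_leffler(0.5, -x) == pytest.approx(erfcx(x), rel=1e-10)

    @pytest.mark.parametrize("num_den", [(2, 5), (3, 5), (4, 5)])
    @pytest.mark.parametrize("x", [0.5, 2.0, 5.0])
    def test_against_high_precision_series(self, num_den, x):
        """80-digit direct series summation as the independent oracle.

        The order is passed to mpmath as an exact rational: a float order
        perturbs the huge alternating terms enough to destroy the
        cancellation.
        """
        import mpmath as mp

        num, den = num_den
        mp.mp.dps = 80
        alpha_mp = mp.mpf(num) / den
        acc, n = mp.mpf(0), 0
        while True:
            term = mp.mpf(-x) ** n / mp.gamma(alpha_mp * n + 1)
            acc += term
            n += 1
            if abs(term) < mp.mpf(10) ** -60 and n > 10:
                break
        assert mittag_leffler(num / den, -x) == pytest.approx(float(acc), rel=1e-10)

    @pytest.mark.parametrize("alpha", [0.3, 0.7])
    def test_large_argument_asymptotics(self, alpha):
        # E_a(-x) ~ 1/(x Gamma(1-a)) - 1/(x^2 Gamma(1-2a))
        x = 1e6
        two_term = rgamma(1.0 - alpha) / x - rgamma(1.0 - 2.0 * alpha) / x**2
        assert mittag_leffler(alpha, -x) == pytest.approx(two_term, rel=1e-5)

    def test_unsupported_branch_rejected(self):
        with pytest.raises(ValueError):
            mittag_leffler(0.5, 1.0)
        with pytest.raises(ValueError):
            mittag_leffler(1.5, -1.0)


class TestCreepFromSpectrum:
    def test_limits(self):
        p = FractionalParams(2.0, 1.0, 1e-2, 0.6)
        S = freq_spectral(p, np.geomspace(1e-8, 1e8, 10))
        J = creep_from_spectrum(S, [1e-12, 1e9])
        assert J[0] == pytest.approx(0.0, abs=1e-6 * p.norm_compliance)
        assert J[1] == pytest.approx(p.norm_compliance, rel=1e-5)

    @pytest.mark.parametrize("alpha", [0.3, 0.5, 0.7])
    def test_quadrature_matches_mittag_leffler_oracle(self, alpha):
        """Spectral superposition equals the closed-form fractional creep."""
        p = FractionalParams(1.0, 1.0, 0.0, alpha)
        t = np.geomspace(1e-3, 1e3, 25)
        S = freq_spectral(p, np.geomspace(1e-8, 1e8, 10))
        np.testing.assert_allclose(creep_from_spectrum(S, t), ml_creep(p, t), rtol=1e-6)

    def test_atom_density_gives_exponential_creep(self):
        p = FractionalParams(1.0, 2.0, 1.0, 1.0)
        S = freq_spectral(p, np.geomspace(0.01, 100, 5))
        t = np.array([0.5, 2.0, 20.0])
        expected = p.norm_compliance * -np.expm1(-t / p.tau_eps)
        np.testing.assert_allclose(creep_from_spectrum(S, t), expected, rtol=1e-12)

    def test_generic_relaxation_transforms_are_consistent(self):
        """A time density and its frequency transform b R(1/Om)/Om^2 give
        the same relaxation superposition."""
        from rheowave.fractional import relaxation_from_spectrum

        tau = np.geomspace(1e-8, 1e8, 2001)
        b = 2.5
        vals = np.exp(-0.5 * (np.log(tau) / 2.0) ** 2) / tau  # ad hoc density
        R = SpectralDensity("time", tau, vals, 1.0)
        om = 1.0 / tau[::-1]
        S = SpectralDensity("frequency", om, b * vals[::-1] * tau[::-1] ** 2 / 1.0, 1.0)
        t = np.geomspace(1e-2, 1e2, 11)
        g_time = relaxation_from_spectrum(R, t, amplitude=b)
        g_freq = relaxation_from_spectrum(S, t)
        np.testing.assert_allclose(g_freq, g_time, rtol=1e-6)

    def test_sampled_density_requires_coverage(self):
        grid = np.geomspace(1e-2, 1e2, 50)  # only 4 decades
        p = FractionalParams(1.0, 1.0, 0.0, 0.5)
        S = SpectralDensity("frequency", grid, np.ones_like(grid), 1.0)
        with pytest.raises(SpectralCoverageError):
            creep_from_spectrum(S, [1.0])


class TestDiscretizeSpectrum:
    def test_atom_case_reproduces_zener_exactly(self):
        p = FractionalParams(1.0, 2.0, 1.0, 1.0)
        net = discretize_spectrum(p, 8, (1e-2, 1e2))
        w = np.geomspace(1e-3, 1e3, 121)
        np.testing.assert_allclose(
            network_modulus(net, w),
            zener_modulus(ZenerParams(1.0, 2.0, 1.0), w),
            rtol=1e-12,
        )

    def test_midband_accuracy_at_spec_density(self):
        """8 units/decade keep the mid-band modulus within 1%."""
        p = FractionalParams(1.0, 1.0, 0.0, 0.5)
        net = discretize_spectrum(p, 8, (1e-2, 1e2))
        w = np.geomspace(1e-1, 1e1, 61)
        Ef = frac_modulus(p, w)
        err = np.max(np.abs(network_modulus(net, w) - Ef) / np.abs(Ef))
        assert err < 0.01

    @pytest.mark.parametrize("alpha", [0.2, 0.5, 0.8])
    def test_error_decreases_with_density(self, alpha):
        p = FractionalParams(1.0, 1.0, 0.0, alpha)
        w = np.geomspace(1e-1, 1e1, 61)
        Ef = frac_modulus(p, w)
        errs = []
        for npd in (4, 16):
            net = discretize_spectrum(p, npd, (1e-2, 1e2))
            errs.append(np.max(np.abs(network_modulus(net, w) - Ef) / np.abs(Ef)))
        assert errs[1] <= errs[0]

    def test_chain_is_passive(self):
        net = discretize_spectrum(FractionalParams(1.0, 1.0, 0.0, 0.4), 6, (0.1, 10.0))
        assert all(u.stiffness >= 0.0 and u.viscosity >= 0.0 for u in net.units)

    def test_static_compliance_is_exact(self):
        p = FractionalParams(4.0, 1.0, 1e-2, 0.6)
        net = discretize_spectrum(p, 8, (1e-2, 1e2))
        E0 = network_modulus(net, 0.0)[0]
        assert E0.real == pytest.approx(p.modulus, rel=1e-9)


class TestHysteresis:
    def test_modulus_is_frequency_independent(self):
        h = HysteresisModulus(2.0, 0.3)
        E = hysteresis_modulus(h, [0.1, 1e5])
        assert E[0] == E[1] == 2.0 + 0.3j

    def test_small_order_loss_is_nearly_flat(self):
        # loss ~ w^0.01 varies by 100^0.01 ~ 1.047 over two decades
        ratio = hysteresis_limit_check(1.0, 1.0, 0.01, (1.0, 100.0))
        assert 1.0 < ratio < 1.10

    def test_moderate_order_is_reported_honestly(self):
        p = FractionalParams(1.0, 1.0, 0.0, 0.3)
        w = np.geomspace(1.0, 100.0, 201)
        E = frac_modulus(p, w)
        ratio = E.imag.max() / E.imag.min()
        assert ratio == pytest.approx(100.0**0.3, rel=1e-3)

    def test_flatness_improves_as_order_vanishes(self):
        r1 = hysteresis_limit_check(1.0, 1.0, 0.02, (1.0, 100.0))
        r2 = hysteresis_limit_check(1.0, 1.0, 0.005, (1.0, 100.0))
        assert r2 < r1
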