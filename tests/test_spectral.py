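"""Concentration, population, increments, kinetics and Kramers-Kronig."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holocri.errors import InvalidArgumentError
from holocri.spectral import (ExtinctionSpectrum, PumpSpectrum, anchor_trend,
                              concentration_from_iri, fit_concentration,
                              increments_from_spectra, iri_from_concentration,
                              kk_rri_trend, kk_trend_on_wavelengths,
                              population_from_states, relaxation_time,
                              water_rri)

from oracles import lorentz_kk_pair

AVOGADRO = 6.02214076e23
PLANCK = 6.62607015e-34
C = 299792458.0


class TestConcentration:
    def test_zero_iri_gives_zero_density(self):
        assert concentration_from_iri(0.0, 461.0, 1e4) == 0.0

    def test_hand_arithmetic_inverse(self):
        rho = concentration_from_iri(2.906e-4, 461.0, 10000.0)
        assert rho == pytest.approx(3.44e-3, rel=1e-3)

    @given(rho=st.floats(1e-6, 1e-1), lam=st.floats(420.0, 650.0),
           eps=st.floats(10.0, 1e5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_round_trip_is_identity(self, rho, lam, eps):
        iri = iri_from_concentration(rho, lam, eps)
        back = concentration_from_iri(iri, lam, eps)
        assert back == pytest.approx(rho, rel=1e-12)

    def test_zero_extinction_unidentifiable(self):
        with pytest.raises(InvalidArgumentError):
            concentration_from_iri(1e-4, 461.0, 0.0)

    def test_spectrum_fit_recovers_exactly(self):
        lam = np.linspace(430.0, 600.0, 40)
        eps = ExtinctionSpectrum(lam, 4e4 * np.exp(-((lam - 446) / 25.0) ** 2))
        kappas = np.array([iri_from_concentration(3.44e-3, w, e)
                           for w, e in zip(lam, eps.epsilon)])
        rho, sd = fit_concentration(lam, kappas, eps)
        assert rho == pytest.approx(3.44e-3, rel=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-10)


class TestPopulation:
    def test_difference_and_ratio(self):
        pop = population_from_states(3.44e-3, 0.56e-3, 1e-4, 1e-4)
        assert pop.rho_pB == pytest.approx(2.88e-3, rel=1e-12)
        assert pop.R_pB == pytest.approx(0.837, abs=5e-4)
        assert pop.sd_rho_pB == pytest.approx(np.hypot(1e-4, 1e-4))
        assert pop.sd_R_pB > 0

    def test_equal_densities_no_pb(self):
        pop = population_from_states(2e-3, 2e-3)
        assert pop.rho_pB == 0.0 and pop.R_pB == 0.0

    def test_full_conversion(self):
        assert population_from_states(2e-3, 0.0).R_pB == 1.0

    def test_inverted_densities_rejected(self):
        with pytest.raises(InvalidArgumentError):
            population_from_states(1e-3, 2e-3)


class TestIncrements:
    LAM = np.linspace(461.0, 582.0, 11)
    POP = population_from_states(3.44e-3, 0.56e-3)

    def test_water_only_gives_zero_increment(self):
        h2o = water_rri(self.LAM)
        on = h2o + self.POP.rho_pB * 1.7 + 0.56e-3 * 0.0
        inc = increments_from_spectra(self.LAM, h2o, on, self.POP)
        np.testing.assert_allclose(inc.alpha_pG, 0.0, atol=1e-12)

    def test_construct_then_solve_exact(self):
        a_pg, a_pb = 2.0, 1.7
        h2o = water_rri(self.LAM)
        off = h2o + 3.44e-3 * a_pg
        on = h2o + 0.56e-3 * a_pg + 2.88e-3 * a_pb
        inc = increments_from_spectra(self.LAM, off, on, self.POP)
        np.testing.assert_allclose(inc.alpha_pG, a_pg, atol=1e-12)
        np.testing.assert_allclose(inc.alpha_pB, a_pb, atol=1e-12)

    def test_matrix_solve_matches_closed_form(self, rng):
        h2o = water_rri(self.LAM)
        off = h2o + rng.uniform(0.005, 0.02, self.LAM.size)
        on = h2o + rng.uniform(0.005, 0.02, self.LAM.size)
        inc = increments_from_spectra(self.LAM, off, on, self.POP)
        a_pg = (off - h2o) / self.POP.rho_pG_off
        a_pb = (on - h2o - self.POP.rho_pG_on * a_pg) / self.POP.rho_pB
        np.testing.assert_allclose(inc.alpha_pG, a_pg, rtol=1e-14)
        np.testing.assert_allclose(inc.alpha_pB, a_pb, rtol=1e-14)

    def test_degenerate_population_rejected(self):
        pop = population_from_states(2e-3, 2e-3)
        with pytest.raises(InvalidArgumentError):
            increments_from_spectra(self.LAM, water_rri(self.LAM),
                                    water_rri(self.LAM), pop)


class TestRelaxationTime:
    EPS = ExtinctionSpectrum(np.array([430.0, 455.0, 480.0]),
                             np.array([30000.0, 30000.0, 30000.0]))

    @staticmethod
    def narrow_pump(total=100.0, centre=455.0, width=2.0):
        lam = np.linspace(centre - width / 2, centre + width / 2, 41)
        dens = np.full_like(lam, total / width)
        return PumpSpectrum(lam, dens)

    def test_monochromatic_closed_form(self):
        """Narrow-band pump against the hand-computed photostationary rate."""
        kin = relaxation_time(0.837, 0.35, self.EPS, self.narrow_pump())
        rate_hand = (np.log(10.0) * ((1 - 0.837) / 0.837) * 0.35
                     * (30000.0 * 0.1) * 455e-9 * 100.0 / (AVOGADRO * PLANCK * C))
        assert kin.tau_s == pytest.approx(1.0 / rate_hand, rel=1e-10)

    def test_tau_monotone_in_population_ratio(self):
        taus = [relaxation_time(r, 0.35, self.EPS, self.narrow_pump()).tau_s
                for r in np.linspace(0.05, 0.95, 19)]
        assert np.all(np.diff(taus) > 0)

    def test_doubling_intensity_halves_tau(self):
        t1 = relaxation_time(0.5, 0.35, self.EPS, self.narrow_pump(100.0)).tau_s
        t2 = relaxation_time(0.5, 0.35, self.EPS, self.narrow_pump(200.0)).tau_s
        assert t2 == pytest.approx(t1 / 2.0, rel=1e-12)

    def test_boundary_ratios_rejected(self):
        with pytest.raises(InvalidArgumentError):
            relaxation_time(1.0, 0.35, self.EPS, self.narrow_pump())
        with pytest.raises(InvalidArgumentError):
            relaxation_time(0.0, 0.35, self.EPS, self.narrow_pump())

    def test_uncertainty_propagation_scale(self):
        kin = relaxation_time(0.837, 0.35, self.EPS, self.narrow_pump(),
                              r_pb_sd=0.035)
        expected = kin.tau_s * 0.035 / (0.837 * (1 - 0.837))
        assert kin.tau_uncertainty_s == pytest.approx(expected, rel=1e-12)


class TestKramersKronig:
    W0, GAMMA, AMP = 4.2e15, 3e14, 4e29

    def test_zero_kappa_gives_constant(self):
        w = np.linspace(1e15, 5e15, 200)
        trend = kk_rri_trend(w, np.zeros_like(w))
        np.testing.assert_allclose(trend, 1.0, atol=1e-15)

    def test_lorentz_oscillator_conjugate(self):
        """Transform of a Lorentz kappa matches its analytic real part."""
        w = np.linspace(0.3 * self.W0, 3 * self.W0, 3000)
        n1, kappa = lorentz_kk_pair(w, self.W0, self.GAMMA, self.AMP)
        trend = kk_rri_trend(w, kappa)
        half = slice(w.size // 4, 3 * w.size // 4)
        anchored = anchor_trend(trend, 1.0 + n1[w.size // 4], index=w.size // 4)
        rms = np.sqrt(np.mean((anchored[half] - (1 + n1[half])) ** 2))
        assert rms / (n1.max() - n1.min()) < 0.02

    def test_operator_linearity(self):
        w = np.linspace(1e15, 6e15, 500)
        _, k1 = lorentz_kk_pair(w, 3e15, 2e14, 2e29)
        _, k2 = lorentz_kk_pair(w, 4.5e15, 4e14, 3e29)
        t12 = kk_rri_trend(w, k1 + k2)
        t1 = kk_rri_trend(w, k1)
        t2 = kk_rri_trend(w, k2)
        np.testing.assert_allclose(t12 - 1.0, (t1 - 1.0) + (t2 - 1.0),
                                   atol=1e-12)

    def test_small_grid_rejected(self):
        with pytest.raises(InvalidArgumentError):
            kk_rri_trend(np.linspace(1e15, 2e15, 20), np.zeros(20))

    def test_nonuniform_grid_resampled_with_warning(self):
        w = np.sort(np.concatenate([np.linspace(1e15, 5e15, 100),
                                    [2.345e15]]))
        with pytest.warns(UserWarning, match="resampl"):
            kk_rri_trend(w, np.zeros_like(w))

    def test_wavelength_wrapper_shape(self):
        lam = np.linspace(430.0, 600.0, 200)
        _, kap = lorentz_kk_pair(2 * np.pi * C / (lam * 1e-9),
                                 2 * np.pi * C / 446e-9, 3e14, 4e29)
        trend = kk_trend_on_wavelengths(lam, kap)
        assert trend.shape == lam.shape and np.all(np.isfinite(trend))


class TestWaterDispersion:
    def test_sodium_line_value(self):
        assert water_rri(589.0) == pytest.approx(1.333, abs=5e-4)

    def test_normal_dispersion_in_band(self):
        lam = np.linspace(461.0, 582.0, 50)
        assert np.all(np.diff(water_rri(lam)) < 0)

    def test_pure_function(self):
        assert water_rri(500.0) == water_rri(500.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            water_rri(380.0)
        with pytest.raises(InvalidArgumentError):
            water_rri(750.0)
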