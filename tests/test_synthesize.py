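"""Synthetic scenario model, field synthesis, and hologram formation."""

import numpy as np
import pytest
import scipy.fft

from holocri.errors import InvalidArgumentError, SamplingError, SidebandOverlapError
from holocri.materials import pmma_index, water_rri
from holocri.mie import theory_curve
from holocri.ftls import scattering_curve
from holocri.spectral import iri_from_concentration
from holocri.synthesize import (GaussianBand, LorentzBand, ProteinScenario,
                                generate_scenario_dataset, make_hologram,
                                medium_cri_from_scenario, synthesize_field,
                                uniform_field)
from holocri.types import ComplexFieldImage, ComplexIndex, ImageGrid, SphereSpec


def tiny_scenario(**kw):
    defaults = dict(
        wavelengths_nm=(461.0, 582.0),
        sphere=SphereSpec(6.0, pmma_index),
        grid=ImageGrid(256, 0.2, 0.25),
        noise_sd=0.005,
        seed=7,
    )
    defaults.update(kw)
    return ProteinScenario(**defaults)


class TestScenarioModel:
    def test_zero_concentration_gives_pure_water(self):
        sc = tiny_scenario(rho_pG_off=0.0, rho_pG_on=0.0)
        ci = medium_cri_from_scenario(sc, "pump-off", 500.0)
        assert ci.kappa == 0.0
        assert ci.n == pytest.approx(water_rri(500.0), abs=1e-12)

    def test_beer_lambert_hand_value(self):
        """ln10/(4 pi) * rho * lambda * eps at 461 nm, by hand."""
        kappa = iri_from_concentration(3.44e-3, 461.0, 10000.0)
        hand = np.log(10.0) * (3.44e-3 * 1e4) * (461e-7) / (4 * np.pi)
        assert kappa == pytest.approx(hand, rel=1e-12)
        assert kappa == pytest.approx(2.906e-4, rel=1e-3)

    def test_pump_state_kappa_scales_with_ground_state_density(self):
        sc = tiny_scenario()
        for wl in sc.wavelengths_nm:
            k_off = medium_cri_from_scenario(sc, "pump-off", wl).kappa
            k_on = medium_cri_from_scenario(sc, "pump-on", wl).kappa
            assert k_on == pytest.approx(
                k_off * sc.rho_pG_on / sc.rho_pG_off, rel=1e-12)

    def test_gaussian_band_tail_is_transparent(self):
        """Band centred at 446 nm, FWHM 30: kappa < 1e-5 past 520 nm."""
        sc = tiny_scenario(band=GaussianBand(446.0, 45000.0, 30.0))
        for wl in (520.0, 560.0, 600.0):
            assert medium_cri_from_scenario(sc, "pump-off", wl).kappa < 1e-5

    def test_lorentz_band_is_kk_self_consistent_shape(self):
        """The dispersive increment peaks at the band flanks (w0 +- g/2)."""
        band = LorentzBand(446.0, 45000.0, 30.0)
        lam = np.linspace(400.0, 600.0, 400)
        inc = np.asarray(band.increment_molar(lam), float)
        # anomalous dispersion: positive below resonance flank, negative above
        assert inc[lam > 470].max() > 0
        assert inc[lam < 440].min() < 0
        peak_lam = lam[np.argmax(inc)]
        assert 446.0 < peak_lam < 480.0

    def test_band_epsilon_peak_value(self):
        for band in (LorentzBand(), GaussianBand()):
            assert float(band.epsilon(band.peak_nm)) == pytest.approx(
                band.eps_max, rel=1e-6)

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(InvalidArgumentError):
            tiny_scenario(rho_pG_on=4e-3)  # exceeds pump-off
        with pytest.raises(InvalidArgumentError):
            tiny_scenario(noise_sd=-0.1)
        sc = tiny_scenario()
        with pytest.raises(InvalidArgumentError):
            medium_cri_from_scenario(sc, "pump-off", 390.0)


class TestFieldSynthesis:
    def test_vanishing_sphere_gives_attenuated_plane_wave(self, small_grid):
        med = ComplexIndex(1.34, 2e-4)
        fld = synthesize_field(SphereSpec(0.01, pmma_index), med, 500.0,
                               small_grid, path_length_um=30.0)
        a_inc = np.exp(-2 * np.pi * 2e-4 * 30.0 / 0.5)
        assert np.abs(np.abs(fld.field) - a_inc).max() < 1e-6 * a_inc
        assert np.abs(np.angle(fld.field)).max() < 1e-6

    def test_background_amplitude_matches_attenuation(self, mid_chain):
        corner = mid_chain["field"].field[:32, :32]
        a_inc = np.exp(-2 * np.pi * 1e-4 * 20.0 / 0.5)
        assert abs(np.abs(corner).mean() / a_inc - 1.0) < 0.1

    def test_discrete_parseval_energy_budget(self, mid_chain):
        fld = mid_chain["field"].field
        spec = scipy.fft.fft2(fld)
        n = fld.shape[0]
        energy_image = np.sum(np.abs(fld) ** 2)
        energy_spec = np.sum(np.abs(spec) ** 2) / n**2
        assert energy_image == pytest.approx(energy_spec, rel=1e-10)

    def test_ftls_round_trip_recovers_theory_curve(self, mid_chain, mid_sphere,
                                                   medium):
        curve = scattering_curve(mid_chain["field"], medium.n, n_bins=100)
        tc = theory_curve(mid_sphere, medium, 500.0, curve.axis)
        meas = curve.intensity / curve.intensity.max()
        rms = np.sqrt(np.mean((meas - tc.intensity) ** 2))
        assert rms < 0.01

    def test_undersampled_na_cone_rejected(self):
        grid = ImageGrid(256, 0.3, 0.45)  # pitch > lambda/(4 NA) at 500 nm
        with pytest.raises(SamplingError):
            synthesize_field(SphereSpec(6.0, pmma_index), ComplexIndex(1.34),
                             500.0, grid)

    def test_sphere_margin_enforced(self, small_grid):
        with pytest.raises(InvalidArgumentError):
            synthesize_field(SphereSpec(100.0, pmma_index), ComplexIndex(1.34),
                             500.0, small_grid)


class TestHolograms:
    def test_uniform_field_closed_form(self, small_grid):
        fld = ComplexFieldImage(np.ones((512, 512), complex), small_grid, 500.0)
        holo = make_hologram(fld, reference_amplitude=1.0)
        assert holo.intensity.mean() == pytest.approx(2.0, abs=1e-3)
        assert holo.intensity.min() >= 0.0
        assert holo.intensity.max() <= 4.0 + 1e-9
        # fringe modulation: 2 + 2 cos(2 pi c . r)
        r = np.arange(512) * small_grid.pixel_pitch_um
        expected = 2.0 + 2.0 * np.cos(
            2 * np.pi * (holo.carrier[0] * r[:, None] + holo.carrier[1] * r[None, :]))
        np.testing.assert_allclose(holo.intensity, expected, atol=1e-9)

    def test_zero_reference_gives_plain_intensity(self, mid_chain):
        fld = mid_chain["field"]
        holo = make_hologram(fld, reference_amplitude=0.0)
        np.testing.assert_allclose(holo.intensity, np.abs(fld.field) ** 2,
                                   atol=1e-12)

    def test_small_carrier_rejected(self, mid_chain):
        with pytest.raises(SidebandOverlapError):
            make_hologram(mid_chain["field"], carrier=(0.4, 0.0))

    def test_aliasing_carrier_rejected(self, mid_chain):
        nyq = mid_chain["field"].grid.nyquist
        with pytest.raises(SidebandOverlapError):
            make_hologram(mid_chain["field"], carrier=(nyq - 0.05, nyq - 0.05))


class TestScenarioDataset:
    def test_dataset_shape_and_truth(self):
        sc = tiny_scenario()
        recs = list(generate_scenario_dataset(sc))
        assert len(recs) == 4  # 2 states x 2 wavelengths
        states = {r.state for r in recs}
        assert states == {"pump-off", "pump-on"}
        for r in recs:
            truth = medium_cri_from_scenario(sc, r.state, r.wavelength_nm)
            assert r.truth.n == truth.n and r.truth.kappa == truth.kappa
            assert r.sample.intensity.shape == (256, 256)

    def test_same_seed_bit_identical(self):
        a = list(generate_scenario_dataset(tiny_scenario()))
        b = list(generate_scenario_dataset(tiny_scenario()))
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.sample.intensity, rb.sample.intensity)
            assert np.array_equal(rb.background.intensity, rb.background.intensity)

    def test_different_seed_differs(self):
        a = next(iter(generate_scenario_dataset(tiny_scenario(seed=7))))
        b = next(iter(generate_scenario_dataset(tiny_scenario(seed=8))))
        assert not np.array_equal(a.sample.intensity, b.sample.intensity)

    def test_noise_free_dataset_is_deterministic_and_noiseless(self):
        sc0 = tiny_scenario(noise_sd=0.0)
        rec = next(iter(generate_scenario_dataset(sc0)))
        fld = synthesize_field(sc0.sphere,
                               medium_cri_from_scenario(sc0, "pump-off", 461.0),
                               461.0, sc0.grid)
        direct = make_hologram(fld, sc0.carrier(), sc0.reference_amplitude)
        np.testing.assert_array_equal(rec.sample.intensity, direct.intensity)
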