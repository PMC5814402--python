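"""Physically consistent synthetic data: scattering curves, complex field
images and off-axis holograms of a microsphere in an absorbing protein
solution.

The multi-wavelength pump-on/pump-off scenario emulates a photoswitchable
chromoprotein (photoactive yellow protein): the ground state pG absorbs in
the blue (default band centred at 446 nm) and the pump beam converts most
of the population to the transparent signalling state pB.  The solution's
complex index is assembled from

* a water real-index baseline (Quan & Fry dispersion);
* an imaginary part from the Beer-Lambert relation
  ``kappa = ln(10)/(4 pi) * rho_pG * lambda * eps(lambda)``;
* a real part from molar refractive-index increments.  With the default
  Lorentz-oscillator band the pG increment carries the dispersion that is
  the exact Kramers-Kronig conjugate of its absorption, so synthetic
  pump-on/off spectra are causally self-consistent.

Field synthesis inverts the FTLS step: the angular spectrum inside the NA
cone is populated from the Mie amplitudes (co-polarised far field
``S2 cos^2(phi) + S1 sin^2(phi)`` with the stationary-phase obliquity
1/cos(theta)), plus the unscattered plane wave attenuated by
``exp(-2 pi kappa t / lambda)`` over a configurable path length, and
inverse-transformed to the image plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
import scipy.fft
from scipy.interpolate import CubicSpline

from . import mie
from .errors import HolocriError, InvalidArgumentError, SamplingError, SidebandOverlapError
from .materials import pmma_index, water_rri
from .types import ComplexFieldImage, ComplexIndex, Hologram, ImageGrid, SphereSpec

__all__ = [
    "LorentzBand",
    "GaussianBand",
    "ProteinScenario",
    "ScenarioRecord",
    "medium_cri_from_scenario",
    "synthesize_field",
    "uniform_field",
    "make_hologram",
    "default_carrier",
    "add_field_noise",
    "generate_scenario_dataset",
]

_C_M_PER_S = 299792458.0
LN10 = np.log(10.0)


def _omega(wavelength_nm) -> np.ndarray:
    return 2.0 * np.pi * _C_M_PER_S / (np.asarray(wavelength_nm, float) * 1e-9)


@dataclass(frozen=True)
class LorentzBand:
    """Single Lorentz-oscillator absorption band of the pG chromophore.

    Parameterised by the printed observables (peak wavelength, peak molar
    extinction, FWHM in wavelength); internally a molar resonant
    refractivity r(w) = A / (w0^2 - w^2 - i gamma w) whose imaginary part
    reproduces eps(lambda) and whose real part is the matching dispersive
    contribution to the refractive-index increment.
    """

    peak_nm: float = 446.0
    eps_max: float = 45000.0   # M^-1 cm^-1
    fwhm_nm: float = 30.0

    @property
    def omega0(self) -> float:
        return float(_omega(self.peak_nm))

    @property
    def gamma(self) -> float:
        lam0_m = self.peak_nm * 1e-9
        return 2.0 * np.pi * _C_M_PER_S * (self.fwhm_nm * 1e-9) / lam0_m**2

    @property
    def amplitude(self) -> float:
        # kappa_molar at resonance = A/(gamma w0) must equal the
        # Beer-Lambert value ln10/(4 pi) lambda0 eps_max
        kappa_peak = LN10 / (4.0 * np.pi) * (self.peak_nm * 1e-7) * self.eps_max
        return kappa_peak * self.gamma * self.omega0

    def _r(self, wavelength_nm) -> np.ndarray:
        w = _omega(wavelength_nm)
        return self.amplitude / (self.omega0**2 - w**2 - 1j * self.gamma * w)

    def kappa_molar(self, wavelength_nm):
        """Imaginary-index contribution per molar concentration."""
        return np.imag(self._r(wavelength_nm))

    def epsilon(self, wavelength_nm):
        """Molar extinction coefficient (M^-1 cm^-1)."""
        lam_cm = np.asarray(wavelength_nm, float) * 1e-7
        return 4.0 * np.pi * self.kappa_molar(wavelength_nm) / (LN10 * lam_cm)

    def increment_molar(self, wavelength_nm):
        """Resonant (dispersive) part of the refractive-index increment."""
        return np.real(self._r(wavelength_nm))


@dataclass(frozen=True)
class GaussianBand:
    """Gaussian-in-wavelength extinction band.

    Purely absorptive: no matching dispersive increment is generated, so
    scenarios built on it are not Kramers-Kronig self-consistent (use
    :class:`LorentzBand` when that matters).
    """

    peak_nm: float = 446.0
    eps_max: float = 45000.0
    fwhm_nm: float = 30.0

    def epsilon(self, wavelength_nm):
        lam = np.asarray(wavelength_nm, float)
        sigma = self.fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return self.eps_max * np.exp(-0.5 * ((lam - self.peak_nm) / sigma) ** 2)

    def kappa_molar(self, wavelength_nm):
        lam_cm = np.asarray(wavelength_nm, float) * 1e-7
        return LN10 / (4.0 * np.pi) * lam_cm * self.epsilon(wavelength_nm)

    def increment_molar(self, wavelength_nm):
        return np.zeros_like(np.asarray(wavelength_nm, float))


def _default_sphere() -> SphereSpec:
    return SphereSpec(100.0, pmma_index)


def _default_grid() -> ImageGrid:
    return ImageGrid(4096, 0.2, 0.25)


@dataclass(frozen=True)
class ProteinScenario:
    """Full pump-on/pump-off multi-wavelength measurement design.

    Concentrations are molar; ``rho_pG_on <= rho_pG_off`` because the pump
    only depletes the ground state.  ``alpha_bg_*`` are the non-resonant
    refractive-index increments (M^-1); the pG state additionally carries
    the band's dispersive increment.
    """

    wavelengths_nm: tuple = tuple(np.linspace(461.0, 582.0, 11))
    band: LorentzBand | GaussianBand = field(default_factory=LorentzBand)
    rho_pG_off: float = 3.44e-3
    rho_pG_on: float = 0.56e-3
    alpha_bg_pG: float = 3.4
    alpha_bg_pB: float = 3.4
    water_temperature_c: float = 20.0
    sphere: SphereSpec = field(default_factory=_default_sphere)
    grid: ImageGrid = field(default_factory=_default_grid)
    carrier_frac: tuple[float, float] = (0.25, 0.25)
    reference_amplitude: float = 1.0
    noise_sd: float = 0.005
    path_length_um: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rho_pG_off < 0 or self.rho_pG_on < 0:
            raise InvalidArgumentError("concentrations must be non-negative")
        if self.rho_pG_on > self.rho_pG_off:
            raise InvalidArgumentError(
                "pump-on pG concentration cannot exceed pump-off"
            )
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise sd must be non-negative")

    @property
    def rho_pB_on(self) -> float:
        return self.rho_pG_off - self.rho_pG_on

    @property
    def path_um(self) -> float:
        return self.path_length_um if self.path_length_um is not None \
            else self.sphere.diameter_um

    def alpha_pG(self, wavelength_nm):
        return self.alpha_bg_pG + self.band.increment_molar(wavelength_nm)

    def alpha_pB(self, wavelength_nm):
        lam = np.asarray(wavelength_nm, float)
        return np.broadcast_to(self.alpha_bg_pB, lam.shape).copy() if lam.ndim \
            else self.alpha_bg_pB

    def carrier(self) -> tuple[float, float]:
        fs = self.grid.sampling_frequency
        return (self.carrier_frac[0] * fs, self.carrier_frac[1] * fs)


def medium_cri_from_scenario(scenario: ProteinScenario,
                             state: Literal["pump-off", "pump-on"],
                             wavelength_nm: float) -> ComplexIndex:
    """Ground-truth solution CRI for one state and wavelength."""
    if not 400.0 <= wavelength_nm <= 700.0:
        raise InvalidArgumentError("wavelength outside water-baseline validity")
    key = state.replace("pump-", "")
    if key == "off":
        rho_pg, rho_pb = scenario.rho_pG_off, 0.0
    elif key == "on":
        rho_pg, rho_pb = scenario.rho_pG_on, scenario.rho_pB_on
    else:
        raise InvalidArgumentError(f"unknown state {state!r}")
    kappa = rho_pg * float(scenario.band.kappa_molar(wavelength_nm))
    if kappa < 0:
        raise HolocriError("internal inconsistency: negative kappa from band model")
    n = (
        water_rri(wavelength_nm, scenario.water_temperature_c)
        + rho_pg * float(scenario.alpha_pG(wavelength_nm))
        + rho_pb * float(scenario.alpha_pB(wavelength_nm))
    )
    return ComplexIndex(n, kappa)


def _incident_amplitude(medium: ComplexIndex, wavelength_nm: float,
                        path_um: float, incident: float = 1.0) -> float:
    lam_um = wavelength_nm * 1e-3
    return incident * float(np.exp(-2.0 * np.pi * medium.kappa * path_um / lam_um))


def uniform_field(medium: ComplexIndex, wavelength_nm: float, grid: ImageGrid,
                  path_length_um: float, incident_amplitude: float = 1.0
                  ) -> ComplexFieldImage:
    """Sphere-free background: attenuated incident plane wave, flat phase."""
    a = _incident_amplitude(medium, wavelength_nm, path_length_um, incident_amplitude)
    arr = np.full((grid.n_pixels, grid.n_pixels), a, dtype=complex)
    return ComplexFieldImage(arr, grid, wavelength_nm)


def synthesize_field(sphere: SphereSpec, medium: ComplexIndex,
                     wavelength_nm: float, grid: ImageGrid,
                     path_length_um: float | None = None,
                     incident_amplitude: float = 1.0,
                     pupil_edge_frac: float = 0.0) -> ComplexFieldImage:
    """Image-plane complex field of a sphere centred in the grid.

    Built in the frequency domain: DC delta for the attenuated incident
    wave plus the Mie angular spectrum inside the NA cone, then an inverse
    DFT.  The Mie amplitudes are evaluated on a dense angle grid and
    cubic-spline interpolated onto the pixel radii.

    ``pupil_edge_frac`` optionally models a soft imaging pupil: a
    raised-cosine roll-off over the outer fraction of the NA disk (default
    hard pupil, which matches the sharp NA bound assumed by the theory
    curve; when a soft pupil is used, fits should ignore the rolled-off
    outer band).
    """
    lam_um = wavelength_nm * 1e-3
    na = grid.numerical_aperture
    if grid.pixel_pitch_um > lam_um / (4.0 * na):
        raise SamplingError(
            f"NA cone under-sampled: pixel pitch {grid.pixel_pitch_um} um "
            f"exceeds lambda/(4 NA) = {lam_um / (4 * na):.4f} um"
        )
    if sphere.diameter_um * 1.2 > grid.field_of_view_um:
        raise InvalidArgumentError(
            "sphere must fit within the grid with at least 20% margin"
        )
    path = path_length_um if path_length_um is not None else sphere.diameter_um
    a_inc = _incident_amplitude(medium, wavelength_nm, path, incident_amplitude)

    n_px = grid.n_pixels
    f1d = np.fft.fftfreq(n_px, d=grid.pixel_pitch_um)
    fx, fy = np.meshgrid(f1d, f1d, indexing="ij")
    fr = np.hypot(fx, fy)
    mask = lam_um * fr <= na
    sin_theta = np.zeros_like(fr)
    sin_theta[mask] = lam_um * fr[mask] / medium.n
    sin_max = na / medium.n

    x = mie.size_parameter(sphere.diameter_um, medium, wavelength_nm)
    m_rel = sphere.index_at(wavelength_nm).m / medium.m
    sol = mie.mie_coefficients(m_rel, x)
    n_periods = sin_max * abs(x) / np.pi
    n_dense = int(max(2048, 100 * n_periods))
    sin_dense = np.linspace(0.0, sin_max * (1 + 1e-12), n_dense)
    s1d, s2d = mie.scattering_amplitudes(sol, np.arcsin(sin_dense))
    s1 = CubicSpline(sin_dense, s1d)(sin_theta[mask])
    s2 = CubicSpline(sin_dense, s2d)(sin_theta[mask])

    phi = np.arctan2(fy[mask], fx[mask])
    cphi2 = np.cos(phi) ** 2
    a_pol = s2 * cphi2 + s1 * (1.0 - cphi2)
    cos_theta = np.sqrt(1.0 - sin_theta[mask] ** 2)

    lam_medium = lam_um / medium.n
    spec = np.zeros((n_px, n_px), dtype=complex)
    # continuous-spectrum weight -a lam_med^2 S /(2 pi cos) sampled on the
    # DFT grid carries a 1/pitch^2 density factor
    spec[mask] = (
        -a_inc * lam_medium**2 / (2.0 * np.pi * grid.pixel_pitch_um**2)
        * a_pol / cos_theta
    )
    if pupil_edge_frac > 0:
        ns_mask = lam_um * fr[mask]
        edge_start = na * (1.0 - pupil_edge_frac)
        t = np.clip((ns_mask - edge_start) / (na - edge_start), 0.0, 1.0)
        spec[mask] *= 0.5 + 0.5 * np.cos(np.pi * t)
    spec[0, 0] += a_inc * n_px**2
    # centre the sphere in the field of view
    arr = np.roll(scipy.fft.ifft2(spec), (n_px // 2, n_px // 2), axis=(0, 1))
    return ComplexFieldImage(arr, grid, wavelength_nm)


def default_carrier(grid: ImageGrid, frac: tuple[float, float] = (0.25, 0.25)
                    ) -> tuple[float, float]:
    fs = grid.sampling_frequency
    return (frac[0] * fs, frac[1] * fs)


def make_hologram(field: ComplexFieldImage, carrier: tuple[float, float] | None = None,
                  reference_amplitude: float = 1.0) -> Hologram:
    """Off-axis interferogram |U + R exp(i 2 pi carrier . r)|^2."""
    grid = field.grid
    if carrier is None:
        carrier = default_carrier(grid)
    cx, cy = carrier
    lam_um = field.wavelength_nm * 1e-3
    band = grid.numerical_aperture / lam_um
    if np.hypot(cx, cy) <= 2.0 * band:
        raise SidebandOverlapError(
            f"carrier magnitude {np.hypot(cx, cy):.3f} cyc/um must exceed "
            f"twice the object band radius {band:.3f} cyc/um"
        )
    nyq = grid.nyquist
    if abs(cx) + band > nyq or abs(cy) + band > nyq:
        raise SidebandOverlapError(
            "sideband would alias: carrier + band radius exceeds Nyquist"
        )
    r = np.arange(grid.n_pixels) * grid.pixel_pitch_um
    ramp = np.exp(2j * np.pi * cx * r)[:, None] * np.exp(2j * np.pi * cy * r)[None, :]
    intensity = np.abs(field.field + reference_amplitude * ramp) ** 2
    return Hologram(intensity, (float(cx), float(cy)), reference_amplitude,
                    grid, field.wavelength_nm)


def add_field_noise(field: ComplexFieldImage, sd: float,
                    rng: np.random.Generator,
                    reference_level: float | None = None) -> ComplexFieldImage:
    """Additive circular complex Gaussian noise.

    ``sd`` is the standard deviation of the complex perturbation modulus
    relative to ``reference_level`` (default: the background amplitude
    estimated from the image corner).
    """
    if sd == 0:
        return field
    if reference_level is None:
        corner = field.field[: max(4, field.grid.n_pixels // 32),
                             : max(4, field.grid.n_pixels // 32)]
        reference_level = float(np.mean(np.abs(corner)))
    shape = field.field.shape
    noise = (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) \
        * (sd * reference_level / np.sqrt(2.0))
    return ComplexFieldImage(field.field + noise, field.grid, field.wavelength_nm)


@dataclass(frozen=True)
class ScenarioRecord:
    """One (state, wavelength) cell of a scenario dataset."""

    state: str
    wavelength_nm: float
    sample: Hologram
    background: Hologram
    truth: ComplexIndex


def generate_scenario_dataset(scenario: ProteinScenario
                              ) -> Iterator[ScenarioRecord]:
    """Yield sample/background hologram pairs with ground truth.

    One pair per (state, wavelength); complex-field noise is added before
    hologram formation; all randomness derives from ``scenario.seed``.
    Yields lazily because a full-scale dataset does not fit in memory.
    """
    states = ("pump-off", "pump-on")
    cells = [(s, float(w)) for s in states for w in scenario.wavelengths_nm]
    children = np.random.SeedSequence(scenario.seed).spawn(len(cells))
    for (state, wl), child in zip(cells, children):
        rng = np.random.default_rng(child)
        truth = medium_cri_from_scenario(scenario, state, wl)
        sample = synthesize_field(scenario.sphere, truth, wl, scenario.grid,
                                  scenario.path_um)
        background = uniform_field(truth, wl, scenario.grid, scenario.path_um)
        a_inc = _incident_amplitude(truth, wl, scenario.path_um)
        sample = add_field_noise(sample, scenario.noise_sd, rng, a_inc)
        background = add_field_noise(background, scenario.noise_sd, rng, a_inc)
        carrier = scenario.carrier()
        yield ScenarioRecord(
            state=state,
            wavelength_nm=wl,
            sample=make_hologram(sample, carrier, scenario.reference_amplitude),
            background=make_hologram(background, carrier, scenario.reference_amplitude),
            truth=truth,
        )
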