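"""Downstream spectral analysis of measured CRI spectra.

Given per-wavelength (n, kappa) of the protein solution in the pump-off
and pump-on states, this module computes the quantities the measurement
exists for:

* ground-state concentration from the imaginary index (Beer-Lambert:
  ``kappa = ln(10)/(4 pi) rho lambda eps(lambda)``);
* the signalling-state population ``rho_pB = rho_off - rho_on`` and its
  ratio ``R_pB = rho_pB / rho_off``;
* per-state refractive-index increments from the pump-on/off real-index
  spectra by an exact per-wavelength 2x2 linear solve against the water
  baseline;
* the photocycle relaxation time from the photostationary balance
  ``1/tau = ln(10) ((1-R)/R) (phi / N_A h c) \\int eps(l) l (dI/dl) dl``;
* a Kramers-Kronig real-index trend from an imaginary-index spectrum
  (Maclaurin alternating-point principal value).  A finite measurement
  band cannot fix the absolute level, so the trend is offset-ambiguous by
  construction and only anchored explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .errors import InvalidArgumentError
from .materials import water_rri

__all__ = [
    "ExtinctionSpectrum",
    "PumpSpectrum",
    "PopulationResult",
    "IncrementSpectrum",
    "KineticsResult",
    "concentration_from_iri",
    "iri_from_concentration",
    "fit_concentration",
    "population_from_states",
    "increments_from_spectra",
    "relaxation_time",
    "kk_rri_trend",
    "kk_trend_on_wavelengths",
    "anchor_trend",
    "water_rri",
]

LN10 = np.log(10.0)
PLANCK_J_S = 6.62607015e-34
AVOGADRO_PER_MOL = 6.02214076e23
LIGHT_SPEED_M_S = 299792458.0


@dataclass(frozen=True)
class ExtinctionSpectrum:
    """Molar extinction coefficient epsilon(lambda), M^-1 cm^-1."""

    wavelengths_nm: np.ndarray
    epsilon: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, float)
        e = np.asarray(self.epsilon, float)
        if w.shape != e.shape or w.ndim != 1:
            raise InvalidArgumentError("wavelengths and epsilon must be 1D, equal length")
        if np.any(np.diff(w) <= 0):
            raise InvalidArgumentError("wavelengths must be strictly increasing")
        if np.any(e < 0):
            raise InvalidArgumentError("extinction coefficients must be >= 0")

    def at(self, wavelengths_nm) -> np.ndarray:
        """Linear interpolation; extrapolation is forbidden."""
        lam = np.asarray(wavelengths_nm, float)
        w = np.asarray(self.wavelengths_nm, float)
        if np.any(lam < w[0]) or np.any(lam > w[-1]):
            raise InvalidArgumentError(
                "extinction spectrum does not cover the requested wavelengths"
            )
        return np.interp(lam, w, np.asarray(self.epsilon, float))


@dataclass(frozen=True)
class PumpSpectrum:
    """Spectral density of the pump beam, W m^-2 nm^-1."""

    wavelengths_nm: np.ndarray
    spectral_density: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, float)
        s = np.asarray(self.spectral_density, float)
        if w.shape != s.shape or w.ndim != 1 or np.any(np.diff(w) <= 0):
            raise InvalidArgumentError("malformed pump spectrum")
        if np.any(s < 0) or not np.all(np.isfinite(s)):
            raise InvalidArgumentError("spectral density must be finite and >= 0")

    @property
    def total_irradiance(self) -> float:
        """Integrated irradiance, W m^-2."""
        return float(np.trapezoid(self.spectral_density, self.wavelengths_nm))


@dataclass(frozen=True)
class PopulationResult:
    rho_pG_off: float
    rho_pG_on: float
    rho_pB: float
    R_pB: float
    sd_rho_pG_off: float = 0.0
    sd_rho_pG_on: float = 0.0
    sd_rho_pB: float = 0.0
    sd_R_pB: float = 0.0


@dataclass(frozen=True)
class IncrementSpectrum:
    wavelengths_nm: np.ndarray
    alpha_pG: np.ndarray
    alpha_pB: np.ndarray


@dataclass(frozen=True)
class KineticsResult:
    tau_s: float
    tau_uncertainty_s: float
    phi: float


def concentration_from_iri(iri: float, wavelength_nm: float,
                           epsilon: float) -> float:
    """Molar concentration from one imaginary-index value.

    Inverts kappa = ln(10)/(4 pi) rho lambda eps; lambda is converted to
    cm to pair with eps in M^-1 cm^-1.
    """
    if epsilon <= 0:
        raise InvalidArgumentError(
            "zero extinction coefficient: concentration unidentifiable"
        )
    if iri < 0:
        raise InvalidArgumentError("imaginary index must be >= 0")
    lam_cm = wavelength_nm * 1e-7
    return 4.0 * np.pi * iri / (LN10 * lam_cm * epsilon)


def iri_from_concentration(rho_m: float, wavelength_nm: float,
                           epsilon: float) -> float:
    """Forward Beer-Lambert: kappa from molar concentration."""
    lam_cm = wavelength_nm * 1e-7
    return LN10 / (4.0 * np.pi) * rho_m * lam_cm * epsilon


def fit_concentration(wavelengths_nm, kappas, epsilon: ExtinctionSpectrum,
                      kappa_sds=None) -> tuple[float, float]:
    """(rho, sd) by weighted linear least squares across a kappa spectrum.

    The model kappa(lambda) = ln10/(4 pi) rho lambda eps(lambda) is linear
    in rho, so the estimate is a closed-form projection; wavelengths with
    strong absorption dominate automatically.
    """
    lam = np.asarray(wavelengths_nm, float)
    k = np.asarray(kappas, float)
    g = LN10 / (4.0 * np.pi) * (lam * 1e-7) * epsilon.at(lam)
    if np.all(g == 0):
        raise InvalidArgumentError("extinction is zero across the band")
    w = np.ones_like(g) if kappa_sds is None \
        else 1.0 / np.maximum(np.asarray(kappa_sds, float), 1e-12) ** 2
    denom = float(np.sum(w * g * g))
    rho = float(np.sum(w * g * k)) / denom
    if kappa_sds is None:
        resid = k - rho * g
        dof = max(k.size - 1, 1)
        sd = float(np.sqrt(np.sum(resid**2) / dof / denom))
    else:
        sd = float(np.sqrt(1.0 / denom))
    return rho, sd


def population_from_states(rho_off: float, rho_on: float,
                           sd_off: float = 0.0, sd_on: float = 0.0
                           ) -> PopulationResult:
    """pB population and ratio from the two photostationary pG densities.

    ``R_pB = (rho_off - rho_on) / rho_off``: the fraction of the total
    protein pool (all pG with the pump off) residing in pB with the pump
    on.  Uncertainties by first-order propagation.
    """
    if rho_on > rho_off:
        raise InvalidArgumentError("pump-on pG density cannot exceed pump-off")
    if rho_off <= 0:
        raise InvalidArgumentError("pump-off density must be positive")
    rho_pb = rho_off - rho_on
    r = rho_pb / rho_off
    sd_pb = float(np.hypot(sd_off, sd_on))
    sd_r = float(np.hypot(sd_on / rho_off, rho_on * sd_off / rho_off**2))
    return PopulationResult(rho_off, rho_on, rho_pb, r,
                            sd_off, sd_on, sd_pb, sd_r)


def increments_from_spectra(wavelengths_nm, rri_off, rri_on,
                            pop: PopulationResult,
                            water: np.ndarray | None = None,
                            temperature_c: float = 20.0) -> IncrementSpectrum:
    """Per-state refractive-index increments alpha(lambda), M^-1.

    Solves, per wavelength, the linear system

        rri_off = rho_pG_off * alpha_pG                    + rri_water
        rri_on  = rho_pB_on  * alpha_pB + rho_pG_on * alpha_pG + rri_water

    exactly (2x2 solve; the matrix is triangular because the pump-off
    solution holds no pB).
    """
    lam = np.asarray(wavelengths_nm, float)
    off = np.asarray(rri_off, float)
    on = np.asarray(rri_on, float)
    if not (lam.shape == off.shape == on.shape):
        raise InvalidArgumentError("spectra must share the wavelength grid")
    if pop.rho_pG_off <= 0 or pop.rho_pB <= 0:
        raise InvalidArgumentError(
            "increments need nonzero pG (pump-off) and pB (pump-on) densities"
        )
    h2o = water_rri(lam, temperature_c) if water is None \
        else np.asarray(water, float)
    mat = np.array([[0.0, pop.rho_pG_off],
                    [pop.rho_pB, pop.rho_pG_on]])
    rhs = np.stack([off - h2o, on - h2o])           # (2, n_wavelengths)
    alpha_pb, alpha_pg = np.linalg.solve(mat, rhs)  # row order per mat
    return IncrementSpectrum(lam, alpha_pg, alpha_pb)


def relaxation_time(r_pb: float, phi: float, epsilon: ExtinctionSpectrum,
                    pump: PumpSpectrum, r_pb_sd: float = 0.0) -> KineticsResult:
    """Signalling-state relaxation time from the photostationary balance.

    All quantities go to SI before the trapezoidal integral: eps in
    M^-1 cm^-1 -> m^2 mol^-1 via x0.1, lambda in m, spectral density in
    W m^-3.  ``R_pB -> 1`` means the reverse rate vanishes (tau unbounded)
    and is rejected distinctly from numeric overflow.
    """
    if not 0.0 < r_pb < 1.0:
        if r_pb >= 1.0:
            raise InvalidArgumentError(
                "R_pB = 1 implies an unbounded relaxation time in the "
                "two-state photostationary model"
            )
        raise InvalidArgumentError("R_pB = 0: no pB population present")
    if not 0.0 < phi <= 1.0:
        raise InvalidArgumentError("quantum yield must be in (0, 1]")
    lam_nm = np.asarray(pump.wavelengths_nm, float)
    eps_si = epsilon.at(lam_nm) * 0.1               # m^2 / mol
    lam_m = lam_nm * 1e-9
    dens_si = np.asarray(pump.spectral_density, float) * 1e9  # W m^-2 m^-1
    integral = float(np.trapezoid(eps_si * lam_m * dens_si, lam_m))
    rate = LN10 * ((1.0 - r_pb) / r_pb) * phi \
        / (AVOGADRO_PER_MOL * PLANCK_J_S * LIGHT_SPEED_M_S) * integral
    if rate <= 0:
        raise InvalidArgumentError("pump spectrum deposits no absorbed power")
    tau = 1.0 / rate
    tau_sd = tau * r_pb_sd / (r_pb * (1.0 - r_pb))
    return KineticsResult(tau, float(tau_sd), float(phi))


def kk_rri_trend(omega: np.ndarray, kappa: np.ndarray) -> np.ndarray:
    """Real-index *trend* from kappa(omega) by the Kramers-Kronig relation.

    Maclaurin's alternating-point method for the principal value: each
    output point sums only over grid points of opposite parity, so the
    singular point is never touched.  kappa is taken as zero outside the
    grid, which a finite measurement band cannot justify — the output is
    therefore meaningful up to an unknown additive offset only (anchor it
    with :func:`anchor_trend`).
    """
    w = np.asarray(omega, float)
    k = np.asarray(kappa, float)
    if w.size < 50:
        raise InvalidArgumentError("need at least 50 grid points")
    if np.any(k < 0):
        raise InvalidArgumentError("kappa must be >= 0")
    if np.any(np.diff(w) <= 0):
        raise InvalidArgumentError("omega grid must be strictly increasing")
    steps = np.diff(w)
    h = float(np.mean(steps))
    if not np.allclose(steps, h, rtol=1e-6):
        warnings.warn("non-uniform omega grid: resampling internally",
                      stacklevel=2)
        wu = np.linspace(w[0], w[-1], w.size)
        k = np.interp(wu, w, k)
        w = wu
        h = float(w[1] - w[0])
    n = w.size
    # one-sided form: n(w) - 1 = (2/pi) P int w' k(w') / (w'^2 - w^2) dw'
    parity = np.arange(n) % 2
    opposite = parity[:, None] != parity[None, :]
    denom = w[None, :] ** 2 - w[:, None] ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        kernel = np.where(opposite, (w * k)[None, :] / denom, 0.0)
    trend = 1.0 + (2.0 / np.pi) * 2.0 * h * kernel.sum(axis=1)
    return trend


def anchor_trend(trend: np.ndarray, reference: float,
                 index: int = 0) -> np.ndarray:
    """Shift an offset-ambiguous trend so ``trend[index] == reference``.

    With an ascending angular-frequency grid, index 0 is the longest
    wavelength — the conventional anchor far from the absorption band.
    """
    t = np.asarray(trend, float)
    return t + (reference - t[index])


def kk_trend_on_wavelengths(wavelengths_nm, kappa,
                            n_points: int = 2048) -> np.ndarray:
    """Convenience: K-K trend for a kappa given on a wavelength grid.

    Resamples onto a uniform angular-frequency grid, transforms, and
    returns the (offset-ambiguous) trend back on the input wavelengths.
    """
    lam = np.asarray(wavelengths_nm, float)
    k = np.asarray(kappa, float)
    order = np.argsort(lam)
    lam_s, k_s = lam[order], k[order]
    w_of_lam = 2.0 * np.pi * LIGHT_SPEED_M_S / (lam_s * 1e-9)
    w_grid = np.linspace(w_of_lam.min(), w_of_lam.max(), n_points)
    k_grid = np.interp(w_grid, w_of_lam[::-1], k_s[::-1])
    trend = kk_rri_trend(w_grid, k_grid)
    out = np.interp(2.0 * np.pi * LIGHT_SPEED_M_S / (lam * 1e-9), w_grid, trend)
    return out
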