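"""Reference dispersions for the media used in the measurement.

``water_rri`` evaluates the Quan & Fry (1995) empirical fit for the real
refractive index of pure water (salinity 0), valid across the visible
band; ``pmma_rri`` evaluates the three-term Sellmeier fit for PMMA
(Szczurowski et al. refractometric data).  Both are pure functions of
wavelength; temperature enters the water formula in degrees Celsius.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidArgumentError
from .types import ComplexIndex

__all__ = ["water_rri", "water_index", "pmma_rri", "pmma_index", "TabulatedIndex"]

# Quan & Fry (1995), Appl. Opt. 34, n(S, T, lambda); S in permil, T in
# Celsius, lambda in nm.  Coefficients for S = 0 reduce to the terms kept
# below.
_QF = dict(
    n0=1.31405, n4=-2.02e-6, n5=15.868, n7=-0.00423, n8=-4382.0, n9=1.1455e6
)


def water_rri(wavelength_nm, temperature_c: float = 20.0):
    """Real refractive index of distilled water, 400-700 nm."""
    lam = np.asarray(wavelength_nm, dtype=float)
    if np.any(lam < 400.0) or np.any(lam > 700.0):
        raise InvalidArgumentError(
            "water dispersion fit is applied only inside 400-700 nm"
        )
    if not -2.0 <= temperature_c <= 40.0:
        raise InvalidArgumentError("water temperature outside fit range")
    c = _QF
    n = (
        c["n0"]
        + c["n4"] * temperature_c**2
        + (c["n5"] + c["n7"] * temperature_c) / lam
        + c["n8"] / lam**2
        + c["n9"] / lam**3
    )
    return n if n.ndim else float(n)


def water_index(wavelength_nm: float, temperature_c: float = 20.0,
                kappa: float = 0.0) -> ComplexIndex:
    """Water as a :class:`ComplexIndex` (absorption negligible in-band)."""
    return ComplexIndex(water_rri(wavelength_nm, temperature_c), kappa)


# Sellmeier coefficients for PMMA, lambda in um.
_PMMA_B = (0.99654, 0.18964, 0.00411)
_PMMA_C = (0.00787, 0.02191, 3.85727)


def pmma_rri(wavelength_nm):
    """Real refractive index of bulk PMMA (Sellmeier fit, visible band)."""
    lam2 = (np.asarray(wavelength_nm, dtype=float) * 1e-3) ** 2
    n2 = 1.0 + sum(b * lam2 / (lam2 - c) for b, c in zip(_PMMA_B, _PMMA_C))
    n = np.sqrt(n2)
    return n if n.ndim else float(n)


def pmma_index(wavelength_nm: float, kappa: float = 1e-5) -> ComplexIndex:
    """PMMA as a :class:`ComplexIndex` with a small default extinction.

    Bulk PMMA is nearly transparent in the visible; the default kappa is a
    nominal residual-absorption value and is refit during calibration.
    """
    return ComplexIndex(pmma_rri(wavelength_nm), kappa)


class TabulatedIndex:
    """Per-wavelength complex index table with linear interpolation.

    Used for calibrated sphere material: exact at the calibration
    wavelengths, linear in between.
    """

    def __init__(self, wavelengths_nm, indices):
        order = np.argsort(wavelengths_nm)
        self._w = np.asarray(wavelengths_nm, dtype=float)[order]
        idx = [indices[i] for i in order]
        self._n = np.array([ci.n for ci in idx])
        self._k = np.array([ci.kappa for ci in idx])
        if self._w.size < 1:
            raise InvalidArgumentError("need at least one tabulated wavelength")

    def __call__(self, wavelength_nm: float) -> ComplexIndex:
        lam = float(wavelength_nm)
        if not (self._w[0] - 1e-9 <= lam <= self._w[-1] + 1e-9):
            raise InvalidArgumentError(
                f"wavelength {lam} nm outside tabulated range "
                f"[{self._w[0]}, {self._w[-1]}]"
            )
        n = float(np.interp(lam, self._w, self._n))
        k = float(np.interp(lam, self._w, self._k))
        return ComplexIndex(n, max(k, 0.0))
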