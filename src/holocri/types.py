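"""Shared domain containers.

Conventions used throughout the package:

* time dependence ``exp(-i omega t)``, so absorption is a *positive*
  imaginary index ``n + i kappa``;
* lengths at the sample plane in micrometres, vacuum wavelengths in
  nanometres;
* spatial frequencies in cycles per micrometre;
* the angle-resolved scattering axis is ``n sin(theta)`` which equals
  ``lambda_vac * f_transverse`` and is therefore independent of the medium
  index assumed during mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "ComplexIndex",
    "SphereSpec",
    "MieSolution",
    "TheoryCurve",
    "ImageGrid",
    "ComplexFieldImage",
    "Hologram",
    "ScatteringCurve",
    "FitResult",
    "CRISpectrum",
]


@dataclass(frozen=True)
class ComplexIndex:
    """One wavelength's complex refractive index ``n + i kappa``."""

    n: float
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.n) and np.isfinite(self.kappa)):
            raise InvalidArgumentError("complex index must be finite")
        if self.n <= 0:
            raise InvalidArgumentError(f"real index must be positive, got {self.n}")
        if self.kappa < 0:
            raise InvalidArgumentError(
                f"imaginary index must be non-negative, got {self.kappa}"
            )

    @property
    def m(self) -> complex:
        """The index as a complex number (absorption = positive imag part)."""
        return complex(self.n, self.kappa)


@dataclass(frozen=True)
class SphereSpec:
    """A homogeneous probe sphere.

    ``material`` is either a single :class:`ComplexIndex` (wavelength-flat)
    or a callable ``wavelength_nm -> ComplexIndex`` such as the PMMA
    dispersion in :mod:`holocri.materials`.
    """

    diameter_um: float
    material: ComplexIndex | Callable[[float], ComplexIndex]

    def __post_init__(self) -> None:
        if not (np.isfinite(self.diameter_um) and self.diameter_um > 0):
            raise InvalidArgumentError("sphere diameter must be positive")

    def index_at(self, wavelength_nm: float) -> ComplexIndex:
        if isinstance(self.material, ComplexIndex):
            return self.material
        return self.material(wavelength_nm)

    @property
    def radius_um(self) -> float:
        return 0.5 * self.diameter_um


@dataclass(frozen=True)
class MieSolution:
    """Truncated Mie coefficient series for one (m, x) pair."""

    a: np.ndarray  # a_1 .. a_{n_max}
    b: np.ndarray
    n_max: int
    size_parameter: complex
    relative_index: complex

    @property
    def orders(self) -> np.ndarray:
        return np.arange(1, self.n_max + 1)


@dataclass(frozen=True)
class TheoryCurve:
    """Normalized model scattering intensity on an ``n sin(theta)`` axis."""

    axis: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        if axis.ndim != 1 or np.any(np.diff(axis) <= 0):
            raise InvalidArgumentError("curve axis must be 1D strictly increasing")
        if np.any(np.asarray(self.intensity) < 0):
            raise InvalidArgumentError("intensities must be non-negative")


@dataclass(frozen=True)
class ImageGrid:
    """Square camera/sample-plane grid."""

    n_pixels: int
    pixel_pitch_um: float
    numerical_aperture: float

    def __post_init__(self) -> None:
        n = self.n_pixels
        if n < 256 or (n & (n - 1)) != 0:
            raise InvalidArgumentError("n_pixels must be a power of two >= 256")
        if self.pixel_pitch_um <= 0:
            raise InvalidArgumentError("pixel pitch must be positive")
        if not (0 < self.numerical_aperture < 1):
            raise InvalidArgumentError("numerical aperture must be in (0, 1)")

    @property
    def field_of_view_um(self) -> float:
        return self.n_pixels * self.pixel_pitch_um

    @property
    def sampling_frequency(self) -> float:
        """Sampling frequency in cycles/um."""
        return 1.0 / self.pixel_pitch_um

    @property
    def nyquist(self) -> float:
        return 0.5 / self.pixel_pitch_um

    @property
    def freq_step(self) -> float:
        return 1.0 / self.field_of_view_um

    def frequency_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Unshifted FFT frequency axes (fx, fy) in cycles/um."""
        f = np.fft.fftfreq(self.n_pixels, d=self.pixel_pitch_um)
        return f, f


@dataclass(frozen=True)
class ComplexFieldImage:
    """Retrieved or simulated complex transmitted field."""

    field: np.ndarray
    grid: ImageGrid
    wavelength_nm: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.field)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise InvalidArgumentError("field must be a square 2D array")
        if arr.shape[0] != self.grid.n_pixels:
            raise InvalidArgumentError("field shape does not match grid")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.field)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.field)


@dataclass(frozen=True)
class Hologram:
    """Off-axis interferogram with a linear fringe carrier."""

    intensity: np.ndarray
    carrier: tuple[float, float]  # (fx, fy), cycles/um
    reference_amplitude: float
    grid: ImageGrid
    wavelength_nm: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity)
        if arr.ndim != 2 or arr.shape[0] != self.grid.n_pixels:
            raise InvalidArgumentError("intensity shape does not match grid")
        if np.any(arr < 0):
            raise InvalidArgumentError("hologram intensity must be non-negative")

    @property
    def carrier_magnitude(self) -> float:
        return float(np.hypot(*self.carrier))


@dataclass(frozen=True)
class ScatteringCurve:
    """Azimuthally averaged angle-resolved scattered intensity.

    ``axis`` holds the per-bin mean of the pixel ``n sin(theta)`` values
    (not the nominal bin centre); ``bin_lo`` the lower edge of each
    reported bin when the curve came from uniform binning.
    """

    axis: np.ndarray
    intensity: np.ndarray
    counts: np.ndarray | None = None
    bin_width: float | None = None
    bin_lo: np.ndarray | None = None
    #: sorted axis values of every contributing pixel (optional; lets a fit
    #: apply the exact same binning operator to model curves)
    pixel_axis: np.ndarray | None = None
    #: start offset of each reported bin within ``pixel_axis``
    pixel_offsets: np.ndarray | None = None

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        if axis.ndim != 1 or np.any(np.diff(axis) <= 0):
            raise InvalidArgumentError("curve axis must be strictly increasing")
        if np.any(np.asarray(self.intensity) < 0):
            raise InvalidArgumentError("intensities must be non-negative")
        if self.counts is not None and np.any(np.asarray(self.counts) < 1):
            raise InvalidArgumentError("every reported bin needs >= 1 pixel")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a Mie inverse fit on one scattering curve."""

    medium_index: ComplexIndex
    diameter_um: float
    residual: float
    init_params: tuple[float, float, float]
    converged: bool
    n_extrema_matched: int | None = None
    n_evaluations: int | None = None
    message: str = ""


@dataclass(frozen=True)
class CRISpectrum:
    """Per-wavelength complex index with replicate scatter."""

    wavelengths_nm: np.ndarray
    indices: Sequence[ComplexIndex]
    sd_n: np.ndarray | None = None
    sd_kappa: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        if np.any(np.diff(w) <= 0):
            raise InvalidArgumentError("wavelengths must be strictly increasing")
        if len(self.indices) != w.size:
            raise InvalidArgumentError("one index per wavelength required")
        for sd in (self.sd_n, self.sd_kappa):
            if sd is not None and np.any(np.asarray(sd) < 0):
                raise InvalidArgumentError("standard deviations must be >= 0")

    @property
    def n(self) -> np.ndarray:
        return np.array([ci.n for ci in self.indices])

    @property
    def kappa(self) -> np.ndarray:
        return np.array([ci.kappa for ci in self.indices])
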