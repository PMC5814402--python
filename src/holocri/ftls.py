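"""Fourier-transform light scattering.

A measured complex transmitted field is numerically propagated to the far
field (a centred 2D discrete Fourier transform), the transverse spatial
frequency of each pixel is mapped to the scattering-angle coordinate
``n sin(theta) = lambda_vac * f_transverse`` (independent of the assumed
medium index, which is why the axis stays put while the fitted index
moves), and the 2D power pattern is azimuthally averaged into a 1D curve.

The obliquity factor cos^2(theta) relating the angular-spectrum power to
far-field radiant intensity is applied in :func:`scattering_curve`; it is
a smooth few-percent correction at the NA used here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft

from .errors import DegenerateCurveError, InvalidArgumentError
from .types import ComplexFieldImage, ImageGrid, ScatteringCurve

__all__ = [
    "FarField",
    "far_field",
    "to_angle_axis",
    "azimuthal_average",
    "scattering_curve",
]


@dataclass(frozen=True)
class FarField:
    """Centred angular spectrum with physical frequency axes."""

    spectrum: np.ndarray      # fftshifted, DC at centre
    freq: np.ndarray          # 1D axis, cycles/um, ascending
    grid: ImageGrid
    wavelength_nm: float

    @property
    def dc_index(self) -> int:
        return self.grid.n_pixels // 2


def far_field(field: ComplexFieldImage) -> FarField:
    """Centred 2D DFT of the field (energy-preserving up to the 1/N^2 of
    the discrete Parseval identity)."""
    arr = np.asarray(field.field)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise InvalidArgumentError("far-field propagation needs a square field")
    spec = scipy.fft.fftshift(scipy.fft.fft2(arr))
    freq = np.fft.fftshift(np.fft.fftfreq(arr.shape[0], d=field.grid.pixel_pitch_um))
    return FarField(spec, freq, field.grid, field.wavelength_nm)


def to_angle_axis(farfield: FarField, medium_n: float) -> np.ndarray:
    """Per-pixel ``n sin(theta)`` map; NaN outside the collection NA.

    The mapping uses only ``lambda * f`` and therefore does not depend on
    ``medium_n``; the argument is kept (and validated) because the angle
    itself does, and downstream obliquity/evanescence reasoning needs a
    physical index.
    """
    if medium_n <= 1.0:
        raise InvalidArgumentError("medium index must exceed 1")
    lam_um = farfield.wavelength_nm * 1e-3
    fx, fy = np.meshgrid(farfield.freq, farfield.freq, indexing="ij")
    ns = lam_um * np.hypot(fx, fy)
    ns[ns > farfield.grid.numerical_aperture] = np.nan
    return ns


def azimuthal_average(power: np.ndarray, axis_map: np.ndarray, n_bins: int = 400,
                      exclude_dc: bool = True,
                      axis_max: float | None = None,
                      keep_pixels: bool = True) -> ScatteringCurve:
    """Mean of ``power`` over uniform ``n sin(theta)`` bins.

    The reported axis of each bin is the mean axis value of its pixels
    (not the nominal centre), which keeps the curve unbiased when bins are
    only a few frequency-pixels wide.  Empty bins are dropped; with
    ``exclude_dc`` the unscattered component (axis below three bin widths)
    is removed.
    """
    if n_bins < 50:
        raise InvalidArgumentError("need at least 50 bins")
    valid = np.isfinite(axis_map) & np.isfinite(power)
    r = axis_map[valid]
    p = power[valid]
    if axis_max is None:
        axis_max = float(r.max()) if r.size else 0.0
    if axis_max <= 0:
        raise InvalidArgumentError("no pixels inside the collection NA")
    width = axis_max / n_bins
    idx = np.minimum((r / width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    p_sum = np.bincount(idx, weights=p, minlength=n_bins)
    r_sum = np.bincount(idx, weights=r, minlength=n_bins)
    keep = counts > 0
    if exclude_dc:
        keep &= (r_sum / np.maximum(counts, 1)) >= 3.0 * width
    if not np.any(keep):
        raise InvalidArgumentError("all bins empty after DC exclusion")
    pixel_axis = pixel_offsets = None
    if keep_pixels:
        in_kept = keep[idx]
        order = np.lexsort((r[in_kept],))
        rk = r[in_kept][order]
        ik = idx[in_kept][order]
        order2 = np.argsort(ik, kind="stable")
        pixel_axis = rk[order2]
        kept_counts = counts[keep]
        pixel_offsets = np.concatenate([[0], np.cumsum(kept_counts)[:-1]])
    return ScatteringCurve(
        axis=r_sum[keep] / counts[keep],
        intensity=p_sum[keep] / counts[keep],
        counts=counts[keep],
        bin_width=width,
        bin_lo=np.nonzero(keep)[0] * width,
        pixel_axis=pixel_axis,
        pixel_offsets=pixel_offsets,
    )


def scattering_curve(field: ComplexFieldImage, medium_n: float,
                     n_bins: int = 400, exclude_dc: bool = True,
                     obliquity: bool = True) -> ScatteringCurve:
    """Field image -> azimuthally averaged angle-resolved intensity curve."""
    ff = far_field(field)
    ns = to_angle_axis(ff, medium_n)
    power = np.abs(ff.spectrum) ** 2
    if obliquity:
        with np.errstate(invalid="ignore"):
            cos2 = 1.0 - (ns / medium_n) ** 2
        power = power * cos2
    curve = azimuthal_average(power, ns, n_bins=n_bins, exclude_dc=exclude_dc,
                              axis_max=field.grid.numerical_aperture)
    if float(np.max(curve.intensity)) <= 0:
        raise DegenerateCurveError("no scattered power inside the NA")
    return curve


def curve_to_csv(curve: ScatteringCurve, path) -> None:
    cols = [curve.axis, curve.intensity]
    header = "n_sin_theta,intensity"
    if curve.counts is not None:
        cols.append(curve.counts)
        header += ",counts"
    np.savetxt(path, np.column_stack(cols), delimiter=",", header=header,
               comments="", fmt="%.15g")
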