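"""Complex-field retrieval from off-axis holograms.

Fourier sideband demodulation: the hologram term U R* exp(-i 2 pi c.r)
places the object spectrum at -c, so the sideband centred on the negated
carrier is cropped with a raised-cosine circular mask, recentred by an
integer-pixel shift, and inverse transformed; dividing the sample by the
background field cancels the reference wave, any residual sub-pixel
carrier ramp and any smooth illumination profile common to both.
"""

from __future__ import annotations

import numpy as np
import scipy.fft

from .errors import DemodulationError, InvalidArgumentError
from .types import ComplexFieldImage, Hologram

__all__ = ["detect_carrier", "retrieve_field", "unwrapped_phase"]


def _jacobsen_delta(xm: complex, x0: complex, xp: complex) -> float:
    """Sub-bin frequency offset of a peak from three complex DFT bins.

    Jacobsen's estimator, exact for an unwindowed complex exponential.
    """
    denom = 2.0 * x0 - xm - xp
    if denom == 0:
        return 0.0
    delta = float(-((xp - xm) / denom).real)
    return float(np.clip(delta, -0.5, 0.5))


def detect_carrier(holo: Hologram, dc_exclusion_frac: float = 0.4,
                   min_peak_ratio: float = 3.0) -> tuple[float, float]:
    """Sub-pixel spatial frequency of the fringe carrier (cycles/um).

    Finds the strongest Fourier peak outside a DC exclusion disk (the
    self-interference band) and refines it to sub-pixel precision.  Of the
    two conjugate sidebands the one in the upper frequency half-plane is
    reported.  Scaling the intensity by a positive constant leaves the
    result unchanged.
    """
    n = holo.grid.n_pixels
    spec = scipy.fft.fft2(np.asarray(holo.intensity, dtype=float))
    f1d = np.fft.fftfreq(n, d=holo.grid.pixel_pitch_um)
    fx, fy = np.meshgrid(f1d, f1d, indexing="ij")
    fr = np.hypot(fx, fy)
    nyq = holo.grid.nyquist
    mag = np.abs(spec)
    search = fr >= dc_exclusion_frac * nyq
    if not np.any(search):
        raise DemodulationError("DC exclusion leaves no search region")
    floor = float(np.median(mag[search]))
    # restrict to the deterministic half-plane fy > 0 (or fy == 0, fx > 0)
    half = search & ((fy > 0) | ((fy == 0) & (fx > 0)))
    masked = np.where(half, mag, 0.0)
    i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
    if masked[i, j] <= 0 or masked[i, j] < min_peak_ratio * floor:
        raise DemodulationError(
            f"no fringe peak above {min_peak_ratio}x the background magnitude"
        )
    di = _jacobsen_delta(spec[(i - 1) % n, j], spec[i, j], spec[(i + 1) % n, j])
    dj = _jacobsen_delta(spec[i, (j - 1) % n], spec[i, j], spec[i, (j + 1) % n])
    df = holo.grid.freq_step
    cx = f1d[i] + di * df
    cy = f1d[j] + dj * df
    return (float(cx), float(cy))


def _sideband_mask(grid, centre: tuple[float, float], radius: float,
                   edge_width_px: float) -> np.ndarray:
    f1d = np.fft.fftfreq(grid.n_pixels, d=grid.pixel_pitch_um)
    fx, fy = np.meshgrid(f1d, f1d, indexing="ij")
    # distance on the frequency torus (sidebands may sit near the edge)
    fs = grid.sampling_frequency
    dx = (fx - centre[0] + 0.5 * fs) % fs - 0.5 * fs
    dy = (fy - centre[1] + 0.5 * fs) % fs - 0.5 * fs
    dist = np.hypot(dx, dy)
    edge = edge_width_px * grid.freq_step
    inner = radius - edge
    mask = np.clip((radius - dist) / max(edge, 1e-300), 0.0, 1.0)
    mask[dist <= inner] = 1.0
    return 0.5 - 0.5 * np.cos(np.pi * mask) if edge > 0 else (dist <= radius) * 1.0


def _demodulate(holo: Hologram, carrier: tuple[float, float], radius: float,
                edge_width_px: float) -> np.ndarray:
    n = holo.grid.n_pixels
    spec = scipy.fft.fft2(np.asarray(holo.intensity, dtype=float))
    centre = (-carrier[0], -carrier[1])
    mask = _sideband_mask(holo.grid, centre, radius, edge_width_px)
    df = holo.grid.freq_step
    shift = (int(np.rint(carrier[0] / df)), int(np.rint(carrier[1] / df)))
    side = np.roll(spec * mask, shift, axis=(0, 1))
    return scipy.fft.ifft2(side)


def retrieve_field(sample: Hologram, background: Hologram,
                   carrier: tuple[float, float] | None = None,
                   mask_radius: float | None = None,
                   edge_width_px: float = 8.0) -> ComplexFieldImage:
    """Background-normalised complex field from a sample/background pair.

    The output amplitude approximates the relative transmittance and the
    phase the sample-induced delay, wrapped to (-pi, pi]; see
    :func:`unwrapped_phase` for a continuous phase map.  FTLS consumes the
    complex field directly, which needs no unwrapping.
    """
    if sample.grid != background.grid or sample.wavelength_nm != background.wavelength_nm:
        raise InvalidArgumentError("sample and background must share grid and wavelength")
    if carrier is None:
        carrier = sample.carrier if sample.carrier is not None \
            else detect_carrier(background)
    if sample.carrier is not None and background.carrier is not None:
        if not np.allclose(sample.carrier, background.carrier):
            raise InvalidArgumentError("sample and background carriers differ")
    cmag = float(np.hypot(*carrier))
    if cmag <= 0:
        raise DemodulationError("zero carrier; hologram has no fringes")
    if mask_radius is None:
        nyq = sample.grid.nyquist
        dist_edge = min(nyq - abs(carrier[0]), nyq - abs(carrier[1]))
        mask_radius = 0.5 * min(cmag, max(dist_edge, 0.0))
    if mask_radius <= 0:
        raise DemodulationError("carrier too close to DC or Nyquist to crop a sideband")

    u_s = _demodulate(sample, carrier, mask_radius, edge_width_px)
    u_b = _demodulate(background, carrier, mask_radius, edge_width_px)
    tiny = 1e-12 * float(np.abs(u_b).max())
    if tiny == 0.0:
        raise DemodulationError("background sideband is empty")
    ratio = u_s / np.where(np.abs(u_b) < tiny, tiny, u_b)
    return ComplexFieldImage(ratio, sample.grid, sample.wavelength_nm)


def unwrapped_phase(field: ComplexFieldImage) -> np.ndarray:
    """Quality-guided 2D unwrapping of the field's phase map."""
    from skimage.restoration import unwrap_phase

    return np.asarray(unwrap_phase(np.angle(field.field)))
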