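"""Mie scattering forward model for a sphere in a weakly absorbing host.

The expansion coefficients a_n, b_n are computed Bohren-&-Huffman style:
the logarithmic derivative D_n(mx) by downward recurrence seeded with a
continued fraction (modified Lentz), and the host Riccati-Bessel functions
psi_n(x), chi_n(x) by upward recurrence.  Both the relative index
``m = m_sphere / m_medium`` and the size parameter
``x = 2 pi m_medium r / lambda`` may be complex; host absorption in the
regime relevant here (kappa_medium <~ 5e-3) gives |Im x| of order 0.1, for
which the plain double-precision recurrences remain well conditioned.  Far
field intensities are formed from |S|^2 without host-path attenuation; the
incident-beam attenuation is carried by the synthesis module.

Time convention exp(-i omega t): absorption is +i kappa and the outgoing
Riccati-Hankel function is xi_n = psi_n - i chi_n.
"""

from __future__ import annotations

import numpy as np

from .errors import CapabilityError, DegenerateCurveError, InvalidArgumentError
from .types import ComplexIndex, MieSolution, SphereSpec, TheoryCurve

__all__ = [
    "recommended_n_max",
    "mie_coefficients",
    "scattering_amplitudes",
    "efficiencies",
    "theory_curve",
    "size_parameter",
]

#: Largest |x| the double-precision recurrences are validated for.
MAX_SIZE_PARAMETER = 1500.0


def recommended_n_max(size_parameter: complex) -> int:
    """Wiscombe truncation order ceil(|x| + 4.05 |x|^(1/3) + 2)."""
    xm = abs(size_parameter)
    return int(np.ceil(xm + 4.05 * xm ** (1.0 / 3.0) + 2.0))


def size_parameter(sphere_diameter_um: float, medium: ComplexIndex,
                   wavelength_nm: float) -> complex:
    """Complex size parameter 2 pi m_medium r / lambda_vacuum."""
    lam_um = wavelength_nm * 1e-3
    return 2.0 * np.pi * medium.m * (0.5 * sphere_diameter_um) / lam_um


def _lentz_log_derivative(z: complex, order: int, tol: float = 1e-16,
                          max_terms: int = 20000) -> complex:
    """D_order(z) = psi'_order / psi_order via the ratio continued fraction.

    Uses r_n = psi_{n-1}/psi_n = (2n+1)/z - 1/r_{n+1} evaluated by the
    modified Lentz algorithm, then D_n = r_n - n/z.
    """
    tiny = 1e-290
    b = (2.0 * order + 1.0) / z
    f = b if b != 0 else tiny
    c = f
    d = 0.0 + 0.0j
    for k in range(1, max_terms):
        b = (2.0 * (order + k) + 1.0) / z
        d = b - d
        if d == 0:
            d = tiny
        c = b - 1.0 / c
        if c == 0:
            c = tiny
        d = 1.0 / d
        delta = c * d
        f *= delta
        if abs(delta - 1.0) < tol:
            return f - order / z
    raise CapabilityError("continued fraction for D_n did not converge")


def _log_derivative_down(z: complex, n_max: int, extra: int = 15) -> np.ndarray:
    """D_1..D_n_max by downward recurrence from a Lentz-seeded start."""
    start = n_max + extra
    d = _lentz_log_derivative(z, start)
    out = np.empty(n_max + 1, dtype=complex)  # out[n] = D_n, index 0 unused
    for n in range(start, 0, -1):
        d = n / z - 1.0 / (d + n / z)
        if 1 <= n - 1 <= n_max:
            out[n - 1] = d
    return out


def _riccati_psi_chi(z: complex, n_max: int) -> tuple[np.ndarray, np.ndarray]:
    """psi_n(z), chi_n(z) for n = 0..n_max.

    chi (dominant beyond the turning point) by upward recurrence; psi
    (minimal) by downward recurrence from an overshoot start so the
    decaying tail n > |z| keeps full relative accuracy, normalised against
    the closed forms at n = 0, 1.  The overshoot margin grows like |z|^(1/3)
    because solution-growth separation is slow near the turning point.
    """
    sz, cz = np.sin(z), np.cos(z)
    chi = np.empty(n_max + 1, dtype=complex)
    chi[0] = cz
    if n_max >= 1:
        chi[1] = cz / z + sz
    for n in range(1, n_max):
        chi[n + 1] = (2.0 * n + 1.0) / z * chi[n] - chi[n - 1]

    extra = max(15, int(10.0 * abs(z) ** (1.0 / 3.0)))
    start = n_max + extra
    p_hi, p_lo = 0.0 + 0.0j, 1e-150 + 0.0j
    psi = np.empty(n_max + 1, dtype=complex)
    for k in range(start, -1, -1):
        if k <= n_max:
            psi[k] = p_lo
        p_hi, p_lo = p_lo, (2.0 * k + 1.0) / z * p_lo - p_hi
        if abs(p_lo) > 1e250:  # rescale to avoid overflow at small |z|
            p_hi /= 1e250
            p_lo /= 1e250
            if k <= n_max:
                psi[k:] /= 1e250
    psi0, psi1 = sz, (sz / z - cz if n_max >= 1 else sz)
    if n_max >= 1 and abs(psi[1]) > abs(psi[0]):
        scale = psi1 / psi[1]
    else:
        scale = psi0 / psi[0]
    psi *= scale
    return psi, chi


def mie_coefficients(relative_index: complex, size_parameter: complex,
                     n_max: int | None = None) -> MieSolution:
    """Expansion coefficients a_n, b_n for a homogeneous sphere.

    Parameters
    ----------
    relative_index
        m = m_sphere / m_medium (complex, absorption positive imaginary).
    size_parameter
        x = 2 pi m_medium r / lambda (complex for an absorbing host).
    n_max
        Truncation order; defaults to the recommended order and must not
        be below it.
    """
    m = complex(relative_index)
    x = complex(size_parameter)
    if not (np.isfinite(m.real) and np.isfinite(m.imag)
            and np.isfinite(x.real) and np.isfinite(x.imag)):
        raise InvalidArgumentError("relative index and size parameter must be finite")
    if abs(x) == 0:
        raise InvalidArgumentError("size parameter must be nonzero")
    if abs(x) > MAX_SIZE_PARAMETER:
        raise CapabilityError(
            f"|x| = {abs(x):.1f} exceeds the supported limit "
            f"{MAX_SIZE_PARAMETER:g} for the double-precision recurrences"
        )
    rec = recommended_n_max(x)
    if n_max is None:
        n_max = rec
    elif n_max < rec:
        raise InvalidArgumentError(
            f"n_max = {n_max} below recommended truncation {rec}"
        )

    if m == 1.0:  # index-matched sphere scatters nothing
        zeros = np.zeros(n_max, dtype=complex)
        return MieSolution(zeros, zeros.copy(), n_max, x, m)

    d = _log_derivative_down(m * x, n_max)
    psi, chi = _riccati_psi_chi(x, n_max)
    xi = psi - 1j * chi

    n = np.arange(1, n_max + 1, dtype=float)
    dn = d[1:]
    fa = dn / m + n / x
    fb = dn * m + n / x
    a = (fa * psi[1:] - psi[:-1]) / (fa * xi[1:] - xi[:-1])
    b = (fb * psi[1:] - psi[:-1]) / (fb * xi[1:] - xi[:-1])
    if not (np.all(np.isfinite(a.view(float))) and np.all(np.isfinite(b.view(float)))):
        raise CapabilityError("overflow in Mie recurrences; reduce |x|")
    return MieSolution(a, b, int(n_max), x, m)


def scattering_amplitudes(solution: MieSolution, angles_rad) -> tuple[np.ndarray, np.ndarray]:
    """Complex amplitudes S1, S2 at the given scattering angles.

    The angular functions pi_n, tau_n are generated by the standard stable
    upward recurrence in cos(theta), vectorized over angles.
    """
    theta = np.atleast_1d(np.asarray(angles_rad, dtype=float))
    if np.any(theta < 0) or np.any(theta > np.pi + 1e-12):
        raise InvalidArgumentError("scattering angles must lie in [0, pi]")
    mu = np.cos(theta)

    s1 = np.zeros(theta.shape, dtype=complex)
    s2 = np.zeros(theta.shape, dtype=complex)
    pi_prev = np.zeros_like(mu)   # pi_0
    pi_cur = np.ones_like(mu)     # pi_1
    for n in range(1, solution.n_max + 1):
        tau = n * mu * pi_cur - (n + 1.0) * pi_prev
        w = (2.0 * n + 1.0) / (n * (n + 1.0))
        s1 += w * (solution.a[n - 1] * pi_cur + solution.b[n - 1] * tau)
        s2 += w * (solution.a[n - 1] * tau + solution.b[n - 1] * pi_cur)
        pi_next = ((2.0 * n + 1.0) * mu * pi_cur - (n + 1.0) * pi_prev) / n
        pi_prev, pi_cur = pi_cur, pi_next
    return s1, s2


def efficiencies(solution: MieSolution) -> tuple[float, float]:
    """(Q_ext, Q_sca) for a transparent host.

    Defined for real size parameter; a small imaginary part (|Im x| below
    1e-9 |x|) is tolerated and ignored.
    """
    x = solution.size_parameter
    if abs(x.imag) > 1e-9 * abs(x):
        raise InvalidArgumentError(
            "efficiencies are defined for a non-absorbing host (real x)"
        )
    xr = x.real
    n = np.arange(1, solution.n_max + 1, dtype=float)
    w = 2.0 * n + 1.0
    q_ext = (2.0 / xr**2) * float(np.sum(w * (solution.a + solution.b).real))
    q_sca = (2.0 / xr**2) * float(
        np.sum(w * (np.abs(solution.a) ** 2 + np.abs(solution.b) ** 2))
    )
    return q_ext, q_sca


def unpolarized_intensity(solution: MieSolution, angles_rad) -> np.ndarray:
    """(|S1|^2 + |S2|^2) / 2 — azimuthal mean for unpolarized detection."""
    s1, s2 = scattering_amplitudes(solution, angles_rad)
    return 0.5 * (np.abs(s1) ** 2 + np.abs(s2) ** 2)


def theory_curve(sphere: SphereSpec, medium: ComplexIndex, wavelength_nm: float,
                 axis, normalize: bool = True) -> TheoryCurve:
    """Model angle-resolved intensity on an ``n sin(theta)`` axis.

    The axis value is ``medium.n * sin(theta)``; values at or above the
    medium index would correspond to evanescent directions and are
    rejected.
    """
    axis = np.asarray(axis, dtype=float)
    if wavelength_nm <= 0:
        raise InvalidArgumentError("wavelength must be positive")
    if np.any(axis < 0) or np.any(axis >= medium.n):
        raise InvalidArgumentError(
            f"axis values must lie in [0, n_medium = {medium.n}); larger "
            "values are evanescent and carry no propagating scattered power"
        )
    x = size_parameter(sphere.diameter_um, medium, wavelength_nm)
    m_rel = sphere.index_at(wavelength_nm).m / medium.m
    sol = mie_coefficients(m_rel, x)
    theta = np.arcsin(axis / medium.n)
    intensity = unpolarized_intensity(sol, theta)
    if normalize:
        peak = float(intensity.max(initial=0.0))
        if peak <= 0.0:
            raise DegenerateCurveError(
                "scattered intensity is identically zero; cannot normalize"
            )
        intensity = intensity / peak
    return TheoryCurve(axis=axis, intensity=intensity)


def curve_to_csv(curve: TheoryCurve, path) -> None:
    """Write a theory curve as a two-column CSV (axis, intensity)."""
    arr = np.column_stack([curve.axis, curve.intensity])
    np.savetxt(path, arr, delimiter=",", header="n_sin_theta,intensity",
               comments="", fmt="%.15g")
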