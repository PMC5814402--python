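"""Independent reference computations used only by the test suite.

Two routes that share no code with holocri.mie:

* ``scipy_mie_coefficients`` — textbook coefficient formula evaluated with
  scipy's spherical Bessel functions (real arguments only).
* ``mpmath_mie_coefficients`` — arbitrary-precision evaluation of the same
  series with mpmath, valid for complex m and x; Riccati-Bessel functions
  by recurrence carried at high working precision so that downward /
  upward stability is immaterial.

Plus closed forms: the Rayleigh small-sphere scattering efficiency and the
exact Lorentz-oscillator Kramers-Kronig conjugate pair.
"""

from __future__ import annotations

import mpmath as mp
import numpy as np
from scipy.special import spherical_jn, spherical_yn


def scipy_mie_coefficients(m: float, x: float, n_max: int):
    """a_n, b_n (n = 1..n_max) from scipy Bessel functions; real m, x."""
    n = np.arange(0, n_max + 1, dtype=float)
    psi_x = x * spherical_jn(n.astype(int), x)
    xi_x = x * (spherical_jn(n.astype(int), x) + 1j * spherical_yn(n.astype(int), x))
    psi_mx = m * x * spherical_jn(n.astype(int), m * x)

    def deriv(f, z):
        d = np.empty_like(f)
        d[0] = np.nan
        d[1:] = f[:-1] - (n[1:] / z) * f[1:]
        return d

    dpsi_x = deriv(psi_x, x)
    dxi_x = deriv(xi_x, x)
    dpsi_mx = deriv(psi_mx, m * x)

    a = (m * psi_mx[1:] * dpsi_x[1:] - psi_x[1:] * dpsi_mx[1:]) / (
        m * psi_mx[1:] * dxi_x[1:] - xi_x[1:] * dpsi_mx[1:]
    )
    b = (psi_mx[1:] * dpsi_x[1:] - m * psi_x[1:] * dpsi_mx[1:]) / (
        psi_mx[1:] * dxi_x[1:] - m * xi_x[1:] * dpsi_mx[1:]
    )
    return a, b


def _mp_riccati(z, n_max):
    """psi_n, chi_n for n = 0..n_max at mpmath working precision.

    psi by downward recurrence from an overshoot order (normalised against
    psi_0), chi by upward recurrence; both exact to working precision.
    """
    # near the turning point n ~ |z| the minimal/dominant solution ratio
    # grows slowly, so the downward start must overshoot generously for the
    # seed error to be suppressed below working precision
    overshoot = n_max + max(100, n_max // 2)
    # downward for the ratio-stable psi
    p_hi = mp.mpc(0)
    p_lo = mp.mpc(1e-40)
    psi_rev = []
    for k in range(overshoot, -1, -1):
        if k <= n_max:
            psi_rev.append(p_lo)
        p_hi, p_lo = p_lo, (2 * k + 1) / z * p_lo - p_hi
    psi = list(reversed(psi_rev))
    scale = mp.sin(z) / psi[0]
    psi = [p * scale for p in psi]
    chi = [mp.cos(z), mp.cos(z) / z + mp.sin(z)]
    for k in range(1, n_max):
        chi.append((2 * k + 1) / z * chi[k] - chi[k - 1])
    return psi, chi[: n_max + 1]


def mpmath_mie_coefficients(m, x, n_max, dps: int = 60):
    """a_n, b_n (n = 1..n_max) at dps decimal digits; complex m, x allowed."""
    with mp.workdps(dps):
        m = mp.mpc(m)
        x = mp.mpc(x)
        psi_x, chi_x = _mp_riccati(x, n_max)
        psi_mx, _ = _mp_riccati(m * x, n_max)
        xi_x = [p - 1j * c for p, c in zip(psi_x, chi_x)]
        a = np.empty(n_max, dtype=complex)
        b = np.empty(n_max, dtype=complex)
        for n in range(1, n_max + 1):
            dpsi_x = psi_x[n - 1] - n / x * psi_x[n]
            dxi_x = xi_x[n - 1] - n / x * xi_x[n]
            dpsi_mx = psi_mx[n - 1] - n / (m * x) * psi_mx[n]
            an = (m * psi_mx[n] * dpsi_x - psi_x[n] * dpsi_mx) / (
                m * psi_mx[n] * dxi_x - xi_x[n] * dpsi_mx
            )
            bn = (psi_mx[n] * dpsi_x - m * psi_x[n] * dpsi_mx) / (
                psi_mx[n] * dxi_x - m * xi_x[n] * dpsi_mx
            )
            a[n - 1] = complex(an)
            b[n - 1] = complex(bn)
    return a, b


def rayleigh_q_sca(m: complex, x: float) -> float:
    """Small-sphere limit Q_sca = (8/3) x^4 |(m^2-1)/(m^2+2)|^2."""
    lor = (m**2 - 1.0) / (m**2 + 2.0)
    return (8.0 / 3.0) * x**4 * abs(lor) ** 2


def lorentz_kk_pair(omega, omega0, gamma, amplitude):
    """Exact conjugate pair of a single Lorentz oscillator.

    chi(w) = A / (w0^2 - w^2 - i gamma w); returns (n_minus_1, kappa) with
    n - 1 = Re chi / 2 and kappa = Im chi / 2, which satisfy the
    refractive-index Kramers-Kronig relation exactly.
    """
    w = np.asarray(omega, dtype=float)
    denom = (omega0**2 - w**2) ** 2 + (gamma * w) ** 2
    n_minus_1 = 0.5 * amplitude * (omega0**2 - w**2) / denom
    kappa = 0.5 * amplitude * gamma * w / denom
    return n_minus_1, kappa
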