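"""Inverse Mie fitting: medium CRI (n, kappa) and sphere diameter from a
measured angle-resolved scattering curve.

The highly oscillatory curve makes naive least squares initialization-
dependent, so the fit is two-stage:

1. *extrema-variance initialization* — a deterministic grid search that
   minimizes the summed squared differences between matched measured and
   theoretical extrema positions (greedy one-to-one nearest-neighbour
   matching; unmatched extrema cost one bin-width squared each);
2. *nonlinear least squares* on the log of the max-normalized intensities,
   which weights fringe positions over peak heights across the several
   decades the curve spans.

The model intensity is averaged over each measured bin (Simpson rule with
an annulus-density weight proportional to the axis value) so that binned
data are compared against binned theory, not point samples.

The same engine fits the sphere instead of the medium for the
water-immersion calibration workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares

from . import mie
from .errors import (CalibrationWarning, DegenerateCurveError,
                     InitializationError, InvalidArgumentError)
from .materials import TabulatedIndex
from .types import ComplexIndex, CRISpectrum, FitResult, ScatteringCurve, SphereSpec

__all__ = [
    "find_extrema",
    "extrema_objective",
    "initialize_candidates",
    "initialize_fit",
    "phase_align_init",
    "fit_cri",
    "fit_curve",
    "fit_sphere_cri",
    "calibrate_sphere",
    "CalibrationResult",
    "spectrum_from_fits",
    "DEFAULT_MEDIUM_BOUNDS",
]

#: fit bounds for the medium: n, kappa, diameter as fraction of nominal
DEFAULT_MEDIUM_BOUNDS = ((1.30, 1.40), (0.0, 5e-3), (0.95, 1.05))
#: default initializer search ranges for the medium
DEFAULT_MEDIUM_GRID = (
    np.linspace(1.32, 1.36, 9),
    np.linspace(0.0, 1e-3, 3),
    np.linspace(0.98, 1.02, 9),  # fraction of nominal diameter
)

# Relative intensity floor inside the log residual.  The deepest fringe
# minima carry little parameter information but huge log sensitivity;
# flooring them at 1e-4 of the curve maximum keeps the least-squares
# surface smooth without touching the fringe structure that carries n, d.
_LOG_FLOOR = 1e-4


def find_extrema(curve: ScatteringCurve, smoothing_halfwidth: int = 0) -> np.ndarray:
    """Ordered sub-bin positions of the local extrema of log-intensity.

    Positions are refined by a parabola through each extremum and its two
    neighbours; adding a constant to the intensity shifts log-values but
    not the positions.
    """
    y = np.log(np.asarray(curve.intensity, float)
               + _LOG_FLOOR * float(np.max(curve.intensity)))
    x = np.asarray(curve.axis, float)
    if smoothing_halfwidth > 0:
        k = 2 * smoothing_halfwidth + 1
        kernel = np.ones(k) / k
        y = np.convolve(y, kernel, mode="same")
        y[:smoothing_halfwidth] = y[smoothing_halfwidth]
        y[-smoothing_halfwidth:] = y[-smoothing_halfwidth - 1]
    d = np.diff(y)
    s = np.sign(d)
    idx = np.nonzero(s[:-1] * s[1:] < 0)[0] + 1
    positions = []
    for i in idx:
        x0, x1, x2 = x[i - 1], x[i], x[i + 1]
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
        a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
        b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
        positions.append(x1 if a == 0 else -b / (2 * a))
    positions = np.asarray(positions)
    if positions.size < 3:
        raise DegenerateCurveError(
            f"only {positions.size} extrema found; need at least 3"
        )
    return np.sort(positions)


def _greedy_match(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, int]:
    """Greedy one-to-one nearest matching; returns (squared dists, n_unmatched)."""
    if p.size == 0 or q.size == 0:
        return np.empty(0), p.size + q.size
    d = np.abs(p[:, None] - q[None, :])
    matched = []
    rows = np.ones(p.size, bool)
    cols = np.ones(q.size, bool)
    order = np.argsort(d, axis=None)
    for flat in order:
        i, j = np.unravel_index(flat, d.shape)
        if rows[i] and cols[j]:
            rows[i] = cols[j] = False
            matched.append(d[i, j] ** 2)
            if not (rows.any() and cols.any()):
                break
    unmatched = int(rows.sum() + cols.sum())
    return np.asarray(matched), unmatched


def extrema_objective(measured_pos: np.ndarray, theory_pos: np.ndarray,
                      bin_width: float) -> tuple[float, int]:
    """(total variance of matched extrema positions + penalty, n matched)."""
    sq, unmatched = _greedy_match(measured_pos, theory_pos)
    return float(sq.sum() + unmatched * bin_width**2), int(sq.size)


def _model_point_intensity(axis, wavelength_nm, medium_m: complex,
                           sphere_m: complex, diameter_um: float) -> np.ndarray:
    lam_um = wavelength_nm * 1e-3
    x = 2.0 * np.pi * medium_m * (0.5 * diameter_um) / lam_um
    sol = mie.mie_coefficients(sphere_m / medium_m, x)
    theta = np.arcsin(np.asarray(axis, float) / medium_m.real)
    return mie.unpolarized_intensity(sol, theta)


class _BinnedModel:
    """Model intensity put through the same binning as the measured curve.

    Three fidelity levels depending on what the curve carries:

    * pixel mode — the curve retains the axis value of every contributing
      frequency pixel; the model is spline-evaluated at those radii and
      averaged per bin, reproducing the measurement's binning operator
      exactly;
    * Simpson mode — only bin edges are known; bin averages by Simpson
      rule with an annulus-density weight (pixel count per axis interval
      grows linearly with the axis value);
    * point mode — no bin structure (external data): point evaluation.
    """

    def __init__(self, curve: ScatteringCurve, wavelength_nm: float,
                 n_sub: int = 8):
        self.wavelength_nm = wavelength_nm
        self.mode = "point"
        if curve.pixel_axis is not None and curve.pixel_offsets is not None \
                and curve.bin_width is not None:
            self.mode = "pixel"
            self.pixels = np.asarray(curve.pixel_axis, float)
            self.offsets = np.asarray(curve.pixel_offsets, int)
            self.bin_counts = np.asarray(curve.counts, float)
            step = float(curve.bin_width) / n_sub
            lo = max(self.pixels.min() - step, 0.0)
            hi = self.pixels.max() + step
            self.dense = np.linspace(lo, hi, int(np.ceil((hi - lo) / step)) + 1)
        elif curve.bin_width is not None and curve.bin_lo is not None:
            self.mode = "simpson"
            w = float(curve.bin_width)
            lo = np.asarray(curve.bin_lo, float)
            step = w / n_sub
            k0 = int(np.rint(lo[0] / step))
            k1 = int(np.rint((lo[-1] + w) / step))
            self.dense = (k0 + np.arange(k1 - k0 + 1)) * step
            self.take = (np.rint(lo / step).astype(int) - k0)[:, None] \
                + np.arange(n_sub + 1)[None, :]
            simp = np.ones(n_sub + 1)
            simp[1:-1:2] = 4.0
            simp[2:-1:2] = 2.0
            self.weights = simp[None, :] * np.maximum(self.dense[self.take], 1e-12)
            self.norm = self.weights.sum(axis=1)
        else:
            self.dense = np.asarray(curve.axis, float)

    def __call__(self, medium_m: complex, sphere_m: complex,
                 diameter_um: float) -> np.ndarray:
        i_dense = _model_point_intensity(self.dense, self.wavelength_nm,
                                         medium_m, sphere_m, diameter_um)
        if self.mode == "point":
            return i_dense
        if self.mode == "simpson":
            return (self.weights * i_dense[self.take]).sum(axis=1) / self.norm
        at_pixels = CubicSpline(self.dense, i_dense)(self.pixels)
        sums = np.add.reduceat(at_pixels, self.offsets)
        return sums / self.bin_counts


def _log_residual(model: np.ndarray, measured_log: np.ndarray) -> np.ndarray:
    m = model / model.max()
    return np.log(m + _LOG_FLOOR) - measured_log


def _measured_log(curve: ScatteringCurve) -> np.ndarray:
    i = np.asarray(curve.intensity, float)
    return np.log(i / i.max() + _LOG_FLOOR)


def initialize_candidates(measured: ScatteringCurve, sphere: SphereSpec,
                          wavelength_nm: float,
                          search_grid: tuple | None = None,
                          smoothing_halfwidth: int = 0
                          ) -> list[tuple[float, tuple[float, float, float], int]]:
    """All grid points ranked by the extrema-variance objective.

    Returns (objective, (n, kappa, d), n_matched) sorted ascending.  The
    fringe pattern makes (n, d) partially degenerate — position alignment
    trades the two along a valley — so downstream fitting should try the
    best few well-separated candidates, not only the argmin.
    """
    n_grid, k_grid, dfrac_grid = search_grid or DEFAULT_MEDIUM_GRID
    meas_pos = find_extrema(measured, smoothing_halfwidth)
    w = measured.bin_width or float(np.median(np.diff(measured.axis)))
    sphere_m = sphere.index_at(wavelength_nm).m
    axis = measured.axis
    out = []
    for d_frac in dfrac_grid:
        d = sphere.diameter_um * d_frac
        for n_med in n_grid:
            for k_med in k_grid:
                model = _model_point_intensity(axis, wavelength_nm,
                                               complex(n_med, k_med), sphere_m, d)
                tc = ScatteringCurve(axis=axis, intensity=model)
                try:
                    theo_pos = find_extrema(tc, smoothing_halfwidth)
                except DegenerateCurveError:
                    continue
                obj, n_match = extrema_objective(meas_pos, theo_pos, w)
                if n_match >= 3:
                    out.append((obj, (float(n_med), float(k_med), float(d)),
                                n_match))
    if not out:
        raise InitializationError(
            "no grid point matched at least 3 extrema; widen the search grid"
        )
    return sorted(out, key=lambda t: t[0])


def _refine_candidate(measured: ScatteringCurve, sphere: SphereSpec,
                      wavelength_nm: float, p: tuple[float, float, float],
                      meas_pos: np.ndarray, bin_width: float,
                      dn: float = 2e-3, dd_frac: float = 3e-3,
                      ) -> tuple[float, tuple[float, float, float], int]:
    """Local sub-grid polish of one initializer candidate.

    The coarse grid cannot resolve the sharp minimum of the extrema
    objective (position alignment degrades within ~1e-3 in n), so each
    promising candidate is refined on a small local (n, d) grid before
    final ranking.
    """
    sphere_m = sphere.index_at(wavelength_nm).m
    axis = measured.axis
    best = (np.inf, p, 0)
    for d in p[2] * (1.0 + np.linspace(-dd_frac, dd_frac, 5)):
        for n_med in p[0] + np.linspace(-dn, dn, 9):
            model = _model_point_intensity(axis, wavelength_nm,
                                           complex(n_med, p[1]), sphere_m, d)
            try:
                theo_pos = find_extrema(
                    ScatteringCurve(axis=axis, intensity=model))
            except DegenerateCurveError:
                continue
            obj, n_match = extrema_objective(meas_pos, theo_pos, bin_width)
            if n_match >= 3 and obj < best[0]:
                best = (obj, (float(n_med), p[1], float(d)), n_match)
    return best


def refined_candidates(measured: ScatteringCurve, sphere: SphereSpec,
                       wavelength_nm: float,
                       search_grid: tuple | None = None,
                       top_k: int = 8
                       ) -> list[tuple[float, tuple[float, float, float], int]]:
    """Coarse grid search + local refinement of the best candidates.

    Candidates are deduplicated (separated by > 3e-3 in n or > 0.5% in d)
    before refinement and re-ranked by the refined objective.
    """
    ranked = initialize_candidates(measured, sphere, wavelength_nm, search_grid)
    distinct: list[tuple[float, tuple[float, float, float], int]] = []
    for cand in ranked:
        if len(distinct) >= top_k:
            break
        _, p, _ = cand
        if all(abs(p[0] - q[1][0]) > 3e-3 or abs(p[2] - q[1][2]) > 5e-3 * p[2]
               for q in distinct):
            distinct.append(cand)
    meas_pos = find_extrema(measured)
    w = measured.bin_width or float(np.median(np.diff(measured.axis)))
    refined = [
        _refine_candidate(measured, sphere, wavelength_nm, p, meas_pos, w)
        for _, p, _ in distinct
    ]
    refined = [r for r in refined if np.isfinite(r[0])]
    if not refined:
        raise InitializationError("no refinable initializer candidate")
    return sorted(refined, key=lambda t: t[0])


def initialize_fit(measured: ScatteringCurve, sphere: SphereSpec,
                   wavelength_nm: float,
                   search_grid: tuple | None = None,
                   smoothing_halfwidth: int = 0) -> tuple[float, float, float]:
    """Initial (n, kappa, d) by extrema-position variance minimization.

    Deterministic: coarse grid search (``search_grid`` is (n values, kappa
    values, diameter fractions of nominal)) followed by local refinement
    of the leading candidates; returns the refined minimizer.
    """
    if smoothing_halfwidth:
        return initialize_candidates(measured, sphere, wavelength_nm,
                                     search_grid, smoothing_halfwidth)[0][1]
    return refined_candidates(measured, sphere, wavelength_nm, search_grid)[0][1]


def _run_lsq(model: _BinnedModel, measured_log: np.ndarray, p0, bounds,
             to_indices, max_nfev: int = 400) -> tuple:
    """Shared trust-region least-squares driver.

    ``to_indices(p)`` maps the parameter vector to (medium_m, sphere_m, d).
    """

    def fun(p):
        med, sph, d = to_indices(p)
        return _log_residual(model(med, sph, d), measured_log)

    scale = np.maximum(np.abs(np.asarray(p0, float)), 1e-4) * 1e-2
    res = least_squares(
        fun, np.asarray(p0, float), bounds=bounds, method="trf",
        jac="3-point", diff_step=[1e-6, 1e-2, 1e-6][: len(p0)],
        x_scale=scale, xtol=1e-12, ftol=1e-12, gtol=1e-14, max_nfev=max_nfev,
    )
    return res


def fit_cri(measured: ScatteringCurve, sphere: SphereSpec, wavelength_nm: float,
            init: tuple[float, float, float],
            bounds: tuple | None = None,
            n_extrema_matched: int | None = None,
            max_nfev: int = 400) -> FitResult:
    """Least-squares fit of medium (n, kappa) and sphere diameter.

    ``init`` comes from :func:`initialize_fit` or the caller.  Failure to
    converge is reported in the result, not raised.
    """
    (n_lo, n_hi), (k_lo, k_hi), (f_lo, f_hi) = bounds or DEFAULT_MEDIUM_BOUNDS
    d_nom = sphere.diameter_um
    lo = [n_lo, k_lo, f_lo * d_nom]
    hi = [n_hi, k_hi, f_hi * d_nom]
    p0 = np.clip(init, lo, hi)
    sphere_m = sphere.index_at(wavelength_nm).m
    model = _BinnedModel(measured, wavelength_nm)
    mlog = _measured_log(measured)

    def to_indices(p):
        return complex(p[0], p[1]), sphere_m, p[2]

    res = _run_lsq(model, mlog, p0, (lo, hi), to_indices, max_nfev=max_nfev)
    return FitResult(
        medium_index=ComplexIndex(float(res.x[0]), max(float(res.x[1]), 0.0)),
        diameter_um=float(res.x[2]),
        residual=float(res.cost),
        init_params=tuple(float(v) for v in init),
        converged=bool(res.success and np.isfinite(res.cost)),
        n_extrema_matched=n_extrema_matched,
        n_evaluations=int(res.nfev),
        message=str(res.message),
    )


def fit_sphere_cri(measured: ScatteringCurve, medium: ComplexIndex,
                   wavelength_nm: float, init: tuple[float, float, float],
                   bounds: tuple | None = None,
                   fix_diameter: float | None = None,
                   max_nfev: int = 400) -> FitResult:
    """Calibration-mode fit: medium known, sphere (n, kappa) [+ d] free.

    The returned ``medium_index`` field holds the *sphere* index (the
    quantity being fitted); ``diameter_um`` is the fitted or fixed value.
    """
    if bounds is None:
        bounds = ((init[0] - 0.03, init[0] + 0.03), (0.0, 1e-3), (0.95, 1.05))
    (n_lo, n_hi), (k_lo, k_hi), (f_lo, f_hi) = bounds
    model = _BinnedModel(measured, wavelength_nm)
    mlog = _measured_log(measured)
    if fix_diameter is None:
        d_nom = init[2]
        lo = [n_lo, k_lo, f_lo * d_nom]
        hi = [n_hi, k_hi, f_hi * d_nom]
        p0 = np.clip(init, lo, hi)

        def to_indices(p):
            return medium.m, complex(p[0], p[1]), p[2]
    else:
        lo = [n_lo, k_lo]
        hi = [n_hi, k_hi]
        p0 = np.clip(init[:2], lo, hi)

        def to_indices(p):
            return medium.m, complex(p[0], p[1]), fix_diameter

    res = _run_lsq(model, mlog, p0, (lo, hi), to_indices, max_nfev=max_nfev)
    d_out = float(res.x[2]) if fix_diameter is None else float(fix_diameter)
    return FitResult(
        medium_index=ComplexIndex(float(res.x[0]), max(float(res.x[1]), 0.0)),
        diameter_um=d_out,
        residual=float(res.cost),
        init_params=tuple(float(v) for v in init),
        converged=bool(res.success and np.isfinite(res.cost)),
        n_evaluations=int(res.nfev),
        message=str(res.message),
    )


def _fringe_phase(intensity: np.ndarray, window_bins: int) -> np.ndarray:
    """Unwrapped analytic phase of the fringe oscillation.

    Log-intensity is detrended by a moving average about 1.5 fringe
    periods wide (removing the envelope, which carries the kappa
    dependence), then the Hilbert-transform phase is unwrapped.  Because
    the phase accumulates over every fringe, comparing two curves' phase
    profiles counts fringes absolutely — there is no one-fringe aliasing.
    """
    from scipy.signal import hilbert

    y = np.log(np.asarray(intensity, float)
               + 1e-4 * float(np.max(intensity)))
    w = max(5, int(window_bins) | 1)
    pad = np.pad(y, w // 2, mode="edge")
    y = y - np.convolve(pad, np.ones(w) / w, mode="valid")
    return np.unwrap(np.angle(hilbert(y)))


def phase_align_init(measured: ScatteringCurve, sphere: SphereSpec,
                     wavelength_nm: float,
                     n_range: tuple[float, float] = (1.32, 1.36),
                     d_frac_range: tuple[float, float] = (0.98, 1.02),
                     kappa_max: float = 1e-3) -> tuple[float, float, float]:
    """Global (n, kappa, d) initializer by fringe-phase alignment.

    Minimizes the offset-free RMS difference between the measured and
    model unwrapped fringe phases over (n, d) — a smooth, alias-free
    landscape — then picks kappa by a 1D scan of the damped log-intensity
    residual at the aligned (n, d).
    """
    axis = np.asarray(measured.axis, float)
    sphere_m = sphere.index_at(wavelength_nm).m
    d_nom = sphere.diameter_um
    bin_w = measured.bin_width or float(np.median(np.diff(axis)))
    period = (wavelength_nm * 1e-3) / d_nom
    win = int(np.rint(1.5 * period / bin_w))
    pm = _fringe_phase(measured.intensity, win)

    def phase_rms(n, k, d):
        model = _model_point_intensity(axis, wavelength_nm,
                                       complex(n, k), sphere_m, d)
        diff = _fringe_phase(model, win) - pm
        return float(np.mean((diff - diff.mean()) ** 2))

    # host absorption shifts the fringe positions appreciably once
    # Im(x) ~ 0.1, so kappa cannot be held at a token value: pick it first
    # on a coarse (n, kappa, d) grid by the same phase objective
    k_grid = np.linspace(0.0, kappa_max, 6)
    coarse = [(n, f * d_nom)
              for n in np.linspace(*n_range, 11)
              for f in np.linspace(*d_frac_range, 5)]
    k_scan = k_grid[int(np.argmin([
        min(phase_rms(n, k, d) for n, d in coarse) for k in k_grid]))]

    # the model has a near-degenerate (n, d) valley along which fringe
    # alignment survives; the phase objective still separates the true
    # alignment from its one-fringe aliases by an order of magnitude, but
    # the scan must be fine enough (~1e-3 in n) to resolve the basin
    n_step = 1e-3
    d_step_frac = 2.5e-3
    seeds = [(n, f * d_nom)
             for n in np.arange(n_range[0], n_range[1] + n_step / 2, n_step)
             for f in np.arange(d_frac_range[0],
                                d_frac_range[1] + d_step_frac / 2, d_step_frac)]
    seed = min(seeds, key=lambda s: phase_rms(s[0], k_scan, s[1]))

    def phase_resid(p):
        model = _model_point_intensity(axis, wavelength_nm,
                                       complex(p[0], k_scan), sphere_m, p[1])
        diff = _fringe_phase(model, win) - pm
        return diff - diff.mean()

    sol = least_squares(
        phase_resid, seed,
        bounds=([n_range[0], d_frac_range[0] * d_nom],
                [n_range[1], d_frac_range[1] * d_nom]),
        diff_step=[1e-4, 1e-4], xtol=1e-12, ftol=1e-12, max_nfev=120,
    )
    n0, d0 = float(sol.x[0]), float(sol.x[1])

    meas_norm = measured.intensity / measured.intensity.max()
    mlog = np.log(meas_norm + 1e-4)
    best_k, best_r = 0.0, np.inf
    for k in np.linspace(0.0, kappa_max, 11):
        model = _model_point_intensity(axis, wavelength_nm,
                                       complex(n0, k), sphere_m, d0)
        r = float(np.mean((np.log(model / model.max() + 1e-4) - mlog) ** 2))
        if r < best_r:
            best_k, best_r = float(k), r
    return (n0, best_k, d0)


def _valley_sweep(measured: ScatteringCurve, sphere: SphereSpec,
                  wavelength_nm: float, best: FitResult,
                  bounds: tuple | None,
                  n_span: float = 7.5e-4, n_points: int = 11) -> FitResult:
    """Deterministic basin hop along the (n, d) degeneracy valley.

    The log-intensity objective has fringe-alias local minima spaced a few
    1e-4 apart in n along a narrow valley in which n and d trade against
    each other.  This sweeps the cost along the locally flattest direction
    (smallest right singular vector of the residual jacobian), restarts a
    short fit from the best off-basin local minima, and keeps the lowest
    final cost.
    """
    model = _BinnedModel(measured, wavelength_nm)
    mlog = _measured_log(measured)
    sphere_m = sphere.index_at(wavelength_nm).m
    p_star = np.array([best.medium_index.n, best.medium_index.kappa,
                       best.diameter_um])

    def resid(p):
        return _log_residual(model(complex(p[0], p[1]), sphere_m, p[2]), mlog)

    steps = np.array([1e-6, 1e-6, 1e-4])
    r0 = resid(p_star)
    jac = np.column_stack([
        (resid(p_star + np.eye(3)[i] * steps[i]) - r0) / steps[i]
        for i in range(3)
    ])
    # scale columns so the SVD sees comparable parameter sensitivities
    col_scale = np.array([1e-3, 1e-4, 1e-1])
    _, _, vt = np.linalg.svd(jac * col_scale, full_matrices=False)
    v = vt[-1] * col_scale
    if abs(v[0]) < 1e-12:
        return best
    v = v / abs(v[0])  # unit step in n
    (n_lo, n_hi), (k_lo, k_hi), (f_lo, f_hi) = bounds or DEFAULT_MEDIUM_BOUNDS
    d_nom = sphere.diameter_um
    lo = np.array([n_lo, k_lo, f_lo * d_nom])
    hi = np.array([n_hi, k_hi, f_hi * d_nom])
    # basins are narrower than the valley's curvature allows a straight ray
    # to track, so restart a short fit from regular offsets instead of
    # looking for ray-local minima
    offsets = np.linspace(-n_span, n_span, n_points)
    offsets = offsets[np.abs(offsets) > 1e-5]
    for s in offsets:
        p = np.clip(p_star + s * v, lo, hi)
        trial = fit_cri(measured, sphere, wavelength_nm, tuple(p), bounds,
                        n_extrema_matched=best.n_extrema_matched,
                        max_nfev=60)
        if trial.residual < best.residual:
            best = trial
    return best


def fit_curve(measured: ScatteringCurve, sphere: SphereSpec,
              wavelength_nm: float,
              search_grid: tuple | None = None,
              bounds: tuple | None = None,
              sweep_rms_threshold: float = 0.01,
              init: tuple[float, float, float] | None = None) -> FitResult:
    """Automatic initialization + least squares in one call.

    With ``init`` (e.g. a warm start from a neighbouring wavelength of the
    same sphere) a plain fit is tried first and accepted when its basin
    looks right.  Otherwise the primary initializer is
    :func:`phase_align_init`; when the fitted log-residual suggests the
    wrong fringe-alignment basin (rms above ``sweep_rms_threshold``), a
    deterministic sweep along the (n, d) degeneracy valley hops to
    neighbouring basins, and as a last resort short descents are started
    from a coarse grid over the search box.  The lowest final cost wins.
    """
    n_bins = measured.axis.size

    def basin_rms(f: FitResult) -> float:
        return float(np.sqrt(2.0 * f.residual / n_bins))

    best = None
    if init is not None:
        warm = fit_cri(measured, sphere, wavelength_nm, init, bounds)
        if basin_rms(warm) < sweep_rms_threshold:
            return warm
        swept = _valley_sweep(measured, sphere, wavelength_nm, warm, bounds)
        if basin_rms(swept) < sweep_rms_threshold:
            return swept
        best = swept if swept.residual < warm.residual else warm
    try:
        auto = phase_align_init(measured, sphere, wavelength_nm)
        trial = fit_cri(measured, sphere, wavelength_nm, auto, bounds)
        if best is None or trial.residual < best.residual:
            best = trial
        for _ in range(3):
            if basin_rms(best) < sweep_rms_threshold:
                break
            swept = _valley_sweep(measured, sphere, wavelength_nm, best, bounds)
            if swept.residual >= best.residual * 0.99:
                best = swept if swept.residual < best.residual else best
                break
            best = swept
        if basin_rms(best) < sweep_rms_threshold:
            return best
    except (InitializationError, DegenerateCurveError, InvalidArgumentError):
        pass

    # last resort: short descents from a coarse (n, d) grid of starts —
    # expensive but only reached when fringe alignment is still ambiguous
    n_grid, _, dfrac_grid = search_grid or DEFAULT_MEDIUM_GRID
    starts = [(n0, 2e-4, f0 * sphere.diameter_um)
              for n0 in np.linspace(n_grid.min(), n_grid.max(), 9)
              for f0 in np.linspace(dfrac_grid.min(), dfrac_grid.max(), 7)]
    trials = [fit_cri(measured, sphere, wavelength_nm, p, bounds, max_nfev=20)
              for p in starts]
    if best is not None:
        trials.append(best)
    for trial in sorted(trials, key=lambda f: f.residual)[:3]:
        polished = fit_cri(
            measured, sphere, wavelength_nm,
            (trial.medium_index.n, trial.medium_index.kappa, trial.diameter_um),
            bounds, n_extrema_matched=trial.n_extrema_matched)
        if best is None or polished.residual < best.residual:
            best = polished
    swept = _valley_sweep(measured, sphere, wavelength_nm, best, bounds)
    return swept if swept.residual < best.residual else best


@dataclass(frozen=True)
class CalibrationResult:
    """Calibrated probe sphere: shared diameter, per-wavelength CRI."""

    sphere: SphereSpec
    wavelengths_nm: np.ndarray
    indices: tuple[ComplexIndex, ...]
    per_wavelength_diameters: np.ndarray
    fits: tuple[FitResult, ...]
    diameter_spread_warning: bool


def calibrate_sphere(curves_in_water: dict[float, ScatteringCurve],
                     water_index: dict[float, ComplexIndex],
                     nominal: SphereSpec,
                     n_search: np.ndarray | None = None,
                     spread_tolerance: float = 0.01) -> CalibrationResult:
    """Water-immersion calibration of the probe sphere's CRI.

    Per wavelength the sphere (n, kappa) and diameter are fitted against
    the known water index; the diameter is then reconciled as the median
    across wavelengths and the per-wavelength sphere indices refit at the
    fixed diameter.  A cross-wavelength diameter spread beyond
    ``spread_tolerance`` raises a :class:`CalibrationWarning` and flags
    the result.
    """
    if set(curves_in_water) != set(water_index):
        raise InvalidArgumentError("curves and water indices must share wavelengths")
    wls = np.array(sorted(curves_in_water))
    nominal_n = nominal.index_at(float(wls[0])).n
    if n_search is None:
        n_search = np.linspace(nominal_n - 0.02, nominal_n + 0.02, 9)
    first_pass: list[FitResult] = []
    for wl in wls:
        curve = curves_in_water[float(wl)]
        med = water_index[float(wl)]
        w = curve.bin_width or float(np.median(np.diff(curve.axis)))
        meas_pos = find_extrema(curve)
        best = None
        for d_frac in np.linspace(0.98, 1.02, 9):
            d = nominal.diameter_um * d_frac
            for n_s in n_search:
                model = _model_point_intensity(curve.axis, float(wl), med.m,
                                               complex(n_s, 0.0), d)
                try:
                    theo_pos = find_extrema(
                        ScatteringCurve(axis=curve.axis, intensity=model))
                except DegenerateCurveError:
                    continue
                obj, n_match = extrema_objective(meas_pos, theo_pos, w)
                if n_match >= 3 and (best is None or obj < best[0]):
                    best = (obj, n_s, d)
        if best is None:
            raise InitializationError(f"calibration init failed at {wl} nm")
        # fringe-alias basins are a few 1e-4 wide in n (and ~0.1% in d):
        # descend from a fine fan of starts around the coarse optimum and
        # keep the best basin
        trials = [
            fit_sphere_cri(curve, med, float(wl),
                           (best[1] + dn, 1e-6, best[2] * (1.0 + dd)),
                           max_nfev=60)
            for dn in np.linspace(-2.1e-3, 2.1e-3, 7)
            for dd in np.linspace(-3e-3, 3e-3, 5)
        ]
        lead = min(trials, key=lambda f: f.residual)
        first_pass.append(
            fit_sphere_cri(curve, med, float(wl),
                           (lead.medium_index.n, lead.medium_index.kappa,
                            lead.diameter_um))
        )
    diameters = np.array([f.diameter_um for f in first_pass])
    d_med = float(np.median(diameters))
    spread = float(diameters.max() - diameters.min()) / d_med
    warn = spread > spread_tolerance
    if warn:
        warnings.warn(
            f"cross-wavelength diameter spread {spread:.2%} exceeds "
            f"{spread_tolerance:.0%}", CalibrationWarning, stacklevel=2)
    second_pass = tuple(
        fit_sphere_cri(curves_in_water[float(wl)], water_index[float(wl)],
                       float(wl), (f.medium_index.n, f.medium_index.kappa, d_med),
                       fix_diameter=d_med)
        for wl, f in zip(wls, first_pass)
    )
    indices = tuple(f.medium_index for f in second_pass)
    sphere = SphereSpec(d_med, TabulatedIndex(wls, list(indices)))
    return CalibrationResult(
        sphere=sphere,
        wavelengths_nm=wls,
        indices=indices,
        per_wavelength_diameters=diameters,
        fits=second_pass,
        diameter_spread_warning=warn,
    )


def spectrum_from_fits(fits_per_wavelength: dict[float, list[FitResult]]
                       ) -> CRISpectrum:
    """Replicate aggregation: mean index and replicate sd per wavelength."""
    wls = np.array(sorted(fits_per_wavelength))
    indices, sd_n, sd_k = [], [], []
    for wl in wls:
        ns = np.array([f.medium_index.n for f in fits_per_wavelength[float(wl)]])
        ks = np.array([f.medium_index.kappa for f in fits_per_wavelength[float(wl)]])
        indices.append(ComplexIndex(float(ns.mean()), max(float(ks.mean()), 0.0)))
        sd_n.append(float(np.std(ns, ddof=1)) if ns.size > 1 else 0.0)
        sd_k.append(float(np.std(ks, ddof=1)) if ks.size > 1 else 0.0)
    return CRISpectrum(wls, tuple(indices), np.array(sd_n), np.array(sd_k))
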