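# Methods

holocri measures the complex refractive index (CRI) `n + i·kappa` of an
absorbing solution by immersing a microsphere of known size in it,
imaging the sphere holographically, converting the retrieved complex
field to an angle-resolved light-scattering curve, and inverting that
curve with Mie theory.  A spectral layer turns per-wavelength indices of
a photoswitchable chromoprotein solution (pump on / pump off) into
concentrations, refractive-index increments, photocycle kinetics and a
Kramers–Kronig consistency check.  This note records the model
assumptions, the numerical choices, and what the synthetic data do and
do not establish.

## Conventions

Time dependence `exp(-i·omega·t)`, so absorption is a positive imaginary
index and the outgoing Riccati–Hankel function is `xi_n = psi_n - i·chi_n`.
Lengths at the sample plane are in micrometres, vacuum wavelengths in
nanometres, spatial frequencies in cycles/um.  The scattering-angle
coordinate is `n·sin(theta) = lambda_vac · f_transverse`; because the
right-hand side involves only measured quantities, the axis of a measured
curve does not move while the fitted medium index changes — the fit
adjusts the model, never the data axis.

## Mie forward model

Expansion coefficients follow the standard logarithmic-derivative
formulation: `D_n(mx)` by downward recurrence seeded with a modified-Lentz
continued fraction 15 orders above the Wiscombe truncation
`ceil(|x| + 4.05|x|^(1/3) + 2)`; the host Riccati–Bessel `chi_n(x)` by
upward recurrence (dominant solution) and `psi_n(x)` by downward
recurrence normalised at the origin, so the decaying tail beyond the
turning point keeps full relative accuracy.  Both the relative index
`m = m_sphere/m_medium` and the size parameter
`x = 2·pi·m_medium·r/lambda` may be complex.  Host absorption enters only
through the complex `x` and the Beer–Lambert attenuation of the incident
beam; the far-field intensity is formed from `|S|^2` without host-path
attenuation.  For the regime in scope (`kappa_medium ≲ 5e-3`,
`|Im x| ≲ 0.3`) the distinction between "inherent" and "apparent"
absorbing-host formulations is below 1e-6 relative and is ignored — an
approximation of this package, documented, not asserted of anyone else's.
Double precision is validated against an arbitrary-precision oracle to
`|x| = 1500`; beyond that a capability error is raised.

Unpolarized detection is modelled as `(|S1|^2 + |S2|^2)/2`, which equals
the azimuthal mean of the co-polarised intensity up to terms of order
`|S1 - S2|^2` (≈ 1e-5 relative at NA 0.25).

## Synthetic data

No raw measurements of this kind are publicly deposited, so the study
conditions are emulated end to end:

* **Scenario.**  Eleven probe wavelengths spanning 461–582 nm, two
  photostationary states: pump off (`rho_pG = 3.44 mM`, no signalling
  state) and pump on (`rho_pG = 0.56 mM`, `rho_pB = 2.88 mM`).  The
  ground-state chromophore band is a single Lorentz oscillator
  parameterised by its observables (peak 446 nm, peak molar extinction
  45 000 M⁻¹cm⁻¹, FWHM 30 nm — the latter two chosen as plausible
  synthetic values for a blue-absorbing chromoprotein).  A Lorentzian
  rather than a Gaussian band is the default because its real part is the
  exact Kramers–Kronig conjugate of its absorption: the scenario's
  refractive-index increment then carries the physically required
  anomalous dispersion, and pump-on/off index differences have a
  wavelength shape for the K–K consistency check to test.  A Gaussian
  band remains available (extinction only, no dispersive increment).
* **Increments.**  Non-resonant (background) increments default to
  3.4 M⁻¹ for both states; the pG state adds the band's resonant term
  (+0.19 M⁻¹ at 461 nm).  With the water baseline (Quan & Fry dispersion,
  20 °C) these defaults reproduce a pump-off solution index of ≈ 1.352 at
  461 nm falling to ≈ 1.345 at 582 nm, the range the method is designed
  to resolve.  Protein in the 14-kDa class at dn/dc ≈ 0.19 mL/g would
  give ≈ 2.7 M⁻¹; the slightly larger default keeps the solution-index
  range stated above.
* **Imaging geometry.**  4096-px grid at 0.2 um pitch (819 um field of
  view), collection NA 0.25, fringe carrier at (1/4, 1/4) of the sampling
  frequency, reference amplitude 1.  These numbers are chosen jointly so
  that (a) the frequency resolution `lambda/FOV` samples the ~`lambda/d`
  Mie fringe spacing of a 100-um sphere about eight times per period,
  (b) the object band (radius NA/lambda ≤ 0.54 cyc/um) clears both the
  DC self-interference band (twice the band radius) and the Nyquist
  boundary with margin, and (c) the sideband crop can use a mask radius
  larger than the full object band.  The sphere is centred in the field
  of view; the field synthesis populates the angular spectrum inside the
  NA cone from the Mie amplitudes (co-polarised `S2·cos²phi + S1·sin²phi`
  with the stationary-phase `1/cos(theta)` obliquity) plus a DC delta for
  the incident wave attenuated by `exp(-2·pi·kappa·t/lambda)` over a
  configurable path length (default: one sphere diameter; the real
  chamber thickness is not specified by the measurement design, and the
  curve normalisation removes the global attenuation factor anyway).
* **Noise.**  Additive circular complex Gaussian noise on the field,
  default sd 0.5% of the background amplitude, applied to sample and
  background fields independently before hologram formation.  This is a
  minimal detector/shot-noise stand-in; real instruments add correlated
  errors (probe-bandwidth decoherence, speckle, vibration, camera
  quantisation) that are *not* modelled, which is why the synthetic
  precision figures come out far better than any real instrument's and
  are read only as "the inversion itself does not limit precision".

## Field retrieval

Fourier sideband demodulation: the hologram term `U·R*·exp(-i2·pi·c·r)`
places the object spectrum at the negated carrier, which is cropped with
a raised-cosine circular mask (edge 8 frequency pixels; radius half the
smaller of the carrier distance to DC and to the Nyquist boundary),
recentred by an integer-pixel roll, and inverse transformed.  Dividing
sample by background cancels the reference wave, the residual sub-pixel
carrier ramp, and any smooth illumination profile common to both.
Carrier detection finds the strongest non-DC peak (3× median magnitude
required) and refines it with Jacobsen's three-bin estimator, exact for
an unwindowed tone.  No window is applied before the transform: with the
default carrier the periodic-boundary artifacts stay outside the
sideband.  Phase is reported wrapped; a quality-guided unwrapping helper
exists but FTLS consumes the complex field, which needs none.

## FTLS

The far field is a centred FFT; pixel frequencies map to
`n·sin(theta) = lambda·f`; pixels outside the NA are dropped; `|A|^2` is
multiplied by `cos²(theta)` (the angular-spectrum-to-radiant-intensity
obliquity, a smooth ≤ 3.5% correction at NA 0.25) and averaged over 400
uniform bins in `[0, NA]` (mean, not median — the azimuthal sample is
homogeneous by symmetry).  Each reported bin carries the mean axis value
of its pixels and, importantly, the full list of contributing pixel
radii, so that a fit can push model curves through the *identical*
binning operator.  The unscattered component is excluded by dropping
bins below three bin widths (the uniform background contributes exactly
one DC pixel; the margin guards leakage).  Empty bins are dropped.

## Inverse fit

Three parameters: medium `n`, medium `kappa`, sphere diameter `d`
(bounds 1.30–1.40, 0–5e-3, nominal ±5%).  The objective is least squares
on `log(I + eps0)` of max-normalised intensities, with `eps0 = 1e-4` of
the curve maximum: the log weights fringe positions over peak heights
across the several decades the curve spans, and the floor removes the
pathological sensitivity of near-empty fringe minima.  The model curve is
bin-averaged exactly as the data (spline evaluation at the recorded pixel
radii, means per bin); without this the ~2.5% contrast loss that binning
inflicts on the measured fringes biases the recovered `kappa` by ~1e-5.

The curve is invariant under intensity scaling (both sides are
max-normalised each iteration), and `d` and `n` are nearly degenerate:
fringe alignment survives along a narrow valley in which the two trade
against each other, with local minima ("fringe-order aliases") spaced a
few 1e-4 apart in `n`.  Initialization therefore proceeds in stages:

1. *Fringe-phase alignment* — the Hilbert-transform phase of the
   envelope-detrended log curve is unwrapped over all fringes and matched
   against model phases on a fine `(n, d)` grid, then polished by local
   least squares.  Counting fringes absolutely removes one-fringe
   aliasing; `kappa` (an envelope property) follows from a 1D scan.
2. *Valley sweep* — if the fitted log-residual rms still exceeds 1%
   (study-scale noise-free fits reach ~0.01–0.2%), short fits are
   restarted from regular offsets along the locally flattest jacobian
   direction, hopping across neighbouring alias basins deterministically.
3. *Grid fallback* — as a last resort, short descents from a coarse
   `(n, d)` grid across the whole search box.

The classical extrema-position initializer (grid search minimising the
summed squared differences between greedily matched measured and model
extrema, one bin-width² penalty per unmatched extremum) is implemented
and exposed (`initialize_fit`, `find_extrema`, `extrema_objective`); on
its own it resolves the valley only when the search grid is finer than
the alias spacing, so the automated pipeline prefers the phase-alignment
route.  The extrema objective remains useful as a cheap, derivative-free
diagnostic and reproduces the documented behaviours (self-consistency at
a grid point, truth below neighbouring probes).

Host absorption shifts the fringe positions appreciably once
`Im(x) ≳ 0.1`, so the phase-alignment stage selects `kappa` on a coarse
grid before the fine `(n, d)` scan rather than holding it at a token
value.  Multi-wavelength pipeline runs additionally warm-start every cell
from its neighbouring wavelength — the physical sphere is the same and
the medium index drifts mainly with the water baseline — which lands
directly in the right basin and reserves the global machinery for the
first cell of each pump state.

Replicate aggregation: per-wavelength mean and sd (ddof = 1) across
independent replicates.

## Calibration

The probe sphere's own CRI is calibrated by the same procedure with the
sphere immersed in distilled water (known index): per wavelength the
sphere `(n, kappa)` and diameter are fitted with the medium fixed
(a fine fan of starts around the coarse optimum handles the alias
basins), the diameter is reconciled as the median across wavelengths
(spread > 1% raises a warning), and the per-wavelength indices are refit
at the fixed diameter.  The result is a tabulated per-wavelength sphere
index with linear interpolation.

## Spectral analysis

* Concentration from the imaginary index inverts
  `kappa = ln(10)/(4·pi)·rho·lambda·eps(lambda)`; across a spectrum the
  estimate is the closed-form weighted projection (linear in `rho`), so
  strongly absorbing wavelengths dominate automatically.
* `R_pB = (rho_off - rho_on)/rho_off` — the pB fraction of the *total*
  protein pool.  First-order uncertainty propagation throughout.
* Increments solve the per-wavelength 2×2 linear system against the
  water baseline exactly (the pump-off row is triangular: no pB present).
* The relaxation time inverts the two-state photostationary balance
  `1/tau = ln10·((1-R)/R)·(phi/(N_A·h·c))·∫ eps·lambda·(dI/dlambda) dlambda`
  with a trapezoidal integral in SI units; CODATA values of `h`, `N_A`,
  `c` are module constants.  The default synthetic pump is a 445-nm,
  18-nm-FWHM LED at 5000 W/m² integrated irradiance (a typical focused
  LED figure, ~0.5 W/cm²), which together with `R_pB = 0.837` and
  `phi = 0.35` yields a relaxation time in the tens of milliseconds.
* The Kramers–Kronig transform uses Maclaurin's alternating-point method
  for the principal value on a uniform angular-frequency grid.  A finite
  measurement band cannot fix the absolute level — neighbouring UV and
  infrared absorption would be required — so the output is explicitly a
  *trend*, offset-ambiguous, with an anchoring helper; the package never
  reports absolute real indices from the transform.  The pipeline's
  consistency check transforms the band-model kappa difference between
  pump states (evaluated on a grid extending 40 nm past the measurement
  band) and compares its *shape* with the measured real-index difference
  by Pearson correlation.
* Water baseline: Quan & Fry empirical dispersion (salinity 0), valid
  400–700 nm, temperature default 20 °C.  PMMA default: three-term
  Sellmeier fit, with a nominal residual extinction 1e-5 that the
  calibration refits.

## Problem sizes used by tests and the acceptance script

The acceptance checks run the study geometry itself: a 100-um sphere on
the 4096-px grid at 500 nm (size parameter ≈ 850), noise-free recovery
plus 30 noisy replicates, and the numerical oracles at
`x ∈ {0.1, 1, 10, 100, 850}`.  Unit tests run the same code paths on
12–50-um spheres and 256–2048-px grids, sizes chosen so the whole suite
exercises every stage in a few minutes; the scenario closure inside the
acceptance script uses a six-wavelength, 50-um, 2048-px reduction, whose
per-cell fit errors (~1e-7 noise-free) are negligible against the
spectral quantities being closed.

## Known limitations

* The (n, d) valley means global convergence ultimately rests on
  deterministic multi-start heuristics; pathological curves with very few
  fringes (small spheres, narrow NA) can still land one alias off, which
  shows up as a large log-residual rather than silently.
* The solution layer is treated as homogeneous; the thickness gradient a
  real chamber shows away from the sphere centre is not modelled, and no
  correction for it is applied.
* Probe-beam bandwidth (fringe-contrast loss at long wavelengths),
  vectorial high-NA effects and camera quantisation are not modelled;
  synthetic precision figures are therefore optimistic bounds of the
  inversion alone, not instrument forecasts.
* The photocycle is collapsed to two states; short-lived intermediates
  are absorbed into the long-lived signalling state.
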