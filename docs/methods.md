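# Methods

This note records the models implemented in `xtalkin`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Primary nucleation from censored induction times

Isothermal induction times in small agitated vials are modelled by the
single-nucleus mechanism: primary nucleation in a vial of volume *V* is a
Poisson process with rate *J·V* (*J* in nuclei mL⁻¹ min⁻¹), so the waiting
time to the first nucleus is exponential. The event is detected only after
the nucleus has grown large enough to trigger measurable secondary
nucleation, which adds a deterministic growth-time offset *t_g*. The
cumulative probability of recording an induction time at or before *t* is

    P(t) = 1 − exp(−J·V·(t − t_g)),   t > t_g;   P(t) = 0 otherwise.

The empirical distribution is estimated as *M⁺(t)/M*, where *M* counts all
vials including those that never nucleate within the hold (censored at
240 min by default, the standard 4 h isothermal hold) and *M⁺(t)* counts
vials nucleated by *t*. Censoring therefore enters only through the
denominator. The model is fitted to the empirical steps by
Levenberg–Marquardt least squares (via `lmfit`) with both parameters
bounded below by zero and *t_g* bounded above by the minimum observed
induction time (MIT), which the offset cannot exceed.

Numerical choices:

- **Initialization.** *t_g⁰* = MIT. *J⁰* is the geometric mean of two
  scale readings: the 63% crossing of the empirical distribution (the 1/e
  point of the exponential, where *J·V·(t − t_g) = 1*) and the
  log-transform of the final step clipped to 1 − 1/(2M). The clip matters:
  when every vial nucleates the final step sits at exactly 1 and the raw
  log diverges.
- **Multi-start.** The objective has a flat spurious corner (*J* large,
  *t_g* at the MIT, model ≈ 1 everywhere) in which LM can stall while
  reporting convergence. The fit therefore always runs a handful of
  deterministic and jittered starts and keeps the solution with the
  lowest residual norm.
- **Ties** in induction times are merged into one step; CDF points are
  weighted equally (no weighting scheme is implied by the estimator).
- **Standard errors** come from the Jacobian at the optimum. Because
  adjacent CDF steps are strongly correlated, these understate the true
  sampling variability at modest *M*; the replicate simulations in the
  test suite quantify the honest scatter (roughly ±25% on *J* at
  *M* = 100, a factor of ~2 at *M* = 25).
- A censored-exponential maximum-likelihood estimate of *J* at fixed
  *t_g* is provided as an independent cross-check; the least-squares CDF
  fit is the reference path.

At least 5 nucleated vials (configurable) are required before a fit is
attempted.

## Secondary nucleation and growth from seeded experiments

A single large seed (nominally 2.5 mm, far above the imaging range) added
to a supersaturated solution produces a burst of secondary nuclei after a
delay. Two instrument streams are analysed:

- **Count traces.** The particle count per image is converted to a number
  density through a linear calibration factor (default 100 particles mL⁻¹
  per count/image; the factor is configurable and estimator and simulator
  always share it, so all tests are calibration-consistent). The secondary
  nucleation rate *B* is the OLS slope of density against time inside the
  imaging validity window — from the first frame with count ≥ 10 (below
  which counts are background-dominated) to the last frame with count
  ≤ 160 before saturation (above ~160 particles overlap in the image). A
  negative fitted slope is reported with a quality flag rather than
  clipped. The delay time is the first threshold crossing (threshold = the
  window floor, 10 counts) measured from seed addition at *t* = 0; for
  unseeded vials the same estimators run with *t* = 0 at the induction
  time.
- **PSD series.** Number-weighted histograms over 99 linear bins spanning
  3–300 μm. Per frame, the volume-weighted d90 is computed with bin
  midpoints as size representatives and count·midpoint³ as volume weights
  (any shape factor cancels in the fraction), interpolating the cumulative
  volume fraction to 0.90 inside the containing bin. Frames with fewer
  than 10 particles are skipped. The growth rate *G* is the OLS slope of
  d90 against time within the count window; d90 tracks the largest
  (oldest) crystals and is insensitive to ongoing nucleation.

Known estimator property: when the validity window is short (high *B*,
high *S*), the d90 trajectory crosses only two or three 3-μm bins and the
sub-3-μm part of the population is invisible, which biases the fitted *G*
low by up to ~15% at the highest supersaturations and compresses the
fitted growth exponent by several percent. This is a property of the
measurement geometry, not of the fitting code, and is visible in the
noise-free end-to-end test.

## Power-law kinetics and solubility

Growth, secondary-nucleation and primary-nucleation rates are summarised
as rate = *k*·(S − 1)ⁿ, fitted by OLS of ln(rate) on ln(S − 1) — the
reproducible reading of exponents taken from log-log plots. Inversion is
closed-form: S = 1 + (rate/*k*)^(1/n). Supersaturation is S = C/C_s on a
mass-per-solvent-mass basis (mg per g of water), with C_s = 249.52 mg/g
as the default 25 °C reference for α-glycine in water.

Equilibrium solubility temperatures are obtained by extrapolating clear
points measured at ≥2 heating rates to zero heating rate (dissolution is
kinetically limited), and solubility data are summarised by a van't Hoff
model ln C = a − b/T(K) fitted by OLS in log space on the mass basis —
only relative trends are used, so the composition basis does not affect
any downstream quantity. Temperatures are kelvin internally, °C at every
interface.

## Mechanism syntheses

- **Minimum size to initiate secondary nucleation (L_sn).** Under the
  single-nucleus mechanism the induction offset is the time for one
  nucleus to grow to L_sn, so offset = L_sn/G(S). Offsets (both the MIT
  and the fitted *t_g*, reported separately — neither is canonical) are
  plotted against 1/G(S) from the fitted growth power law (not per-vial
  estimates), and L_sn is the slope of a least-squares line through the
  origin, Σxy/Σx². The MIT-based estimate is biased high by the smallest
  waiting time (≈ 1/(M·J·V)) but is markedly more stable at modest M than
  the t_g-based one, which absorbs CDF shape error.
- **Seeded delay line.** Mean delay per supersaturation against 1/G(S),
  ordinary OLS with free intercept: the intercept is the minimum delay
  for secondary nucleation to start in the fast-growth limit and the
  slope is the size a new nucleus must reach to be detected. The
  qualitative correction of L_sn for the detectable size is reported
  alongside, not applied.
- **Behavior table.** Aligns J·V (per vial), B (per single seed per vial
  volume) and G on shared supersaturations to expose their relative
  magnitudes.

## MSMPR design relations

For a steady-state mixed-suspension mixed-product-removal crystallizer
with size-independent growth and cubic crystals (volume shape factor
k_v = 1, exposed as a constant), the population density is
n(L) = n₀·exp(−L/Gτ), giving the closures d43 = 4Gτ, φ = 6·k_v·n₀·(Gτ)⁴
and B = n₀·G. The design map G = d43/(4τ), B = φG/(6·k_v·(Gτ)⁴) and its
inverse are computed in SI internally and reported in μm/min and
particles/(mL·min); the moment closures are verified against numerical
quadrature of the population density in the test suite, and the
forward/inverse pair round-trips to 1e-9 over wide parameter sweeps. The
reference design point (φ = 0.1, d43 = 10⁻⁴ m, τ = 1000 s → B =
6.4×10⁴ /(mL·min), G = 1.5 μm/min) is reproduced to machine precision.
The MSMPR *B* is per suspension volume and is labelled separately from
the per-seed experimental *B* when the two are compared at the operating
supersaturation.

## Synthetic data generator

The simulator emulates the three instrument streams with the statistical
structure the estimators assume:

- induction times: exponential waiting time at rate J·V plus the offset
  t_g, censored at the hold time;
- seeded counts: zero before the delay, then expected density
  B·(t − delay) converted to counts through the calibration factor, with
  optional Poisson sampling per frame (deterministic mode gives the exact
  expectation, so traces are non-integer but exactly linear);
- PSD series: nuclei born at rate B·V after the delay at 1 μm (below the
  3 μm detection floor; the true birth size is unobservable and is a
  config knob), all growing at a single prevailing G, histogrammed per
  frame into the 99 instrument bins with sizes outside 3–300 μm invisible.

Default magnitudes follow the glycine/water study conditions: 3 mL vials,
4 h hold, J ~ 10⁻³–10⁻² nuclei/(mL·min), t_g tens of minutes, B ~
10³–10⁴ /(mL·min) with a ~5 min delay, G ~ 10 μm/min, calibration factor
100. The workflow-suite generator derives J, B, G at each supersaturation
from supplied power laws (defaults k_G = 3000 μm/min, g = 2.86; k_B =
2×10⁷ /(mL·min), b = 3.5; k_J = 2.5 /(mL·min), n = 3 — chosen to
reproduce the order of magnitude of the measured rates across S =
1.04–1.20) and can impose a fixed minimum size L by setting
t_g = L/G(S). It adapts the frame interval so the 10→160 count window is
resolved by at least a dozen frames (at the highest rates the window
spans well under a minute, mirroring the instrument's seconds-scale
imaging) and ends traces shortly after count saturation, which also keeps
the tracked particle population at the tens-of-thousands scale.

Not emulated, hence not demonstrated by passing tests: growth-rate
dispersion between individual crystals (a single prevailing G is used, as
in the analysis), solute depletion (concentration change is <1% over the
measurement window in the emulated regime), seed-size dependence of B,
agitation hydrodynamics, optical artefacts of the imaging, and any
non-exponential induction statistics (e.g. multiple nucleation events per
vial).

## Problem sizes used in the test suite

Replicate recovery runs use 200 ensembles of M = 25 vials at the extreme
measured (J, t_g) pairs plus one M = 10⁵ ensemble; slope-estimator checks
use 200 noisy traces; the d90 oracle comparison uses 100 random PSDs; the
MSMPR round-trip sweep uses 1000 random designs; the end-to-end runs use
6 supersaturations × (25 or 200) vials × 3 seeded traces. The full suite
completes in well under a minute on one CPU.

## Known limitations

- Standard errors of the induction fit understate sampling variability at
  modest M (correlated CDF steps); use replicates for honest intervals.
- The d90-slope growth estimator is biased low where the validity window
  is short relative to the 3-μm bin width (highest supersaturations).
- The window-selection rule conditions on noisy counts, which biases the
  mean fitted B low by ~2% at coarse framing; the bias shrinks with frame
  rate.
- The linear calibration from counts to density is an assumption; a
  nonlinear instrument calibration would require replacing
  `counts_to_density`.
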