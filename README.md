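# xtalkin

Rapid assessment of crystallization kinetics from small-vial experiments:
primary and secondary nucleation rates, crystal growth rates, mechanistic
sizes and delays, and steady-state MSMPR design relations — with a
Monte-Carlo simulator of the instrument data so the whole pipeline is
testable end to end.

The package is aimed at crystallization process development: given a few
3 mL vial experiments (unseeded induction-time series plus single-crystal
seeded runs monitored by in-situ imaging), it quantifies the kinetics
needed to choose operating conditions for batch or continuous (MSMPR)
crystallizers.

## Models

**Primary nucleation.** Induction times of a stochastically nucleating
vial of volume *V* follow an exponential distribution with a growth-time
offset:

    P(t) = 1 − exp(−J·V·(t − t_g)),  t > t_g

*J* (nuclei mL⁻¹ min⁻¹) and *t_g* (min) are fitted by Levenberg–Marquardt
least squares to the empirical distribution M⁺(t)/M, where censored vials
(no nucleation within the 4 h hold) count only in the denominator *M*.

**Secondary nucleation and growth.** In seeded runs, the particle count
per image is converted to a number density via a calibration factor, and
*B* (particles mL⁻¹ min⁻¹) is the slope of density vs time inside the
imaging validity window (counts 10→160). *G* (μm/min) is the slope of the
volume-weighted d90 of the 99-bin (3–300 μm) size distribution vs time in
the same window.

**Power-law kinetics.** Both rates and *J* follow rate = k·(S−1)ⁿ, fitted
in log-log space; S = C/C_s is the supersaturation ratio.

**Mechanism.** Plotting induction offsets (minimum induction time or
fitted t_g) against 1/G(S) and fitting through the origin gives the
minimum crystal size L_sn required to initiate detectable secondary
nucleation; the seeded delay vs 1/G(S) line gives the minimum initiation
delay (intercept) and detectable crystal size (slope).

**MSMPR design.** For cubic crystals at steady state, n(L) =
n₀·exp(−L/Gτ) closes to d43 = 4Gτ and φ = 6n₀(Gτ)⁴ with B = n₀G, so a
target (φ, d43, τ) maps to required (B, G) and back.

## Worked example

Required kinetics for a single-stage MSMPR making a 100 μm (d43) product
at 10 vol% solids with a ~17 min residence time:

```
$ xtalkin msmpr --phi 0.1 --d43-um 100 --tau-s 1000
{
  "B_per_mL_min": 64000.00000000001,
  "G_um_per_min": 1.5000000000000002,
  "n0_per_m4": 4.266666666666667e+16
}
```

The design needs a nucleation rate of 6.4×10⁴ particles per mL per minute
and a growth rate of 1.5 μm/min; inverting a fitted growth power law at
that G tells you the supersaturation the crystallizer must hold.

Fitting a censored induction-time ensemble (here simulated, 100 vials at
J = 1.3×10⁻³ nuclei/(mL·min), t_g = 37 min, 4 h hold):

```python
from xtalkin import simulate, induction

cfg = simulate.SimulationConfig(J_true=1.3e-3, V=3.0, t_g_true=37.0,
                                censor_time=240.0, seed=2)
ds = simulate.simulate_induction_times(cfg, 100)
fit = induction.fit_induction_model(ds)
print(f"nucleated {fit.n_nucleated}/{fit.M} vials")
print(f"J   = {fit.J:.2e} +/- {fit.J_stderr:.1e} nuclei/(mL min)")
print(f"t_g = {fit.t_g:.1f} min   MIT = {induction.minimum_induction_time(ds):.1f} min")
```

prints

```
nucleated 58/100 vials
J   = 1.52e-03 +/- 2.2e-05 nuclei/(mL min)
t_g = 33.3 min   MIT = 38.3 min
```

i.e. the rate is recovered to ~17% and the offset to ~10% from a single
100-vial ensemble — representative of the statistical scatter at this
scale (the reported standard error understates it; see
`docs/methods.md`).

The full pipeline (`xtalkin simulate` → `xtalkin report`, or
`xtalkin.io.run_pipeline` from Python) chains solubility extrapolation,
induction fitting, seeded rate estimation, power-law fits, the mechanism
syntheses and MSMPR guidance into one JSON report.

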