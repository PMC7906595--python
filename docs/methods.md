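# Methods

## Model

`fermkin` models a closed (batch) yeast culture with four state variables:
biomass `X`, glucose `S`, ethanol `P`, and a lumped byproduct pool `Z`
(glycerol + acetic acid + succinic acid), all in g/L.  Specific growth
follows Monod kinetics in `S` multiplied by an inhibition factor in `Z`:

```
mu(S, Z) = mu_max0 · S/(K_s + S) · f(Z)
dX/dt = mu X,   dS/dt = −mu X / Y_xs,   dP/dt = −Y_ps dS/dt,   dZ/dt = −Y_zs dS/dt
```

Assumptions baked into this form:

* **Constant yields.** Biomass, ethanol and byproducts are formed in fixed
  stoichiometric proportion to sugar consumed (`Y_xs`, `Y_ps`, `Y_zs`
  g/g).  There is no maintenance term and no endogenous decay, so the
  linear mass-balance relations `X − X0 = Y_xs (S0 − S)` etc. hold exactly
  along every trajectory and pin the endpoints of a complete batch
  regardless of the kinetics.
* **Lumped inhibition.** The byproduct pool acts as a single inhibitor;
  per-component kinetics are out of scope.  `Z` only scales the maximum
  growth rate — the half-velocity constant is experimentally insensitive
  to byproduct level (observed band 11.4–11.7 g/L), so `K_s` is not a
  function of `Z`.
* **Fixed environment.** Temperature, pH and aeration switching are not
  modelled; units are fixed package-wide (h, g/L, h⁻¹).

### Inhibition families

`f` must satisfy `f(0) = 1` (no byproduct, no inhibition) and `f(Z) = 0`
for `Z ≥ Z_m` (growth stops at the critical concentration; `f` is clamped,
never negative).  Three families are registered:

| family      | f(Z)              | free parameters        |
|-------------|-------------------|------------------------|
| linear      | 1 − Z/Z_m         | mu_max0, Z_m           |
| parabolic   | 1 − (Z/Z_m)²      | mu_max0, Z_m           |
| exponential | (1 − Z/Z_m)^K_z   | mu_max0, Z_m, K_z      |

The "exponential" family is the Luong-type power law: among the forms
bearing that name in the inhibition-kinetics literature it is the one that
satisfies **both** limit conditions with a finite `Z_m` (a true
`e^(−K_z Z)` law never reaches zero), and it admits the calibrated
exponent `K_z = 0.83`.  It nests the linear law at `K_z = 1`, which is why
family selection needs an explicit tie-break (below).  The registry is
extensible (`register_family`) so alternative readings can be added
without touching the solver.

### Calibrated defaults

`mu_max0 = 0.244 h⁻¹`, `K_s = 11.5 g/L` (midpoint of the 11.4–11.7
stability band), `Z_m = 60 g/L`, `K_z = 0.83`; yields `Y_xs = 0.28`,
`Y_ps = 0.42`, `Y_zs = 0.0442 g/g` (averages over six initial-sugar levels
spanning 25–250 g/L).  Default initial condition `X0 = 1 g/L` (standard
inoculum), `P0 = Z0 = 0`; `Z0 > 0` is supported for spiked-byproduct
experiments.  The byproduct pool splits 56/36/8% into
glycerol/acetic/succinic by mass.

## Numerics

* **Integrator.** Classical fixed-step RK4, reference step `dt = 0.01 h`.
  A fixed step keeps every run bit-reproducible from its configuration; at
  these growth rates (`mu ≤ 0.244 h⁻¹`) the local error scale
  `(mu·dt)⁵` is ~10⁻¹³ per step, far below measurement noise.  Grid
  refinement shows clean 4th-order convergence, and trajectories agree
  with an independent adaptive integrator (`scipy.integrate.solve_ivp` at
  `rtol = 1e-10`) to ~10⁻⁷ relative.
* **Substrate exhaustion.** The right-hand side freezes the system at
  `S ≤ 0` (and with no inoculum).  When a step overshoots S below zero the
  state is projected back along the stoichiometric ray (X, P, Z corrected
  by yield × overshoot, S set to 0) — the only clamping rule that
  preserves the mass-balance relations exactly; conservation error along a
  full batch is ≤ 10⁻¹³·S0 in practice (tolerance asserted: 10⁻⁶·S0).
* **Fermentation time** is the time for S to fall to 1% of S0 (threshold
  configurable), linearly interpolated between bracketing grid points; a
  run that never reaches it yields NaN, which propagates through the
  model-vs-model delay arithmetic.
* **Inhibition fitting** is bounded nonlinear least squares
  (`scipy.optimize.least_squares`, trust-region reflective) on
  `mu_max0·f(Z)`.  Multi-start initialisation: `Z_m` starts at 1.2× the
  largest Z with observed growth (lower bound just above it, so the fitted
  `Z_m` always exceeds every growing observation), `K_z` starts at
  {0.5, 1, 2}, `mu_max0` at the observation nearest Z = 0; `mu_max0` is
  free by default and can be pinned.  Non-convergence never raises — the
  result carries an honest flag.  R² uses deviations from the observation
  mean.
* **Family selection** ranks converged fits by R² descending; fits whose
  R² agree within 10⁻⁶ are tied and the family with fewer free parameters
  wins (needed because the power law nests the linear law).
* **Bootstrap intervals** for the inhibition parameters use a residual
  bootstrap with residuals standardised by the fitted values before
  resampling — the measurement error is multiplicative, so raw residuals
  are heteroscedastic and exchanging them unscaled understates variability
  at strongly inhibited levels.  Refits start from the full-data estimate.
  Nominal 95% percentile intervals cover the generating `(Z_m, K_z)` in
  ~93% of noisy synthetic replicates.
* **Monod-constant recovery** from a time course fits simulated classical
  trajectories to observed biomass and glucose jointly, each variable
  normalised by its observed range, simulation started from the first
  observed sample (`dt = 0.05 h` inside the fit loop).

## Synthetic data

The generators produce every input the calibration and evaluation
workflows need, with no external data:

* **Time courses** — the model sampled on the experimental 13-point
  schedule (0, 2, …, 48, 72 h) plus multiplicative Gaussian noise
  (`sd = relative_sd·value + floor_sd`, truncated at zero; default 5%
  relative, approximating HPLC repeatability).  Zero-noise output is exact
  to the solver.
* **mu-vs-Z curves** — the spiked-byproduct experiment design:
  `mu_max0·f(Z)` plus the same noise model, with `K_s` observations drawn
  uniformly from the 11.4–11.7 g/L stability band; byproduct levels above
  `Z_m` map to zero growth.  The lactic-acid channel is identically zero
  (its presence indicates bacterial contamination, not normal
  fermentation).
* **Yield endpoints** — complete simulated batches across initial-sugar
  levels.

What the generators do **not** emulate: inter-run biological variability,
instrument drift or autocorrelated errors, the micro-aerobic start-up
phase, or ethanol/substrate inhibition at high titres.  Passing tests
therefore demonstrate internal consistency and recoverability under an
idealised error model, not field performance on real broths.

## Design choices

* The modified and classical models are compared with descriptive
  statistics only (MSE, RMSE, AAD, R²); formal model-selection tests are
  out of scope.  AAD defaults to the **sum** of absolute deviations
  (the convention consistent with the magnitudes reported for 13-sample
  courses), with a mean-mode flag.
* Observed-vs-simulated alignment is linear interpolation of the dense
  simulated grid at the observation times; observation times outside the
  simulated horizon are an error, and pairs with missing observations are
  dropped per variable.
* The byproduct-vs-sugar regression is fitted with a free intercept (the
  slope is the yield; the intercept is expected ≈ 0), with a
  through-origin variant by flag.
* Configuration is one JSON document validated recursively — unknown keys
  are rejected by name — and all randomness takes explicit seeds; there is
  no hidden global state.
* Problem sizes in the test suite are chosen for desk-scale runs: full
  batches at `dt = 0.01 h`, bootstrap coverage over 200 replicates of a
  12-point curve at 100 resamples each.

## Known limitations

* **Monod-parameter collinearity.** From a noisy 13-sample batch course,
  `mu_max` and `K_s` are nearly unidentifiable jointly (the classic ridge:
  only samples inside the brief depletion transition inform `K_s`).  With
  5% multiplicative noise the recovered `K_s` can be off by an order of
  magnitude even though the fitted trajectory predicts the course to
  R² > 0.98.  The noise-free round trip recovers both constants to <10⁻³;
  under noise, the fit should be read as predictive, not as a `K_s`
  measurement.  Denser sampling through the depletion phase is the remedy
  on real data.
* The model-vs-model fermentation delay depends on the per-S0 parameter
  sets used; with one calibrated parameter set shared across initial-sugar
  levels only the qualitative trend (delay grows with S0) is meaningful.
* The trajectory invariants (S non-increasing, X/P/Z non-decreasing) hold
  for the implemented rate laws; user-registered families that violate
  monotonicity of `f` could break them.
* Fed-batch and continuous operation, stiff-solver support, and
  per-component inhibition constants are out of scope.
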