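# Methods

## The compartment model

The room (default V = 30 m³, ventilated at λ = 1.0 h⁻¹) is divided into
eight equal sub-volumes on a 2×2×2 grid, each treated as well mixed.
Assumptions inherited from the underlying mass balance: chemical losses are
dominated by ventilation (no wall sorption, deposition or reaction terms),
the infiltrating air carries zero concentration, and all flows are constant
in time. Bulk ventilation is unidirectional along the y axis: each of the
four (x, z) columns carries Q/4 = Vλ/4 from outdoors through its y=1
compartment to its y=2 compartment and out. On top of the advection, every
pair of face-adjacent compartments (labels differing in one coordinate,
three neighbours each, on all three axes including the flow axis) exchanges
air symmetrically at Q_ex = (V/8)·λ_ex. λ_ex is a lumped descriptor of
convective and dispersive in-room mixing; it is independent of λ and is the
quantity estimated from data.

Writing C for the vector of compartment concentrations, the system is
dC/dt = A C + b(t) with A a Metzler matrix (so non-negative states remain
non-negative); the well-mixed model is the same equation in one state. The
perfect-mixing limit holds by construction: as λ_ex → ∞ the compartments
homogenize and their mean follows the well-mixed solution, since summing
the compartment equations cancels the exchange terms pairwise and the
outlet removal of a homogeneous field equals QC̄.

### Emission

The default release is instantaneous: the emitted mass enters the source
compartment ("111") as a state jump C → C + m/(V/8) at the application
time. A trigger or propellant burst lasts seconds, far shorter than the
fastest transport timescale in the model (1/(2λ + 3λ_ex) ≈ 4 min at the
default rates), and the anchored well-mixed TWA pair is consistent with a
pure C₀e^{−λt} decay, so a jump is the appropriate idealization. A
constant-rate mode (mass spread uniformly over a stated duration) is
provided for sensitivity analysis, and the synthetic generator additionally
offers a first-order discharge mode (release rate k × mass remaining,
default off) to emulate the aerosol-to-vapour lag of trigger sprays.

### Solvers

Two independent routes solve the same linear system:

* `simulate_model2` — adaptive LSODA integration, rtol 1e-8 / atol 1e-12,
  restarted at every release jump or rate breakpoint (jumps are never
  represented as narrow forcing spikes, which adaptive steppers can step
  over);
* `solve_matrix_exponential` — the exact affine propagator
  exp([[A, b], [0, 0]]·Δt), which handles singular A (λ = λ_ex = 0) without
  special cases.

The test suite requires mutual agreement below 1e-6 relative and a
per-interval discrete mass-balance residual below 1e-6 of the emitted mass;
both typically sit near 1e-9. The matrix-exponential route also backs the
fitting loop, where its exactness and speed (one 9×9 `expm` per output
step) matter.

## Preprocessing pipeline

Measured-style traces go through four stages in fixed order — calibrate →
background-subtract → smooth → normalize — and each operation stamps the
series stage and refuses out-of-order application (stages may be skipped
forward, e.g. model output enters at the calibrated stage, but never
repeated or reversed).

* **Calibration**: ordinary least squares of instrument signal against
  nominal concentration (injected mass / 0.29 m³ mixing-chamber volume,
  assuming complete evaporation). An intercept is fitted because a signal
  offset exists in practice; at least three points are required and a
  non-positive slope is an error.
* **Background subtraction**: per-compartment mean over a pre-application
  window of at least 5 min, subtracted from the whole trace. The window is
  half-open ([t₀, t₁)) so a release at exactly t₁ cannot contaminate the
  estimate. Negative residuals are preserved, never clipped.
* **Smoothing**: centred running average, default 2.5 min. At the edges the
  window shrinks symmetrically (no padding, no dropped samples) and the
  output grid equals the input grid. Centred alignment was chosen because
  it is phase-free; the window must exceed twice the sampling interval.
* **Normalization**: concentrations scaled by reference/applied product
  mass (default reference 1 g), making independent applications
  comparable.

## Fitting λ_ex

One λ_ex per replicate is estimated by nonlinear least squares over all
eight compartments and all time points with uniform weighting, V, λ and the
emission held fixed, starting from λ_ex = λ. The parameter is
box-constrained to [0, 10³] h⁻¹ (trust-region-reflective least squares via
lmfit) rather than transformed, so a genuine zero-mixing boundary estimate
is reported as exactly zero with a clean convergence flag.

Because the data have been run through the 2.5-min running average, the
same averaging operator is applied to the model trajectories before
residuals are formed. This matters: smoothing smears the fast early
transient of the source compartment, and fitting smoothed data against an
unsmoothed model biases λ_ex by several percent even at zero noise. With
the operator applied to both sides, the zero-noise end-to-end pipeline
(generate → preprocess → fit) recovers the generating λ_ex to machine
precision, and the suite enforces < 0.1 %.

Replicate estimates are aggregated by a trimmed mean with
floor(trim_fraction·n) values removed from each tail (default fraction
0.25, configurable); at n = 3 this removes nothing and equals the plain
mean. Non-convergence of any replicate fit is flagged in the result, never
silently dropped.

## Exposure metrics

* **TWA**: (1/T)·∫C dt over [application, application + T] by the
  trapezoidal rule, window endpoints linearly interpolated; default
  windows 0.1 h and 0.3 h.
* **CV(t)**: standard deviation of the eight compartment concentrations at
  t divided by their mean. The sample (n−1) deviation is the default, with
  the population variant behind a switch, since the underlying definition
  does not specify one. Times where the mean falls below 1 % of its peak
  are reported as NaN instead of producing exploding ratios (relevant for
  early near-background propellant traces). CV is computed on whatever
  stage the caller supplies — by default the fully processed (smoothed,
  normalized) series — and the stage is recorded alongside.

## Synthetic data generator

The generator emulates what a PTR-qMS sampling eight points in a chamber
would record: the exact eight-compartment solution at the scenario's true
λ_ex, plus a per-compartment additive background (drawn within ±20 % of the
scenario level, kept under the pre-application ceilings of 10 mg m⁻³ for
trigger and 1 mg m⁻³ for propellant scenarios), a slowly varying additive
drift (piecewise-linear noise with ~2-min nodes), and multiplicative
Gaussian noise on the total signal (counting noise grows with signal;
default sd 5 %, chosen as a plausible instrument scale since no noise model
is stated anywhere — it is a config parameter, not an asserted truth).
Applied product mass varies between replicates (default 2 g ± 5 %); emitted
chemical mass is applied mass × chemical mass fraction, with the ethanol
mass fraction derived from the preset's 20/50/80 % v/v composition via
component densities. The 2 g default puts the converged room concentration
in the 15–30 mg m⁻³ range a trigger-ethanol chamber run reaches; the
propellant preset's effective emitted mass (12 mg) likewise targets a
0.05–0.15 mg m⁻³ converged level — applied masses per trial are not
published, so both are order-of-magnitude choices recorded in every study
manifest. Sampling is 1 s by default (the instrument's 100 ms scan is the
configurable floor; 1 s keeps desk-scale runtimes). Trigger presets default
to 3 replicates, the propellant preset to 1.

All randomness derives from `default_rng((seed, replicate_index))`, so each
replicate is byte-reproducible and adding replicates never perturbs earlier
ones. The generating truth (λ_ex, backgrounds, masses) is stored in the
series metadata, which is what makes end-to-end parameter-recovery tests
possible.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: aerosol formation, deposition and
liquid-to-vapour phase transition (the main physical driver of early-time
heterogeneity for trigger sprays), humidity/temperature effects, instrument
drift correlated across compartments from sequential sampling, and any
mismatch between the eight-compartment topology and real room airflow.
Recovery results show the estimator is correct under the model's own
assumptions, not that the model captures a given room.

## Problem sizes

Tests and the acceptance script run at desk scale: 20-min trajectories on
grids of 400–2100 points, triplicate studies at 1–5 s sampling, and
noise-ladder studies of three seeded replicates per level. These sizes were
chosen so the whole suite completes in well under a minute while leaving
discretization errors orders of magnitude below the asserted tolerances.

## Known limitations

* The 2×2×2 topology is fixed; arbitrary grids are out of scope.
* λ, V and the emitted mass are never co-estimated with λ_ex; confounding
  between emitted mass and mixing rate is therefore not addressed.
* The CV of measured chamber data typically exceeds the model's CV at the
  fitted λ_ex (the model lacks the aerosol phase lag), so model CV values
  should be read as lower bounds on real spatial uncertainty.
* Uncertainty reporting is limited to per-replicate spread; no interval
  estimation is attempted.
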