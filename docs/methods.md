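# Methods

## Model

The viscoelastic element is a Standard Linear Solid in the Maxwell form:
a spring E₀ in parallel with a Maxwell arm (spring E₁ in series with a
dashpot η). Its constitutive equation, written on the Maxwell-arm stress
σ_m with total stress σ = E₀ε + σ_m, is

    dσ_m/dt = E₁ dε/dt − σ_m/τ,   τ = η/E₁.

Strain is normalised to 1 at end-inspiration, so all moduli are in
pressure units (cmH₂O) and the step-strain relaxation is
P(t) = E₀ + E₁·e^(−t/τ). `viscovent.sls` provides both the closed form
and a direct ODE integration (scipy Radau, rtol 1e-10, piecewise-linear
strain interpolation) used as an independent oracle; the two agree to
< 1e-6 cmH₂O over ten time constants, the contract the test suite
asserts. The ODE route exists only for cross-validation and for
arbitrary strain histories; the simulator itself uses the closed form.

## Trace synthesis

One CMV cycle of period T = 60/rate at sampling rate 31.25 Hz (the
datalogger rate; the magnet bench tooling uses 50 Hz) has three phases:

* **Inspiration** — constant flow for `insp_flow_fraction`·T (default
  0.25: the true inspiratory-time settings of the bench runs are not
  recorded, so a conventional 25% duty is used and exposed in config).
  Flow is rescaled to the grid-snapped flow time so the trapezoid
  integral of the flow column delivers the tidal volume exactly.
  Pressure = Raw·Q + V(t)/C + actuator end-inspiratory pressure. The
  elastic term during inspiration follows the analytic volume ramp rather
  than the half-step-lagged trapezoid column, so the decomposition
  Ppeak = Raw·Q + VT/C + E1-equivalent holds to machine precision.
* **Pause** — `pause_fraction`·T of zero flow, interpreted as a fraction
  of the whole cycle period (ventilator-style pause percentage; a
  fraction-of-inspiration dialect can be emulated by rescaling). Pressure
  is the plateau VT/C plus the actuator decay. The actuator's pause clock
  starts at the first zero-flow sample, matching the estimation
  convention that the relaxation time origin is t₂ (zero flow).
* **Expiration** — passive single-compartment decay with time constant
  Raw·C. This phase is cosmetic realism (the analysis uses only
  inspiration and pause); its flow profile is rescaled by ~2% so the
  volume column remains an exact running trapezoid of the flow column
  despite the flow discontinuity at expiration onset, and each cycle
  starts from an empty lung.

Noise has two components, both Gaussian and seeded: per-sample pressure
noise (default SD 0.1 cmH₂O, a plausible transducer/quantisation floor
that leaves fit R² in the observed >95% range) and a per-cycle
perturbation of the actuator drop amplitude (default SD equal to the
bench replicate spreads, 0.22 / 0.17 cmH₂O at AB 25 / 30 mm). Identical
seed and config give bit-identical traces.

## Actuator

**Force law.** The magnet force–distance model interpolates the bench
anchors exactly: 6.91 N at the 10 mm baseline (neodymium-4mm pair) and
the three 10 s decay anchors (46.74 / 64.25 / 79.16% at 30 / 50 / 80
mm/min, i.e. force anchors at 15 / 18.33 / 23.33 mm). A power-law-with-
offset backbone A/(d−c)ⁿ is least-squares fitted in log space, then
multiplied by a PCHIP interpolant of the anchor residuals (clamped
outside the anchor range), giving exact anchor reproduction on a
physics-flavoured, strictly decreasing curve. Because the bench data stop
at 23.33 mm, a *synthetic* far-field anchor — 0.5% of the baseline force
at baseline+stroke (80 mm) — pins the tail; it is a construction choice,
not a measurement. The weaker pairs (2.60 N neodymium-2mm, 1.59 N
ceramic-4mm) reuse the same shape rescaled to their baseline force, an
assumption since their time-domain decays were not characterised
numerically.

**Calibration.** AB distance maps to the E₁-equivalent pressure (3.48 /
2.20 cmH₂O at 25 / 30 mm, linear in between, warning outside) and
(PWM, AB) maps to the fitted viscosity η (1.181, 0.403, 1.166, 0.442
cmH₂O·s at the four calibrated corners, bilinear). τ = η/E₁ is derived.
Note that η — not τ — is the quantity controlled (almost) purely by PWM:
the calibrated η varies ~3× across PWM but ≤10% across AB, whereas τ
necessarily changes with AB because E₁ does. The default PWM is 74.51%,
the faster calibrated anchor: it is a calibration point (no
interpolation) and its sub-0.21 s time constants let the relaxation
essentially complete within even a 20%-of-cycle pause, so landmark-based
E₁ readings are truncation-bias-free to <2%. At slower settings (PWM
68.63% or the interpolated 70%) the exponential tail of the
phenomenological mode outlives a short pause and the measured P₁−P₂
underestimates E₁ by up to ~7–16%; the physical rig does not show this
because its return stroke completes and the force genuinely vanishes.

**Modes.** Phenomenological mode emits E₁·e^(−t/τ) during the pause (and
E₁ during inspiration, treating AB as quasi-static while the rod is
extended). Mechanistic mode instead moves the rod magnet at a constant
return speed — calibrated so the force falls to 1/e of its
end-inspiratory value after one calibrated τ — and converts force to
pressure through an effective bellows area (default derived so the
mechanistic end-inspiratory pressure at AB 25 mm equals the calibrated
3.48 cmH₂O). The two modes agree on total drop magnitude to ~2% and the
mechanistic decay is well captured by the exponential fit (R² > 0.95).

## Estimation

* **Segmentation** — t₂ is the first sample with |flow| < 1e-3 L/s after
  inspiratory flow (first qualifying sample wins ties); P₁ is the
  pressure there; the pause window is the contiguous zero-flow run; P₂ is
  the mean of its final 20% (minimum 5 samples — averaging suppresses
  noise while keeping the truncation bias of an asymptotic plateau
  bounded); Ppeak is the cycle maximum. Pauses shorter than 0.3 s raise
  an explicit no-pause error.
* **E₁** — mean of per-replicate drops; D'Agostino–Pearson omnibus
  normality (refused below n = 8, the test's validity floor); one-sample
  t-test against a configurable hypothesised value defaulting to the
  mean rounded to two decimals (the reported point estimate), since a
  test against an externally fixed null is not meaningful for a
  calibration quantity.
* **Regression** — nonlinear least squares (scipy `curve_fit`) on
  P(t) = E₀ + E₁·e^(−E₁t/η) with E₁ fixed, free (E₀, η), initialised at
  E₀ = last-sample pressure and η = E₁·(window/4), bounds E₀ ≥ 0,
  η > 0. R² is computed against the segment mean. A linearised
  log-regression variant (`method="log-linear"`: E₀ fixed at the plateau
  mean, slope of log-excess) is provided for comparison with
  spreadsheet-style fits. Noiseless round trips recover parameters to
  ≲1e-6; degenerate constant segments are flagged (η at its lower bound,
  R² undefined).

## Experiments

`FactorialDesign` enumerates every combination of two-level factors times
replicates; run *i* uses child seed (master·100003 + i) mod 2³¹, recorded
per run. The two bench designs ship as presets: 2² (PWM × AB, 35% pause,
Raw 18, VT 150 → 12 executions) and 2⁴ (Raw × compliance × VT × AB, 20%
pause, PWM 70% → 48 executions); PWM 70% lies between the calibrated
points and its runs are flagged `pwm_interpolated`. Failed runs are
recorded with their error, never dropped.

## Problem sizes

The reproduction experiments are desk-scale by design: single cycles
(~144 samples at 31.25 Hz), 24-cycle replicate runs, and 200-replicate
noise sweeps (50 per calibration run), which keep the whole suite and the
acceptance script within seconds while leaving Monte-Carlo standard
errors well inside the asserted tolerances.

## What the synthetic traces do and do not show

The generator reproduces the *calibrated* behaviour of the bench system:
landmark geometry, exponential pause decay, replicate spread, and the
printed force anchors. It does not emulate ventilator circuit dynamics
(finite occlusion time between t₁ and t₂, trigger/cycling, PEEP),
cardiogenic or sensor drift artefacts, frequency dependence of the
viscoelastic response, multi-compartment behaviour, or anything about
the force–distance curve beyond the printed anchors (the published
curves themselves are figure-only). Passing tests therefore validate the
model, calibration, and pipeline logic — not the hardware's unmodelled
physics. Absolute peak pressures of the bench recordings are not
reproducible because the bench inspiratory-time settings were not
reported; no claim is made about them.
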