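# Methods

This note documents the scientific model behind `chromoswitch`, the
defaults it ships, the choices made where the design was genuinely open,
and what the synthetic data can and cannot tell you about real
experiments.

## Photochemical model

A photoswitch is a closed two-state system (E, Z) under monochromatic,
optically thin illumination. Per-molecule excitation rates are
`k_EZ = C ε_E(λ) Φ_EZ I` and `k_ZE = C ε_Z(λ) Φ_ZE I` with
`C = ln(10)/10`, the standard conversion from decadic molar absorptivity
(M⁻¹ cm⁻¹) and photon flux (mol photons m⁻² s⁻¹) to s⁻¹ (Avogadro's number
cancels). Adding a thermal Z→E rate `k_th` gives the relaxation rate
`k_obs = k_EZ + k_ZE + k_th` and photostationary Z fraction
`φ_λ = k_EZ / k_obs`. With `k_th = 0` (the default: a bistable
azobenzene with stable bidirectional PSSs) `φ_λ` is a pure ratio of
ε·Φ products — independent of flux, which the tests assert across six
orders of magnitude.

Illumination protocols are ordered (wavelength, flux, duration) segments.
Within a segment the trajectory is the exact exponential
`f_Z(t) = φ + (f_Z(0) − φ) e^{−k_obs t}`, so propagation is
piecewise-analytic and the reported samples carry no integration error;
the sampling density (default 200 samples/segment) affects reporting
resolution only. A generic ODE solver and an explicit Euler scheme appear
only as independent oracles in the test suite (agreement 1e−6 at steady
state, 1e−4 along trajectories).

Deliberate simplifications: monochromatic light (no LED bandwidth
averaging), optically thin sample (no inner-filter or tissue attenuation),
no photobleaching or side chemistry.

## Synthetic spectra and calibration

True per-isomer absorptivities and quantum yields of the azobenzene–
xanthine reagents are not available in machine-readable form, so the
`synth` module builds a labelled *synthetic stand-in*: Gaussian bands in
the wavelength domain (E: strong π→π* at 350 nm, σ = 30 nm; weak n→π* at
440 nm, σ = 35 nm; Z: blue-shifted π→π* at 315 nm, σ = 28 nm; n→π* at
435 nm, σ = 25 nm) on a 280–600 nm, 1-nm grid. Quantum yields default to
Φ_EZ = 0.30, Φ_ZE = 0.45 — mid-range azobenzene values stated as
conventions, not measurements of any specific compound.

Band amplitudes are then calibrated by deterministic least squares (in log
space, keeping them positive) so the closed-form PSS reproduces the
anchors

| anchor | meaning |
|---|---|
| φ(360 nm) = 0.95 | the ~95% Z photostationary state |
| φ(410 nm) = 0.18 | the ~82% E photostationary state |
| φ(440 nm) = 0.02 | near-complete E at the off wavelength |

The first two anchors are the compound's characterised PSS pair. The third
is this package's own encoding of the observed electrophysiology off-state:
440-nm illumination returns currents essentially to baseline, which in the
response model requires the residual-Z agonism at the off wavelength to be
no larger than the constitutive tone it displaces; φ(440) ≈ 0.02 achieves
exactly that (see "Response model" below). Calibration residuals must stay
below 0.005 absolute in φ or a `CalibrationError` reports them. Because
the calibration fixes only three amplitudes, band positions and widths are
conventions; the resulting spectra are qualitatively azobenzene-like but
are not a digitisation of any measured spectrum.

The default photon flux, 1e−3 mol photons m⁻² s⁻¹, puts `k_obs` near
1–1.5 s⁻¹ in the working bands — second-scale switching, chosen as a
convention because instrument fluxes are unpublished.

## Pharmacological model

Binding is quasi-equilibrium (instantaneous relative to photoswitching and
readout) and depletion-free (nanomolar ligand vs. far scarcer receptor),
so occupancies follow the Gaddum competitive expressions in total
concentration `c` and Z fraction `f_Z`. Receptor activation uses a
Black–Leff operational map: stimulus
`S = b·ρ_free + max(b + e_Z, 0)·ρ_Z + max(b + e_E, 0)·ρ_E`,
response `E* = (τS)^n / ((τS)^n + 1)`.

* `b` (basal tone, default 0.02) — small constitutive activity, as seen in
  near-zero baseline currents.
* `e_Z = +1`, `e_E = −0.3` — Z full agonist, E inverse agonist. The
  magnitude of the negative efficacy is a placeholder: inverse agonism of
  the E isomers is qualitative in the source pharmacology, with no
  measured magnitude. Any `e_E ≤ −b` behaves identically at saturation
  because of the zero clamp.
* `τ = 10`, `n = 1` — receptor reserve strong enough that the plateau
  response is set by φ_λ alone over ≥100-fold concentration once occupancy
  nears saturation, reconciling occupancy arithmetic with the observed
  wide dose-independent window.

A single competitive site is modelled; the tetrameric stoichiometry of the
real channels (four binding sites, possible subunit-occupancy gating) is
intentionally not represented — no quantitative gating data exist to
constrain it.

**Presets.** Printed potencies are *response* EC50s. With equal affinities
and `n = 1` the response is a Möbius function of `c` with half-effect at
`EC50 = K (1 + τb) / (1 + τ s̄)`, `s̄` the mixture stimulus at the
reference PSS (f_Z = 0.95). Preset Kd values are obtained by inverting
this: `trpc4_azpico` (EC50 3.0 nM → Kd ≈ 26.7 nM), `trpc5_azpico`
(4.0 nM), `trpc5_azhc` (6.4 nM), plus an inactive-on-TRPC4 AzHC preset and
a hypothetical ideal affinity switch (Z-only binder) for contrast.

**Threshold convention.** `independence_threshold` declares the target
"near saturation" at total occupancy ≥ 0.83, giving `c_min = Kd·0.83/0.17`
(≈ 4.88 Kd; smallest integer multiple 5). Its "EC50 multiples" are
multiples of the occupancy half-saturation (= Kd). Under receptor reserve
the response EC50 is lower than Kd, so the same threshold expressed in
response-EC50 multiples would be larger; the occupancy convention is the
one used throughout and is a documented convention, not a measurement.

**Off-state arithmetic.** At the off-PSS, E-occupied receptors contribute
zero stimulus (clamped inverse agonism) and residual Z contributes
`(b + e_Z)·φ_off` per occupied receptor. With `b = 0.02` and
`φ(440) = 0.02` the occupied-state stimulus `1.02·0.02 ≈ 0.0204` almost
exactly replaces the displaced constitutive tone, so the off plateau sits
within well under 2% of the compound-free baseline at any concentration —
the mechanism by which an ideal efficacy switch "switches off" despite
incomplete photoswitching.

**Classification.** `classify_switch` applies, in order: inactive (both
|eff| < 0.05); affinity (Kd ratio > 10); ideal_efficacy (ratio ≤ 3,
opposing efficacies or one silent binder with the other ≥ 0.5, both
numerically-determined half-effect potencies < 50 nM); otherwise
nonideal_efficacy. The ratio and silent-binder cut-offs are package
conventions quantifying the qualitative "identical or very similar
affinity" requirement.

## Simulation and readout

`run_experiment` composes the analytic `f_Z(t)` with the occupancy/response
map. Readouts: `instantaneous` (electrophysiology-like, linear) and
`first_order_lag` (plate-reader-like; default `lag_tau = 2 s`, a
convention standing in for an unpublished reporter lag). Optional Gaussian
readout noise is seeded; identical seeds give bit-identical traces.
`cycle_stats` pairs consecutive segments into cycles and reports per-cycle
extrema; `fatigue_slope` is the slope of ln(amplitude) vs. cycle index, so
a programmed 2%-per-cycle decay reads out as ln(0.98) ≈ −0.0202.
Wavelength scans cycle each scan wavelength against a fixed
counter-wavelength with segment lengths of 10/k_obs (so every segment ends
within 0.005% of its PSS plateau) and report the end-of-segment effect.

## Fitting

Hill fits use the four-parameter logistic with multi-start least squares
(7 log-spaced EC50 initialisations spanning the design, bounds
n ∈ [0.2, 10]); decreasing curves are normalised to `top ≥ bottom` with a
recorded direction. Flat data raise a diagnostic error rather than return
a spurious EC50. Standard errors come from the Jacobian at the optimum;
log-EC50 errors by the delta method.

Action-spectrum model comparison fits the offset/scale of each rival model
by ordinary least squares and compares AIC under Gaussian residuals
(3 parameters each, so the comparison reduces to the RSS ratio);
|ΔAIC| < 2 is a tie, and RSS is floored at numerical noise so two exact
fits tie rather than amplifying rounding error. Joint multi-concentration
data expose the affinity model's intrinsic `b·log10(c₂/c₁)` prediction
shift — the concentration-doubling discriminator.

The recovery harness repeats seeded generate→fit cycles (default noise:
multiplicative lognormal, sd 5%, plate-reader-like) and reports bias,
median bias, RMSE and nominal-95% CI coverage of log10 EC50; fit failures
are counted, not fatal. All randomness flows from one integer seed through
`numpy` SeedSequence spawning.

## Problem sizes and determinism

Default study conditions: the 12-point half-log concentration ladder from
12 pM to 1.6 µM; 36-cycle 360/440-nm cycling with 10/k_obs segments and
200 samples/segment; action-spectrum scans on a 340–480 nm, 5-nm grid;
200 replicates for noisy recovery and 50 for model discrimination. The
dose–wavelength surface used to measure concentration independence spans
three decades above the saturation threshold (76 log-spaced points). All
are the package's chosen desk-scale conditions and run in seconds to a few
minutes on one core.

## Known limitations

* The synthetic spectra and quantum yields are calibrated stand-ins;
  passing tests show the *model's* internal consistency and the
  recoverability of its parameters, not agreement with any measured
  spectrum or the true photophysics of a specific reagent.
* Single-site competitive binding ignores tetramer stoichiometry,
  heteromeric channel composition and cooperative gating.
* The operational transduction parameters (τ, n) and the inverse-agonist
  magnitude are conventions; only their qualitative regime (reserve large
  enough for plateau independence; e_E ≤ −b) is constrained by the
  modelled observations.
* No tissue optics, pharmacokinetics, or downstream oscillatory readouts:
  the simulator ends at the primary receptor response.
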