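# Methods

## The kinetic model

Neuroglobin keeps its distal His64 coordinated to the heme iron, so an
exogenous ligand can bind only while the His64–Fe bond is broken. The
package models this with a five-state reaction network of population
fractions (pseudo-first order at fixed solvent CO):

```
pair  --k_gem_rebind-->  co          geminate rebinding from the pocket
pair  --k_out--------->  deoxy       CO escape to solvent
pair  <--k_trap_in / k_trap_out-->  trap    docking-site exchange
deoxy <--k_his_on / k_his_off--->   hexa    His64 gating
deoxy --k_co_on*[CO]--> co           bimolecular binding
co    --k_co_off------> deoxy        CO dissociation
```

`deoxy` is the 5-coordinate binding-competent species, `hexa` the
bis-histidyl 6-coordinate species, `pair` the photodissociated CO still
in the distal pocket, `trap` a temporary docking site. The observable
is the unliganded fraction N(t) = 1 − co(t). All rates are in s⁻¹
(`k_co_on` in M⁻¹s⁻¹), times in seconds, concentrations in molar;
reported rates are rounded to two significant figures.

The network is linear, so simulation uses a stiff implicit integrator
(BDF, rtol 1e-8, atol 1e-10) with the analytic constant Jacobian,
evaluated on log-spaced grids because a photolysis trace spans
nanoseconds to seconds. The deoxy/hexa pair with irreversible CO
capture (k_co_off = 0, empty pocket states) has an exact 2×2
eigen-solution, `closed_form_two_state`, kept solely as an oracle; the
property suite certifies agreement with the integrator to 1e-8 (the
integrator is run at rtol 1e-10 in those comparisons so its own error
sits below the certified level).

Derived relations:

* observed stopped-flow rate (rapid pre-equilibrium treatment):
  k_obs = k_his_off·k_CO_on[CO] / (k_his_on + k_CO_on[CO]), saturating at
  the His64 dissociation rate. The steady-state denominator
  (k_his_on + k_his_off + k_CO_on[CO]) is available behind
  `form="steady_state"`; the source analysis does not print which form
  was fitted, and the pre-equilibrium form is the default because it
  reproduces the stated high-[CO] limit.
* overall affinity: c50 = (1 + K_H)·k_CO_off/k_CO_on with
  K_H = k_his_on/k_his_off; His64 competition weakens the apparent
  affinity.
* geminate partition: on the nanosecond window the pocket CO either
  rebinds or escapes, giving a single exponential with amplitude
  Φ = k_gem_rebind/k_gem and rate k_gem = k_gem_rebind + k_out, hence
  k_out = (1−Φ)k_gem and k_−1 = Φ·k_gem. The mapping is an exact
  bijection.

## Estimators

**Multiexponential decomposition.** Traces are fitted as
offset + Σ aᵢ·exp(−kᵢt) by variable projection: rates are optimised in
log space (multi-start: an even log-rate spread, "peeling" seeds that
extend the previous model order by one rate swept across every decade,
and random log-uniform restarts), amplitudes and offset solved linearly
at each step. Model order (0–4 components) is chosen by corrected
Akaike criterion; a larger model is accepted only when it improves AICc
by ≥ 10, because adding decays to kinetic traces is notoriously
unstable. Ties keep the smaller model. Two numerical guards matter:

* residuals below ~3×10⁻⁵ of the signal span are treated as optimizer
  noise (an RSS floor in the AICc comparison); without it, noiseless
  traces drive the criterion to accept cancelling component pairs;
* on log-sampled grids spanning ≥ 2 decades, points are weighted by
  their local log-time spacing (capped at 50 points/decade) so each
  decade contributes comparably, and the AICc is calibrated on the Kish
  effective sample size of those weights. Linearly sampled traces keep
  uniform weights — there the instrument already concentrates samples
  where the signal evolves.

Standard errors come from the full nonlinear Jacobian at the optimum.
A constant trace returns an offset-only result flagged `degenerate`.

**k_obs([CO]) fit.** Levenberg–Marquardt fit of the gated-binding
hyperbola; only the plateau (k_his_off) and the ratio
c_half = k_his_on/k_co_on are identifiable. When every point sits on
the plateau the fit is flagged `plateau_only`.

**Hill plot.** Ordinary least squares of log10(Y/(1−Y)) against
log10[CO]; c50 is the abscissa of the zero crossing (exact for a
single-site isotherm, which also fixes the choice of log-concentration
abscissa), with errors propagated through the full parameter
covariance.

**ν3 band decomposition.** Lorentzian bands (Gaussian/pseudo-Voigt
selectable) over a jointly fitted linear baseline in the 1450–1550 cm⁻¹
window, multi-started with jittered centers; models with different band
counts are compared by AICc. For the heavily overlapped ν3 triple the
comparison fixes each bandwidth at its known value
(`vary_fwhm=False`) — the standard deconvolution protocol when widths
are known from better-resolved spectra; with widths free, a two-band
model absorbs the three-band sum to well below realistic noise and no
estimator can recover the middle band.

**Conformer zoning.** Fe–CO adducts are classified by ν(C–O):
≥ 1955 cm⁻¹ → A0 (open pocket), < 1945 cm⁻¹ → the closed H-bonded
class, in between → A1; boundary values resolve to the
higher-frequency class. The literature labels the closed class either
A1 or A3, so the label is configurable (`closed_label`, default
"A3"). The back-bonding line is an OLS regression of ν(Fe–C) on
ν(C–O); its slope should be negative for physically sensible inputs.

## Pipelines

`run_rapid_mixing` fits each concentration's trace (conservative model
selection), assembles k_obs([CO]) per phase and fits the hyperbola,
converts overall amplitudes to bound fractions Y for the Hill fit
(relative to a full-signal reference of 1), and averages the fast-phase
amplitude fraction across concentrations. Assigning the fast phase to
the reversed-heme population is a labelling convention, not a fitted
quantity.

`run_lfp` segments a wide progress curve at 10 µs and 10 ms
(configurable) into geminate, bimolecular and slow phases. The
geminate phase yields (Φ, k_gem) from the fastest pocket-scale
component (rate ≥ 10⁶ s⁻¹) with Φ measured against the model value at
t = 0; the slow-phase rate estimates His64 displacement (a single
exponential by default; a two-step option exists but is untested
against printed values because the source could not resolve two steps
either). A separate trap search refits the curve out to 100 µs — far
enough for a microsecond-lifetime component to decay completely — and
labels a non-fastest component with rate in [5×10⁴, 5×10⁵] s⁻¹ and
amplitude fraction ≥ 2% as the docking-site trap.

## Synthetic data and fixtures

All inputs are generated, seeded and deterministic: noise is additive
Gaussian with sd = noise_sd × signal span (default noise_sd 1%), plus
optional linear baseline drift for spectra (off by default).
Generators emulate the documented acquisition protocols: stopped-flow
traces are averages of 3 repeats per concentration on a linear
2000-point grid (1 ms dead time to 40 s); LFP curves use a log grid of
600 points from 1 ns to 10 s at 0.2 mM CO with k_co_off set to zero;
spectra are averages of 6 accumulations on a 0.25 cm⁻¹ grid. Averaging
scales noise by 1/√n of the raw 1%.

The fixtures pin the printed observables: `wt_like` (monoexponential,
k_obs(500 µM) = 0.13 s⁻¹, Φ = 12%, k_gem = 2.9×10⁷ s⁻¹,
c50 = 20.6 µM), `cdless_like` (73:27 fast:slow populations at 1.2 and
0.62 s⁻¹, Φ = 16%, k_gem = 5.4×10⁷ s⁻¹, c50 = 19.0 µM, optional 7 µs
trap), `nu3_wt` (bands 1500.5/1506.5 cm⁻¹) and `nu3_cdless`
(1500.5/1502.5/1506.5 cm⁻¹, FWHM 10.5/10.5/8.5 cm⁻¹; heights
1.0/0.6/0.8 are free choices made so the third band carries real
area). These observables under-determine the microscopic rates, so
each population's (k_his_off, k_co_off) pair is back-solved by root
finding such that the slowest relaxation eigenvalue of the
deoxy/hexa/CO subsystem at 500 µM equals the printed k_obs exactly and
c50 matches, given chosen (k_co_on, c_half): wild-type kon = 5×10⁷
M⁻¹s⁻¹ with c_half = 10 µM (so k_obs is nearly CO-independent over
0.1–1 mM, as observed), CDless fast population kon = 1×10⁸ with
c_half = 30 µM and slow population kon = 5×10⁷ with c_half = 10 µM
(the mutant's second-order binding is faster). Each fixture records
these pinnings on its `pinning` field. The trap influx rate
(1.5×10⁷ s⁻¹, ~20% occupancy) is a free choice giving the
few-percent-amplitude docking phase; only its ~7 µs lifetime is pinned.

## What the synthetic data do and do not show

The generators reproduce the model's kinetic structure with seeded
Gaussian noise; they do not emulate shot noise, lamp drift,
photoselection, partial photolysis, temperature series or
instrument-response convolution. Passing recovery tests therefore
demonstrates that the estimators are unbiased and correctly calibrated
under the stated noise model at the study's problem sizes — not that
they would survive every instrumental artefact of real traces.

Two limitations found during development are worth stating plainly:

* At 0.2 mM CO the 7 µs docking-site eigenmode carries < 1% amplitude
  in N(t): pocket rebinding from the trap and bimolecular replacement
  nearly cancel, and any free 3-exponential fit absorbs the mode to
  ~10⁻⁴ pointwise, making it statistically unidentifiable at realistic
  noise. The trap-detection contrast is therefore demonstrated at 2 µM
  CO, where the competing bimolecular channel is suppressed and the
  docking phase is kinetically isolated (the same reason such traps
  are classically observed at low temperature).
* With free bandwidths, two Lorentzians fit the overlapped ν3 triple
  to far below 1% noise; the three-band requirement becomes decidable
  only with bandwidths fixed at their known values and averaged,
  well-sampled spectra, which is how the decomposition is run here.

## Problem sizes and reproducibility

Tests and the acceptance script run everything at the fixture problem
sizes above: 20-replicate-seed medians for stochastic recoveries,
50 random rate sets for the closed-form/integrator equivalence, 20 for
thermodynamic consistency. `scripts/acceptance.py --seed S` derives
all replicate seeds from S; generators are pure functions of
(fixture, seed), so outputs are byte-identical across re-runs.
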