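# Methods

## Model

The package simulates a two-node transcriptional circuit: an output node A
(reporter-expressing) and a buffer node B (an activator, e.g. a phage RNA
polymerase), wired as a negative feedback loop with positive feedback on the
buffer:

* an external inducer (input, μM) derepresses the promoter of A,
* B activates A,
* A represses B (e.g. via a dCas nuclease–guide complex),
* B activates its own production.

All regulation uses Hill kernels combined multiplicatively (AND logic) with
basal leaks, and each node decays/dilutes at first order:

    dA/dt = α1 · D(I) · [B^n_BA/(K_BA^n_BA + B^n_BA) + β_BA] − γ_A A
    dB/dt = α2 · [1/(1 + (A/K_AB)^n_AB) + β_AB] · S(B) − γ_B B

The input drive `D(I) = 1/(1 + (K_TFtot/(1 + I/K_IR))^n_RA) + β_RA` models
indirect derepression: the inducer sequesters a repressor of effective
abundance `K_TFtot` with half-effect concentration `K_IR`.

`S(B)` is the buffer self-activation factor and carries the key design
constraint. In the weak-feedback limit (`B ≪ K_BB`, `n_BB = 1`) it is
proportional to B, so the interior steady state of the B equation forces the
repression factor to the fixed value `γ_B K_BB/α2` regardless of the input.
The output then settles at

    A* = K_AB · (α2/(γ_B K_BB) − 1)^(1/n_AB)

for every input: robust perfect adaptation. The `ideal_linear` form
implements `S(B) = B/K_BB + β_BB` exactly; the `hill` form is the physical
saturating kernel. Cooperative self-activation (`n_BB > 1`) destroys the
cancellation and, for sufficiently steep kernels, makes the buffer
subsystem bistable.

Units: time in hours, input in μM, node concentrations in arbitrary units
with removal rates near 1/h (growth dilution is folded into γ).

### Output readout

The reported observable is the node-A concentration. At steady state the B
equation pins A (through the repression factor), so A is the adapting
species and matches a fluorescent reporter co-driven with the A node.

### Structural variants

* `null_pf` — self-activation replaced by a constitutive factor `c_pf`.
  To compare "promoter strengths" across parameter sets, `c_pf` is
  expressed as a multiple of the full circuit's operating-point
  self-activation factor (`matched_c_pf`); the multiple 1 reproduces the
  pre-step operating point exactly, larger multiples are stronger
  constitutive replacements.
* `nonlinear_pf` — cooperative self-activation with `n_BB = 2.3`, the
  characterised coefficient of the substitute activator part.
* `no_repression` — repressor gene deleted: the repression factor is frozen
  at its unrepressed value `1 + β_AB` (the promoter leak semantics are
  kept, the term is not removed).

## Reference parameter sets

`defaults_v1("ideal_linear")` is the minimal closed-form set
(α1=10, α2=2, γ=1, K's=1, n_AB=2, K_TFtot=3, K_IR=1; leaks 0.01 or 0): at
input 2 μM its leak-free steady state is exactly (A, B) = (1, 0.25).

`defaults_v1("hill")` is the saturating counterpart used for the
edge-perturbation panels: α1=100, α2=320, K_AB=0.5, K_BA=1, K_BB=40,
n_BB=1, β_RA=β_AB=0.01, β_BA=10⁻³, β_BB=10⁻⁵. These values were chosen so
the circuit genuinely occupies the regime the design requires:

* **weakness/linearity** — operating B ≈ 0.027 ≪ 0.05·K_BB;
* **interior-balance headroom** — α2/(γ_B K_BB) = 8, so the adaptive fixed
  point survives scaling the self-activation strength down 4-fold
  (it exists only while α2 > γ_B K_BB);
* **activation headroom** — the B→A activation operates ~40-fold below
  saturation, so weakening that edge 25-fold still leaves an adaptive
  balance (B rises, the activation factor compensates);
* **weak leak** — the self-activation leak must be small relative to the
  operating signal `B/K_BB` over the whole perturbation panel; a leak of
  0.01 would exceed the linear-regime signal and destroy adaptation, which
  is why β_BB is near zero (the physical self-activating promoter is
  essentially silent without its activator) and β_BA is 10⁻³.

Under these defaults the base circuit shows AErr ≈ 0.009 for a 2→300 μM
step, and all four edge scalings (self-activation ×2/×0.25, activation
×0.2/×0.04) stay below AErr 0.05 — comfortably inside the ≤ 0.20 band the
perturbation experiments define.

`bistable_nonlinear_pf()` is the nonlinear-feedback operating point
(α2=4, K_BB=1, n_BB=2.3, weak repression K_AB=10): its reduced B-equation
has stable states near B ≈ 0.043 and B ≈ 3.3–3.9 separated by an unstable
threshold, the two-population regime.

## Numerics

* Integration: `scipy.solve_ivp` with LSODA (stiff-capable), rtol 1e-8,
  atol 1e-10 (relaxed to 1e-7/1e-9 inside fitting loops).
* Steady states: chunked integration (chunks of 10/γ h, horizon 500 h) with
  a Newton polish after each chunk; the polish is accepted only if it stays
  within 25% of the integrated state (basin guard). Convergence: derivative
  max-norm below 1e-9 of the removal flux, or relative state change below
  1e-8 per chunk. Non-convergence raises an explicit error.
* Pre-equilibration initial state: (ε, ε) with ε = 10⁻³·K_BB, because B = 0
  is absorbing when β_BB = 0 while real systems always have basal
  expression.
* Fixed points: sign-change bracketing of the reduced 1-D steady-state
  residual in B (A eliminated through the A-equation balance) on a log grid
  of 400 points, Brent polishing, grid refined ×4 (with a warning) until
  the root count is stable; B = 0 added analytically when leak-free.
  Stability from eigenvalues of the finite-difference 2×2 Jacobian.
* Pulse peaks are read from the dense ODE interpolant on a 20× refined
  grid, never only from the sampling grid.

## Adaptation metric and classification

AErr = |Output1 − Output2|/Output1, with Output1 the mean of the final
`tail_n` (default 3) samples of the stepped series and Output2 the mean of
*all* samples of the unswitched control — the operational definition used
for the time-course measurements. A response is *responsive* when its peak
rises at least 50% above the control level (`sens_min = 0.5`) and *adapting*
when additionally AErr ≤ 0.1 (`aerr_max`). Both thresholds are free
parameters and are serialized into every screen report.

## Robustness screen

Cassettes are drawn log-uniformly (rates α ∈ [0.1, 1000], affinities
K ∈ [0.01, 100]); Hill coefficients uniformly on {1, 2, 3, 4}; γ's fixed at
1 (time-scale normalisation); leaks fixed (β_RA = β_BA = β_AB = 0.01,
β_BB = 10⁻⁴). The input-drive constants (K_TFtot, K_IR, n_RA) are held at
their design values so every cassette receives the same external stimulus:
the screen asks whether the *network* adapts, not whether the inducer
module responds. The reference screen step is 2 → 200 μM over 24 h at 0.1 h
resolution.

`fraction_adapting` is the adapting fraction among *responsive* cassettes.
Non-responsive cassettes (too little loop gain to produce a pulse) carry no
information about adaptation; counting them against either topology would
only dilute the comparison, and both totals are reported.

The "restricted analytic regime" (`weak_linear_regime`) is the set of
cassettes where the weak-linear theory applies: interior balance reachable
(α2 > γ_B K_BB), operating B ≤ 0.05·K_BB at both step endpoints, and every
internal Hill edge operating in its responsive range — above its leak floor
and below saturation — so the loop is actually closed. A closed-form
prescreen (the ideal-limit balance with a 2× slack margin on every
inequality) rejects most draws before any integration, making rejection
sampling of 200 in-regime cassettes take seconds rather than hours; the
exact ODE-based conditions are then verified for every accepted cassette.

Non-convergent integrations are recorded per cassette, never dropped; a
screen aborts if more than 5% of cassettes fail.

## Fitting

* Hill curves: least squares on log10 responses (fluorescence spans
  decades), multi-start bounded Nelder–Mead via lmfit followed by a
  trust-region polish; bounds n ∈ [0.5, 4], K within the dose range
  ×[0.1, 10]. Data with < 2-fold response range raise an unidentifiability
  error instead of returning a silent fit.
* Circuit fits: multi-start Nelder–Mead (default 20 restarts, seeded
  log-normal jitter of the initial point; restart 0 unjittered) in
  log-parameter space, objective = summed squared log10 residuals over all
  stepped and control series, weighted 1/SD² when SDs are given. The
  restart spread of near-optimal parameter values is reported as an
  identifiability proxy (`covariance_proxy`), and the best-vertex objective
  history is recorded (non-increasing by construction of the simplex
  accept rule — asserted in tests).
* Substitution prediction replaces α2 only and re-simulates; nothing is
  refit.

### Identifiability

Step-response data constrain the model sloppily. In the weak-linear
operating regime α1 only sets the scale of the (unobserved) buffer node —
with an unsaturated n_BA = 1 activation, the dynamics of `act(B)/act(B₀)`
are invariant to that scale — and α2, K_AB trade off along the
adapted-level manifold `A* = K_AB(α2/(γ_B K_BB) − 1)^(1/n_AB)`. Noiseless
data still pin all parameters through leak and saturation residues, but
under realistic replicate noise only certain directions (notably α2 with
the rest held, and any predicted observable) are recovered reliably.
`FitResult.covariance_proxy` (restart spread of near-optimal values) flags
the sloppy directions; the recovery tests assert parameter-level accuracy
where it is identifiable and observable-level accuracy where it is not.

## Synthetic data

Replicate noise is multiplicative log-normal with unit mean and exact CV
(`σ = sqrt(log(1+cv²))`, factor `exp(σz − σ²/2)`); default CV 0.1 with 3
replicates, emulating triplicate cytometry means whose error bars scale
with the mean. The generator reproduces: Hill-shaped promoter activation
panels (activities log-spaced over an exact 150-fold span, coefficients
drawn in [1.0, 1.3]), steady-state input–output curves, and pulse-shaped
step-response time courses sharing one pre-equilibrated baseline.

What the generator does **not** emulate: single-cell cytometry
distributions (only means and SDs), growth-phase and dilution artefacts of
the harvesting protocol, autofluorescence background, or day-to-day batch
effects. Passing recovery tests therefore show correctness of the
inference machinery under the stated noise model, not robustness to every
artefact of real cytometry data.

## Problem sizes used in the shipped checks

Chosen as sensible desk-scale sizes: screens use 200 cassettes (restricted
sampling) or 30–40 (unit checks); the Hill-recovery Monte Carlo uses 100
seeded runs; circuit-fit recovery uses two step experiments on a 17-point
grid with 2 restarts; noisy circuit-fit recovery uses 8 seeded runs.

## Known limitations

* Deterministic ODEs only; no stochastic (Gillespie) simulation, so the
  bistable variant's two populations appear as two fixed points, not as a
  bimodal distribution.
* The no-repression and null-PF variants inherit the leak conventions of
  the full model; other deletion semantics (removing terms entirely) would
  change quantitative, not qualitative, outcomes.
* AErr is measured at the end of a finite window (as in the underlying
  time-course protocol); circuits with relaxation times beyond the window
  register as non-adapting even though they would eventually return.
* Global environmental perturbations (growth rate, carbon source, chassis)
  are representable only as global scalings of rate parameters.
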