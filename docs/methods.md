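# Methods

## Model and scope

The package treats the single-species chemostat with Monod–Haldane
(substrate-inhibition) growth μ(S) = mS/(a + S + KS²) in two forms: the
deterministic planar flow

dS/dt = Q(S⁰ − S) − (1/δ) μ(S) x,  dx/dt = μ(S) x − Q x,

and its Itô perturbation with multiplicative white noise σ₁S dB₁, σ₂x dB₂
on the two coordinates.  The noise models environmental fluctuation whose
standard deviation scales with the state ("large populations fluctuate
more"); σᵢ have units 1/√time.  The exact SDE solution is known to stay
strictly positive for positive initial data; the schemes below do not
automatically inherit that property, which drives several design choices.

Everything the package asserts analytically is a closed-form function of
(Q, S⁰, m, a, K, δ, σ₁, σ₂) except one quantity, the supremum constant C
(below), which is computed numerically.

## Deterministic analysis

Interior steady states solve QKS² + (Q − m)S + Qa = 0 with
x* = δ(S⁰ − S*).  Roots are admissible when 0 < S* < S⁰ − 10⁻¹², the
strict upper cut enforcing x* > 0 — without it a root marginally above S⁰
would produce a spurious "equilibrium" with negative biomass.  K = 0
degrades gracefully to Monod kinetics (linear break-even equation).  The
list is empty for Q ≥ m (the root sum (m−Q)/(QK) is then non-positive).

Stability comes from the eigenvalues of the analytic Jacobian.  An
eigenvalue real part below 10⁻⁸·max(Q, m) in magnitude is treated as zero
and the state labelled non-hyperbolic, so parameter sets sitting on a
bifurcation do not get a sign label from rounding noise.
`classify_equilibrium` refuses points whose drift residual exceeds 10⁻⁷
rather than classify a non-equilibrium.

The reference ODE integrator is fixed-step classical RK4 (default
dt = 0.01).  Fixed step, not adaptive, so deterministic and stochastic
trajectories share one time grid and overlay sample-by-sample; the
self-convergence test confirms the expected ~16× endpoint-error drop when
dt halves.

## Stochastic schemes

The primary scheme is Milstein-type: per coordinate with noise σv dB,

v' = v + (drift)Δt + σ v ξ √Δt + (σ²/2) v (ξ²Δt − Δt),

with ξ ~ N(0,1).  The correction term is coded exactly as ξ²Δt − Δt (not
as ΔB² − Δt); the two are equal in exact arithmetic but the former is the
discretisation the package defines, and tests pin it down (ξ = ±1
annihilates the correction, reducing the step to Euler–Maruyama).
Strong order ≈ 1 (Milstein) vs ≈ 1/2 (Euler–Maruyama) is verified on
geometric Brownian motion against its closed form driven by the same
Brownian increments.

**Positivity.**  The update can step a coordinate below zero even though
the exact solution cannot.  Policy: clamp any post-step coordinate below a
floor (default 10⁻¹²) to the floor and count the event in
`Trajectory.floor_hits`, keeping the scheme verbatim while making
pathologies observable.  In the weak-noise regimes the floor is never
touched (asserted in tests).  For work near extinction, where the floor
would contaminate log-slope estimates, `simulate_log_space` integrates the
Itô-corrected drift of (log S, log x) by Euler–Maruyama and exponentiates
back: strictly positive by construction, floor_hits ≡ 0.  The two schemes
agree distributionally (ensemble mean of x(T) within Monte-Carlo error).

**Reproducibility.**  Each path owns `numpy.random.default_rng(seed)`
whose normal stream is consumed as an (n_steps, 2) array, row i holding
(ξ₁ᵢ, ξ₂ᵢ) — ξ₁ before ξ₂ every step.  Ensembles use seeds
base_seed + k and advance all paths at once through the same vectorised
update arithmetic, so ensemble path k is bit-identical to a single run
with seed base_seed + k; the trajectory CSV is byte-reproducible from
(seed, config, parameters).  Default dt = 0.01.

## Ergodicity and extinction checkers

With Q̃ = Q + σ₂²/2 and D = a + S⁰ + KS⁰², stationarity requires

σ₁ < G₀,  σ₁² < min(−2C/S⁰, Q),  Q̃ < mS⁰/D,  σ₂² < 2Q,

where G₀ = min(Q/(Q̃K), 4Q·gap/(b² + 4Q̃K·gap)) with gap = mS⁰ − Q̃D and
b = Q̃ − m + 2Q̃KS⁰, and C = sup_{S>0} G(S)/(a + S + KS²) for the downward
quadratic G(S) defined in `criteria`.  Notes:

* The second branch of G₀ equals the first times
  4Q̃K·gap/(b² + 4Q̃K·gap) ≤ 1, so the minimum always resolves to the
  second branch (equality only at b = 0).  The implementation still takes
  the min as defined; a sweep test documents the identity.
* G₀ is undefined when K = 0 or gap ≤ 0; the checker returns a
  "not applicable" marker and forces a false verdict with the reason
  recorded rather than inventing a number.
* **C is reported twice.**  The supremum is found by a 4000-point grid on
  (10⁻⁶, max(10S⁰, vertex of G + 5S⁰)] refined by bounded scalar
  optimisation (a boundary-hitting maximiser raises a warning, possible
  only when σ₁ is large enough to flip the sign of the leading
  coefficient).  Alongside it, the ratio evaluated exactly at S = S⁰ —
  where G collapses to −σ₁(mS⁰ − Q̃D) — is reported, because 4-dp
  reference tables for these parameter regimes are reproduced by the
  S⁰ evaluation while the true supremum differs in the fourth decimal
  (e.g. 0.0086 vs 0.00851 for the weak-noise preset).  The checker's
  verdict always uses the supremum, the conservative reading of the
  condition; the reproduction report compares the S⁰-evaluated variant.
  The numeric supremum matches a brute-force dense grid (step 10⁻⁵) to
  10⁻⁶ on all preset parameter sets.

Extinction holds almost surely when (i) Q̃ ≥ m or (ii) Q̃ < m and
(1 − 4aK)Q̃² − 2Q̃m + m² < 0.  The reported decay-rate bound is the closed
form sup_S μ(S) − Q̃ = m/(1 + 2√(aK)) − Q̃ (m − Q̃ for K = 0); under
either case it is negative, and under case (i) only g < 0 (not the
stronger g < −Q̃) is asserted.  Consistency across the two theories —
case (i) forces the break-even inequality of the stationarity check to
fail, since mS⁰/D < m ≤ Q̃ — is asserted over a random parameter sweep.

## Long-run estimators

* Pathwise Lyapunov slope: (1/t)·log(x(t)/x(0)) per grid time; samples at
  or below the positivity floor are excluded and counted (they are
  clamping artefacts, and retaining them biases the horizon slope toward
  log(floor/x₀)/T).  For genuinely extinct paths the log-space scheme
  gives the uncontaminated estimate.
* Extinction is operationalised as first passage of x below 10⁻⁶ —
  far below every preset equilibrium (≥ 0.67) and far above the floor.
  Ensemble extinction fractions use the first-passage definition
  ("extinct by t"), which makes them monotone in t.
* Stationary histograms discard a burn-in (default 10% of the horizon; no
  mixing-time theory is available to prefer anything sharper), use
  Freedman–Diaconis bins (robust to the heavy right tail of x under large
  σ₂, overridable), and normalise to unit mass (checked to 10⁻⁹).  An
  optional Gaussian KDE uses Silverman's bandwidth.  The estimator stack
  is validated against the closed-form Ornstein–Uhlenbeck stationary law
  N(c, σ²/2θ) simulated with the same machinery — an oracle independent
  of the chemostat model.
* Ergodic averages are plain rectangle-rule time averages post burn-in;
  a self-consistency test checks window-to-window stabilisation.

## Presets, scenario matrix and problem sizes

Six presets span the regimes: two ergodic (weak/moderate noise, Q = 1),
dilution-driven extinction (Q = 2.2), Haldane-discriminant extinction
(Q = 1.6), noise-induced extinction (Q = 1.1, σ₂ = 1.5, deterministically
persistent), and a bistable noise-free structure (Q = 0.7, S⁰ = 2.4,
m = 3, a = 0.9, K = 1.6).  Parameter values, noise intensities and initial
states are the regimes' standard worked values; the bistable preset's
initial state (0.5, 2.0) is the package's choice of a point in the
interior node's basin, since that regime's outcome is basin-dependent.

The scenario matrix runs the four (Q, σ₂) cells (1, 0.1), (1.1, 1.5),
(1.6, 0.4), (2.2, 0.4) with σ₁ taken from each cell's source regime
(0.05 for Q = 1, 0.3 otherwise); deterministic labels come from the ODE
endpoint, stochastic labels from the ensemble extinction fraction at the
horizon (≥ 1/2 ⇒ Extinction).  Defaults of 200 paths to T = 200 at
dt = 0.01 give fractions of 0 (ergodic cell) and 1.0 (all three extinction
cells) with comfortable margin; the Monte-Carlo tests use the same sizes.
Mean first-passage times in the (1.1, 1.5) and (2.2, 0.4) cells are
statistically indistinguishable at these sizes (≈ 12.9 vs 11.9 with heavy
right tail under strong noise), so "which regime is faster" is asserted
only through the early-time fractions (29% vs 5% extinct by t = 10),
where the ordering is robust.

## Known limitations

* The ergodicity conditions are sufficient, not necessary: a false
  verdict means "not established", not "not ergodic" (the bistable preset
  is the standing example).
* Local stability only: eigenvalue labels say nothing about basins; the
  globally-attracting claim for the unique-equilibrium regime is not
  certified by this package.
* The supremum constant C is numerical; its documented 10⁻⁶ agreement
  with a dense grid holds on the preset sets, not universally.
* Histogram/KDE estimates assume the path survived; floored samples are
  excluded but a heavily clamped path should be re-run in log space.
* No regime-switching (coloured) noise, no jump noise, no periodic
  forcing, no bifurcation continuation, and no basin-of-attraction
  computation.
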