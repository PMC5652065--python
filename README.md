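# stochemostat

Stochastic chemostat dynamics under substrate inhibition: when does a
continuously cultured microbial population persist, and when does
environmental noise — or the dilution rate — drive it extinct?

The package is for microbial ecologists, bioprocess modellers and applied
probabilists who want to go from a parameter set to a verdict (ergodic
persistence vs almost-sure extinction), and from a verdict to simulated
sample paths and long-run statistics, with every quantity reproducible from
a seed.

## The model

A chemostat feeds nutrient at concentration S⁰ into a well-mixed vessel at
dilution rate Q; substrate S and biomass x wash out at the same rate.
Growth follows the Monod–Haldane (substrate-inhibition) response

    μ(S) = m S / (a + S + K S²),

which rises at low substrate and is inhibited at high substrate (maximal at
S = √(a/K) with value m/(1 + 2√(aK))).  Multiplicative white noise on both
state variables gives the Itô SDE

    dS = [Q(S⁰ − S) − (1/δ) μ(S) x] dt + σ₁ S dB₁,
    dx = [μ(S) x − Q x] dt + σ₂ x dB₂,

with δ the yield coefficient and B₁, B₂ independent Brownian motions.

The library provides:

* **Deterministic analysis** (`stochemostat.deterministic`): interior
  equilibria from the quadratic QKS² + (Q−m)S + Qa = 0 with
  x* = δ(S⁰ − S*), the washout state (S⁰, 0), eigenvalue-based stability
  labels, and a fixed-step RK4 reference integrator.
* **Stochastic simulation** (`stochemostat.sde`): the Milstein scheme

      v' = v + (drift) Δt + σ v ξ √Δt + (σ²/2) v (ξ²Δt − Δt),

  plus Euler–Maruyama and a strictly positive log-space variant; seeded,
  vectorised ensembles where path k of an ensemble is bit-identical to a
  single run with seed `base_seed + k`.
* **Analytic condition checkers** (`stochemostat.criteria`): with the
  effective dilution Q̃ = Q + σ₂²/2, the ergodicity conditions
  σ₁ < G₀, σ₁² < min(−2C/S⁰, Q), Q̃ < μ(S⁰), σ₂² < 2Q (a stationary
  distribution exists and time averages converge), and the extinction
  conditions Q̃ ≥ m or (1−4aK)Q̃² − 2Q̃m + m² < 0 (the biomass decays
  exponentially, almost surely, at rate at most m/(1+2√(aK)) − Q̃).
* **Long-run statistics** (`stochemostat.longrun`): stationary histograms
  and kernel densities, ergodic averages, pathwise Lyapunov-slope
  estimates (1/t)·log x(t), first-passage extinction detection and
  ensemble extinction fractions.
* **Presets and a thin CLI** (`stochemostat.presets`, `stochemostat.cli`):
  six named parameter regimes with their reference values, a reproduction
  report, a survival/extinction scenario matrix, and shell commands
  (`simulate`, `equilibria`, `check-ergodicity`, `check-extinction`,
  `stationary`, `extinction`, `reproduce`, `scenario-table`).

## Worked example

```python
from stochemostat import (check_stationarity, check_extinction, preset,
                          simulate, SimulationConfig, stationary_histogram)

pr = preset("stationary-low-noise")     # Q=1, m=2, S0=2, a=0.2, K=0.3,
                                        # delta=1.6, sigma1=0.05, sigma2=0.1
rep = check_stationarity(pr.params, pr.noise)
print(rep.q_tilde, rep.G0, rep.floor_at_S0, rep.break_even, rep.verdict)
```

prints

```
1.005 3.1192358674672542 0.008573529411764707 1.176470588235294 True
```

Q̃ = 1.0050 is below the break-even rate μ(S⁰) = 1.1765, σ₁ = 0.05 is below
G₀ = 3.1192, and σ₁² = 0.0025 is below the floor 0.0086: all four
inequalities hold, so the process is ergodic — biomass persists and
fluctuates around the interior equilibrium.  A long simulated path confirms
it (`python examples/stationary_fluctuations.py`):

```
simulated 1000 time units, floor hits: 0
deterministic interior equilibrium: (S*, x*) = (0.2137, 2.8581)
S: stationary mean=0.2195  variance=0.00112  mode~0.213  (90001 samples)
x: stationary mean=2.8500  variance=0.06627  mode~2.832  (90001 samples)
```

Conversely `python examples/noise_induced_extinction.py` (Q = 1.1,
σ₂ = 1.5) shows noise-induced extinction: Q̃ = 2.2250 ≥ m = 2, and a single
log-space path decays with horizon log-slope −0.9018, consistent with the
analytic rate bound −0.8826 — although the noise-free system with the same
parameters has a globally attracting interior equilibrium (0.2715, 2.7657).

Each script in `examples/` is a short narrative of one capability:
equilibrium structure of the bistable regime, condition checks across all
presets, stationary densities, noise-induced extinction, and the
survival/extinction scenario matrix.

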