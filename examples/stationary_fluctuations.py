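"""Simulate the weak-noise ergodic regime and estimate its stationary law.

One Milstein path to T = 1000 (dt = 0.01); after a burn-in the histogram of
the samples estimates the stationary density, whose mode should sit near
the interior equilibrium of the noise-free flow.
"""

from stochemostat import (
    SimulationConfig,
    interior_equilibria,
    preset,
    simulate,
    stationary_histogram,
)

pr = preset("stationary-low-noise")
cfg = SimulationConfig(dt=0.01, n_steps=100_000, seed=7)
traj = simulate(pr.params, pr.noise, pr.init, cfg)
print(f"simulated {traj.horizon:.0f} time units, floor hits: {traj.floor_hits}")

(eq,) = interior_equilibria(pr.params)
print(f"deterministic interior equilibrium: (S*, x*) = ({eq.S:.4f}, {eq.x:.4f})")

for name, est in stationary_histogram(traj, burn_in=100.0).items():
    centers = 0.5 * (est.bin_edges[:-1] + est.bin_edges[1:])
    mode = centers[est.densities.argmax()]
    print(f"{name}: stationary mean={est.mean:.4f}  variance={est.variance:.5f}  "
          f"mode~{mode:.3f}  ({est.n_samples} samples)")

print("\nMeans and modes hug the deterministic equilibrium: weak noise makes "
      "the process fluctuate around it instead of destroying persistence.")
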