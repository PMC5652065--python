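"""Noise-induced extinction: deterministically persistent, stochastically doomed.

At Q = 1.1 the noise-free chemostat has a globally attracting interior
equilibrium, yet biomass noise sigma2 = 1.5 raises the effective dilution
Qt = Q + sigma2^2/2 = 2.225 above the maximal growth rate m = 2, so the
stochastic biomass decays exponentially almost surely.
"""

from stochemostat import (
    SimulationConfig,
    check_extinction,
    extinction_outcome,
    log_growth_estimate,
    preset,
    simulate_log_space,
)

pr = preset("noise-induced-extinction")
rep = check_extinction(pr.params, pr.noise)
print(f"Qt = {rep.q_tilde:.4f} >= m = {pr.params.m}: extinction case {rep.case}")
print(f"exponential rate bound: {rep.rate_bound:+.4f} (1/time)\n")

# the log-space scheme tracks arbitrarily small biomass without a floor,
# so the pathwise log-slope is uncontaminated by clamping
cfg = SimulationConfig(dt=0.01, n_steps=20_000, seed=3)
traj = simulate_log_space(pr.params, pr.noise, pr.init, cfg)
out = extinction_outcome(traj, threshold=1e-6)
lg = log_growth_estimate(traj)
print(f"single path (seed {cfg.seed}): extinct={out.extinct}, "
      f"first passage below 1e-6 at t={out.first_passage_time}")
print(f"pathwise (1/t) log x(t) at the horizon: {lg.final:+.4f}")
print("\nThe empirical log-slope is negative, consistent with the analytic "
      "bound: exponential die-out driven purely by noise.")
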