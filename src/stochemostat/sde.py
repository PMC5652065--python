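"""Stochastic integration of the chemostat SDE

    dS = [Q (S0 - S) - (1/delta) mu(S) x] dt + sigma1 S dB1,
    dx = [mu(S) x - Q x] dt            + sigma2 x dB2,

with independent Brownian motions B1, B2, using a Milstein-type scheme whose
update is, per coordinate with noise ``sigma v dB``,

    v' = v + (drift) dt + sigma v xi sqrt(dt) + (sigma^2/2) v (xi^2 dt - dt),

``xi`` a standard normal draw.  Euler-Maruyama (drops the correction term)
and a log-space Euler-Maruyama variant (strictly positive by construction)
are provided as alternatives.

Reproducibility contract: every path owns a ``numpy.random.default_rng(seed)``
generator whose normal stream is consumed as an ``(n_steps, 2)`` array, row i
holding ``(xi1_i, xi2_i)`` -- i.e. xi1 is drawn before xi2 at each step.
Ensembles advance all paths simultaneously with the same update arithmetic,
so path k of an ensemble is bit-identical to a single run with seed
``base_seed + k``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .params import ChemostatParams, NoiseParams, State, Trajectory

__all__ = [
    "SimulationConfig",
    "SdeBlowup",
    "milstein_step",
    "simulate",
    "simulate_log_space",
    "simulate_ensemble",
    "simulate_scalar_sde",
]

SCHEMES = ("euler_maruyama", "milstein", "milstein_log")


@dataclass(frozen=True)
class SimulationConfig:
    """Discretisation controls for a stochastic run.

    ``floor`` is the positivity floor: the Milstein/Euler updates can step a
    coordinate below zero even though the exact solution stays positive, so
    any post-step coordinate below ``floor`` is clamped to it and counted in
    ``Trajectory.floor_hits``.  The log-space scheme needs no floor.
    """

    dt: float = 0.01
    n_steps: int = 1000
    seed: int = 0
    floor: float = 1e-12
    scheme: str = "milstein"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.floor <= 0:
            raise ValueError("floor must be > 0")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")


class SdeBlowup(RuntimeError):
    """Raised when a stochastic step produces a non-finite state."""

    def __init__(self, step: int):
        super().__init__(f"non-finite state after step {step}")
        self.step = step


def _advance(S, x, p: ChemostatParams, n: NoiseParams, dt, xi1, xi2, scheme: str):
    """One update of the chosen scheme; S, x, xi1, xi2 may be arrays."""
    sqdt = math.sqrt(dt)
    if scheme == "milstein_log":
        den = p.a + S + p.K * S * S
        dlogS = (
            p.Q * (p.S0 / S - 1.0) - p.m * x / (p.delta * den) - 0.5 * n.sigma1**2
        ) * dt + n.sigma1 * xi1 * sqdt
        dlogx = (p.m * S / den - p.Q - 0.5 * n.sigma2**2) * dt + n.sigma2 * xi2 * sqdt
        return S * np.exp(dlogS), x * np.exp(dlogx)
    mu = p.m * S / (p.a + S + p.K * S * S)
    dS = (p.Q * (p.S0 - S) - mu * x / p.delta) * dt + n.sigma1 * S * xi1 * sqdt
    dx = (mu * x - p.Q * x) * dt + n.sigma2 * x * xi2 * sqdt
    if scheme == "milstein":
        # correction written exactly as (xi^2 dt - dt), not (dB^2 - dt)
        dS = dS + 0.5 * n.sigma1**2 * S * (xi1 * xi1 * dt - dt)
        dx = dx + 0.5 * n.sigma2**2 * x * (xi2 * xi2 * dt - dt)
    return S + dS, x + dx


def milstein_step(
    s: State,
    p: ChemostatParams,
    n: NoiseParams,
    dt: float,
    xi1: float,
    xi2: float,
    floor: float = 1e-12,
) -> State:
    """A single Milstein update from state ``s`` given normal draws xi1, xi2.

    The positivity policy (clamp to ``floor``) is applied to the result.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not all(math.isfinite(v) for v in (s.S, s.x, xi1, xi2)):
        raise ValueError("non-finite input to milstein_step")
    S1, x1 = _advance(s.S, s.x, p, n, dt, xi1, xi2, "milstein")
    return State(max(float(S1), floor), max(float(x1), floor))


def _run_batch(
    p: ChemostatParams,
    n: NoiseParams,
    init: State,
    cfg: SimulationConfig,
    seeds: list[int],
) -> list[Trajectory]:
    n_paths = len(seeds)
    n_steps = cfg.n_steps
    xi = np.empty((n_paths, n_steps, 2))
    for k, sd in enumerate(seeds):
        xi[k] = np.random.default_rng(sd).standard_normal((n_steps, 2))

    if cfg.scheme == "milstein_log" and (init.S <= 0 or init.x <= 0):
        raise ValueError("log-space scheme requires strictly positive initial state")

    S_paths = np.empty((n_paths, n_steps + 1))
    x_paths = np.empty((n_paths, n_steps + 1))
    S_paths[:, 0] = init.S
    x_paths[:, 0] = init.x
    floor_hits = np.zeros(n_paths, dtype=int)
    S = np.full(n_paths, float(init.S))
    x = np.full(n_paths, float(init.x))
    for i in range(n_steps):
        S, x = _advance(S, x, p, n, cfg.dt, xi[:, i, 0], xi[:, i, 1], cfg.scheme)
        if not (np.all(np.isfinite(S)) and np.all(np.isfinite(x))):
            raise SdeBlowup(i + 1)
        if cfg.scheme != "milstein_log":
            lowS = S < cfg.floor
            lowx = x < cfg.floor
            if lowS.any() or lowx.any():
                floor_hits += lowS.astype(int) + lowx.astype(int)
                S = np.where(lowS, cfg.floor, S)
                x = np.where(lowx, cfg.floor, x)
        S_paths[:, i + 1] = S
        x_paths[:, i + 1] = x

    times = np.arange(n_steps + 1) * cfg.dt
    return [
        Trajectory(
            times=times,
            S_path=S_paths[k],
            x_path=x_paths[k],
            scheme=cfg.scheme,
            dt=cfg.dt,
            seed=seeds[k],
            floor_hits=int(floor_hits[k]),
        )
        for k in range(n_paths)
    ]


def simulate(
    p: ChemostatParams, n: NoiseParams, init: State, cfg: SimulationConfig
) -> Trajectory:
    """Integrate one path of the stochastic chemostat.

    The same ``(seed, cfg, params)`` always reproduces the identical path.
    """
    return _run_batch(p, n, init, cfg, [cfg.seed])[0]


def simulate_log_space(
    p: ChemostatParams, n: NoiseParams, init: State, cfg: SimulationConfig
) -> Trajectory:
    """Integrate one path with Euler-Maruyama on ``(log S, log x)``.

    The drift in log coordinates picks up the Ito corrections
    ``-sigma_i^2/2``; exponentiating back guarantees strict positivity, so
    ``floor_hits`` is always 0.  Requires a strictly positive initial state.
    """
    return _run_batch(p, n, init, replace(cfg, scheme="milstein_log"), [cfg.seed])[0]


def simulate_ensemble(
    p: ChemostatParams,
    n: NoiseParams,
    init: State,
    cfg: SimulationConfig,
    n_paths: int,
    base_seed: int,
) -> list[Trajectory]:
    """Independent paths with seeds ``base_seed + k`` for k = 0..n_paths-1."""
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    return _run_batch(p, n, init, cfg, [base_seed + k for k in range(n_paths)])


def simulate_scalar_sde(
    drift,
    diffusion,
    y0: float,
    dt: float,
    n_steps: int,
    seed: int | None = None,
    increments: np.ndarray | None = None,
    scheme: str = "milstein",
    diffusion_prime=None,
):
    """Generic scalar SDE integrator ``dY = f(Y) dt + b(Y) dB``.

    Used for validating the stepping machinery against processes with known
    laws (geometric Brownian motion, Ornstein-Uhlenbeck).  ``increments`` may
    supply the Brownian increments explicitly (shape ``(n_steps,)``), e.g. a
    coarsened fine path for strong-convergence studies; otherwise they are
    drawn from ``default_rng(seed)``.  The Milstein scheme needs
    ``diffusion_prime`` (db/dy); Euler-Maruyama does not.

    Returns ``(times, y)`` arrays of length ``n_steps + 1``.
    """
    if scheme not in ("euler_maruyama", "milstein"):
        raise ValueError("scheme must be 'euler_maruyama' or 'milstein'")
    if scheme == "milstein" and diffusion_prime is None:
        raise ValueError("milstein scheme requires diffusion_prime")
    if increments is None:
        if seed is None:
            raise ValueError("either increments or seed must be given")
        increments = np.random.default_rng(seed).standard_normal(n_steps) * math.sqrt(dt)
    increments = np.asarray(increments, dtype=float)
    if increments.shape[0] != n_steps:
        raise ValueError("increments must have length n_steps")
    y = np.empty(n_steps + 1)
    y[0] = y0
    for i in range(n_steps):
        yi = y[i]
        dB = increments[i]
        step = drift(yi) * dt + diffusion(yi) * dB
        if scheme == "milstein":
            step += 0.5 * diffusion(yi) * diffusion_prime(yi) * (dB * dB - dt)
        y[i + 1] = yi + step
        if not math.isfinite(y[i + 1]):
            raise SdeBlowup(i + 1)
    return np.arange(n_steps + 1) * dt, y
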