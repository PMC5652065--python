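"""Empirical long-run statistics of simulated trajectories.

Covers the observable side of the theory: histogram/kernel estimates of the
stationary law, ergodic (time) averages, the pathwise exponential growth
rate ``(1/t) log x(t)`` whose negativity signals extinction, first-passage
detection below an extinction threshold, and ensemble extinction fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import Trajectory

__all__ = [
    "LogGrowthEstimate",
    "log_growth_estimate",
    "ExtinctionOutcome",
    "extinction_outcome",
    "StationaryEstimate",
    "stationary_histogram",
    "ergodic_average",
    "ensemble_extinction_fraction",
    "extinction_fraction_series",
]

#: Below this biomass concentration a path counts as extinct: far below any
#: realistic equilibrium, far above the simulator's positivity floor.
DEFAULT_EXTINCTION_THRESHOLD = 1e-6


@dataclass(frozen=True)
class LogGrowthEstimate:
    """Pathwise Lyapunov-exponent estimate ``(1/t) log(x(t)/x(0))``."""

    times: np.ndarray          # t > 0 where the estimate is defined
    slope: np.ndarray          # (1/t) log(x(t)/x(0)) at those times
    final: float               # the estimate at the horizon
    n_excluded: int            # samples at/below the floor, left out


def log_growth_estimate(
    traj: Trajectory, floor: float | None = None
) -> LogGrowthEstimate:
    """Estimate the exponential growth/decay rate of the biomass path.

    A negative final value is the empirical signature of exponential
    extinction.  Samples at or below ``floor`` (clamped artefacts of the
    positivity policy) are excluded from the series and counted.
    """
    x0 = float(traj.x_path[0])
    if x0 <= 0:
        raise ValueError("x(0) must be strictly positive")
    t = traj.times[1:]
    x = traj.x_path[1:]
    keep = x > (floor if floor is not None else 0.0)
    n_excluded = int(np.sum(~keep))
    if not np.any(keep):
        raise ValueError("no usable samples above the floor")
    slope = np.log(x[keep] / x0) / t[keep]
    # the horizon estimate uses the last usable sample
    final = float(slope[-1])
    return LogGrowthEstimate(
        times=t[keep], slope=slope, final=final, n_excluded=n_excluded
    )


@dataclass(frozen=True)
class ExtinctionOutcome:
    extinct: bool
    first_passage_time: float | None
    final_log_slope: float


def extinction_outcome(
    traj: Trajectory, threshold: float = DEFAULT_EXTINCTION_THRESHOLD
) -> ExtinctionOutcome:
    """First crossing of the biomass below ``threshold``, if any."""
    below = traj.x_path < threshold
    if below.any():
        idx = int(np.argmax(below))
        fpt = float(traj.times[idx])
        extinct = True
    else:
        fpt = None
        extinct = False
    lg = log_growth_estimate(traj)
    return ExtinctionOutcome(
        extinct=extinct, first_passage_time=fpt, final_log_slope=lg.final
    )


@dataclass(frozen=True)
class StationaryEstimate:
    """Normalized histogram of post-burn-in samples of one coordinate."""

    variable: str
    bin_edges: np.ndarray
    densities: np.ndarray
    burn_in: float
    n_samples: int
    mean: float
    variance: float
    n_floored: int = 0

    def kde(self, bw_method: str = "silverman"):
        """Gaussian kernel density (callable) over the retained samples."""
        from scipy.stats import gaussian_kde

        return gaussian_kde(self._samples, bw_method=bw_method)

    # retained samples kept for the KDE; not part of the dataclass equality
    def __post_init__(self):
        object.__setattr__(self, "_samples", None)


def _one_histogram(
    name: str, samples: np.ndarray, burn_in: float, n_bins, n_floored: int
) -> StationaryEstimate:
    if len(samples) < 100:
        raise ValueError(
            f"only {len(samples)} post-burn-in samples for {name}; need >= 100"
        )
    if np.ptp(samples) == 0:
        # constant path: a single occupied bin carrying all the mass
        c = samples[0]
        width = max(abs(c) * 1e-6, 1e-12)
        edges = np.array([c - width / 2, c + width / 2])
        dens = np.array([1.0 / width])
    else:
        bins = n_bins if n_bins is not None else "fd"
        dens, edges = np.histogram(samples, bins=bins, density=True)
    est = StationaryEstimate(
        variable=name,
        bin_edges=edges,
        densities=dens,
        burn_in=burn_in,
        n_samples=len(samples),
        mean=float(np.mean(samples)),
        variance=float(np.var(samples, ddof=1)),
        n_floored=n_floored,
    )
    object.__setattr__(est, "_samples", samples)
    return est


def stationary_histogram(
    traj: Trajectory,
    burn_in: float | None = None,
    n_bins: int | None = None,
    floor: float | None = None,
) -> dict[str, StationaryEstimate]:
    """Histogram estimate of the stationary law of ``S`` and ``x``.

    ``burn_in`` (time discarded from the start; default 10% of the horizon)
    removes the transient.  Bin edges follow the Freedman-Diaconis rule
    unless ``n_bins`` overrides.  Samples clamped at the positivity floor are
    artefacts of the clamping policy and are excluded (pass ``floor`` to
    enable this) and counted in ``n_floored``.
    """
    if burn_in is None:
        burn_in = 0.1 * traj.horizon
    if burn_in >= traj.horizon:
        raise ValueError("burn_in must be smaller than the trajectory horizon")
    keep_t = traj.times >= burn_in
    out = {}
    for name, path in (("S", traj.S_path), ("x", traj.x_path)):
        samples = path[keep_t]
        if floor is not None:
            ok = samples > floor
            n_floored = int(np.sum(~ok))
            samples = samples[ok]
        else:
            n_floored = 0
        out[name] = _one_histogram(name, samples, burn_in, n_bins, n_floored)
    return out


def ergodic_average(traj: Trajectory, func, burn_in: float | None = None) -> float:
    """Time average of ``func(S, x)`` over the post-burn-in path.

    ``func`` must be vectorised over arrays of S and x; the average is the
    rectangle rule on the uniform grid, i.e. the plain mean of the samples.
    Under ergodicity this converges to the state-space mean of ``func``
    under the stationary law as the horizon grows.
    """
    if burn_in is None:
        burn_in = 0.1 * traj.horizon
    if burn_in >= traj.horizon:
        raise ValueError("burn_in must be smaller than the trajectory horizon")
    keep = traj.times >= burn_in
    vals = np.asarray(func(traj.S_path[keep], traj.x_path[keep]), dtype=float)
    if vals.shape != traj.S_path[keep].shape:
        vals = np.broadcast_to(vals, traj.S_path[keep].shape)
    return float(np.mean(vals))


def ensemble_extinction_fraction(
    ensemble: list[Trajectory],
    threshold: float = DEFAULT_EXTINCTION_THRESHOLD,
    t: float | None = None,
) -> float:
    """Fraction of paths whose biomass has dropped below ``threshold`` by
    time ``t`` (first-passage definition, hence monotone non-decreasing
    in ``t`` on a fixed ensemble).

    ``t`` defaults to the common horizon.  All trajectories must share a
    grid containing ``t``.
    """
    if t is None:
        t = ensemble[0].horizon
    frac = 0
    for traj in ensemble:
        idx = int(round(t / traj.dt))
        if idx < 0 or idx >= len(traj):
            raise ValueError(f"time {t} outside trajectory grid")
        if abs(traj.times[idx] - t) > 1e-9 * max(1.0, abs(t)):
            raise ValueError(f"time {t} not on the trajectory grid")
        frac += bool(np.min(traj.x_path[: idx + 1]) < threshold)
    return frac / len(ensemble)


def extinction_fraction_series(
    ensemble: list[Trajectory], threshold: float = DEFAULT_EXTINCTION_THRESHOLD
) -> tuple[np.ndarray, np.ndarray]:
    """Extinction fraction at every grid time (first-passage definition,
    so the series is monotone non-decreasing)."""
    times = ensemble[0].times
    below = np.zeros(len(times))
    for traj in ensemble:
        if len(traj) != len(times):
            raise ValueError("all trajectories must share a time grid")
        below += np.minimum.accumulate(traj.x_path) < threshold
    return times, below / len(ensemble)
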