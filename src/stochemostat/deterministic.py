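"""Deterministic Monod-Haldane chemostat: response function, vector field,
equilibria, linear stability and a fixed-step reference ODE integrator.

The flow is

    dS/dt = Q (S0 - S) - (1/delta) mu(S) x,
    dx/dt = mu(S) x - Q x,        mu(S) = m S / (a + S + K S^2).

Interior steady states solve the quadratic ``Q K S^2 + (Q - m) S + Q a = 0``
(which requires ``Q < m``) together with ``x* = delta (S0 - S*)``; the washout
state ``(S0, 0)`` always exists and is a stable node exactly when the dilution
rate exceeds the break-even growth rate ``mu(S0)``.
"""

from __future__ import annotations

import math

import numpy as np

from .params import ChemostatParams, Equilibrium, State, Trajectory

__all__ = [
    "growth_rate",
    "growth_rate_prime",
    "growth_rate_peak",
    "NoInteriorMaximum",
    "drift",
    "jacobian",
    "interior_equilibria",
    "washout_equilibrium",
    "classify_equilibrium",
    "integrate_ode",
    "OdeBlowup",
]

#: An eigenvalue real part smaller than this multiple of max(Q, m) is treated
#: as zero, so bifurcation-adjacent parameters classify as non-hyperbolic
#: instead of flipping sign on rounding noise.
HYPERBOLICITY_RTOL = 1e-8

#: Residual tolerance for accepting a point as a steady state.
EQUILIBRIUM_RESIDUAL_TOL = 1e-7


class NoInteriorMaximum(ValueError):
    """Raised when K = 0: mu is monotone increasing and its supremum is m,
    attained only in the limit S -> infinity."""


class OdeBlowup(RuntimeError):
    """Raised when the ODE integration produces a non-finite state."""

    def __init__(self, t: float):
        super().__init__(f"non-finite state at t = {t:g}")
        self.t = t


def growth_rate(S, p: ChemostatParams):
    """Monod-Haldane specific growth rate ``m S / (a + S + K S^2)``.

    Accepts a scalar or array of substrate concentrations ``S >= 0``.
    """
    S_arr = np.asarray(S, dtype=float)
    if np.any(S_arr < 0):
        raise ValueError("substrate concentration must be >= 0")
    out = p.m * S_arr / (p.a + S_arr + p.K * S_arr * S_arr)
    return float(out) if np.isscalar(S) or S_arr.ndim == 0 else out


def growth_rate_prime(S, p: ChemostatParams):
    """Derivative ``mu'(S) = m (a - K S^2) / (a + S + K S^2)^2``."""
    S_arr = np.asarray(S, dtype=float)
    den = p.a + S_arr + p.K * S_arr * S_arr
    out = p.m * (p.a - p.K * S_arr * S_arr) / (den * den)
    return float(out) if np.isscalar(S) or S_arr.ndim == 0 else out


def growth_rate_peak(p: ChemostatParams) -> tuple[float, float]:
    """Location and value of the global maximum of the response over S > 0.

    For K > 0 the response peaks at ``S = sqrt(a/K)`` with value
    ``m / (1 + 2 sqrt(a K))``.  For K = 0 there is no interior maximum
    (:class:`NoInteriorMaximum` is raised; the supremum is ``m``).
    """
    if p.K == 0:
        raise NoInteriorMaximum(
            "K = 0: Monod kinetics has no interior maximum; supremum is m"
        )
    S_peak = math.sqrt(p.a / p.K)
    mu_peak = p.m / (1.0 + 2.0 * math.sqrt(p.a * p.K))
    return S_peak, mu_peak


def drift(s: State, p: ChemostatParams) -> tuple[float, float]:
    """Deterministic vector field ``(dS/dt, dx/dt)`` at state ``s``."""
    mu = growth_rate(s.S, p)
    return (p.Q * (p.S0 - s.S) - mu * s.x / p.delta, mu * s.x - p.Q * s.x)


def jacobian(s: State, p: ChemostatParams) -> np.ndarray:
    """Analytic Jacobian of the vector field at ``s`` (2x2 array)."""
    mu = growth_rate(s.S, p)
    mup = growth_rate_prime(s.S, p)
    return np.array(
        [
            [-p.Q - mup * s.x / p.delta, -mu / p.delta],
            [mup * s.x, mu - p.Q],
        ]
    )


def _stability_label(eigenvalues: np.ndarray, p: ChemostatParams) -> str:
    tol = HYPERBOLICITY_RTOL * max(p.Q, p.m)
    re = eigenvalues.real
    im = eigenvalues.imag
    if np.any(np.abs(re) < tol):
        return "non-hyperbolic"
    complex_pair = np.any(np.abs(im) > tol)
    if np.all(re < 0):
        return "stable spiral" if complex_pair else "stable node"
    if np.all(re > 0):
        return "unstable spiral" if complex_pair else "unstable node"
    return "saddle"


def _make_equilibrium(S: float, x: float, kind: str, p: ChemostatParams) -> Equilibrium:
    ev = np.linalg.eigvals(jacobian(State(S, x), p))
    ev = ev[np.argsort(ev.real)]
    return Equilibrium(
        S=S,
        x=x,
        kind=kind,
        eigenvalues=(complex(ev[0]), complex(ev[1])),
        stability=_stability_label(ev, p),
    )


def interior_equilibria(p: ChemostatParams) -> list[Equilibrium]:
    """All interior steady states, sorted by their substrate coordinate.

    Roots S* of ``Q K S^2 + (Q - m) S + Q a = 0`` are admissible when
    ``0 < S* < S0`` (strictly, so that ``x* = delta (S0 - S*) > 0``); the list
    is empty when ``Q >= m`` or no root is admissible.  ``K = 0`` degenerates
    to the linear break-even equation of Monod kinetics.
    """
    if p.Q >= p.m:
        return []
    if p.K == 0:
        roots = [p.Q * p.a / (p.m - p.Q)]
    else:
        roots = list(np.roots([p.Q * p.K, p.Q - p.m, p.Q * p.a]))
        if any(abs(r.imag) > 0 for r in np.atleast_1d(np.asarray(roots, complex))):
            roots = [r.real for r in roots if abs(r.imag) < 1e-12]
        else:
            roots = [float(np.real(r)) for r in roots]
    out = []
    for S_star in sorted(roots):
        if 0 < S_star < p.S0 - 1e-12:
            x_star = p.delta * (p.S0 - S_star)
            out.append(_make_equilibrium(float(S_star), float(x_star), "interior", p))
    return out


def washout_equilibrium(p: ChemostatParams) -> Equilibrium:
    """The biomass-free steady state ``(S0, 0)``.

    A stable node when ``Q > mu(S0)`` (the culture washes out), a saddle when
    ``Q < mu(S0)``, non-hyperbolic at equality.
    """
    return _make_equilibrium(p.S0, 0.0, "washout", p)


def classify_equilibrium(S: float, x: float, p: ChemostatParams) -> str:
    """Stability label of a steady state given by its coordinates.

    The point must actually be a steady state: the drift residual (max-norm)
    must be below ``EQUILIBRIUM_RESIDUAL_TOL``, else a ``ValueError`` reports
    the residual.
    """
    f = drift(State(S, x), p)
    residual = max(abs(f[0]), abs(f[1]))
    if residual > EQUILIBRIUM_RESIDUAL_TOL:
        raise ValueError(
            f"({S}, {x}) is not a steady state: drift residual {residual:.3e}"
        )
    ev = np.linalg.eigvals(jacobian(State(S, x), p))
    return _stability_label(ev, p)


def all_equilibria(p: ChemostatParams) -> list[Equilibrium]:
    """Washout equilibrium followed by the interior ones (sorted by S*)."""
    return [washout_equilibrium(p)] + interior_equilibria(p)


def integrate_ode(
    p: ChemostatParams, init: State, t_end: float, dt: float = 0.01
) -> Trajectory:
    """Classic fixed-step 4th-order Runge-Kutta solution of the flow.

    A fixed step keeps the grid identical to the stochastic schemes so that
    deterministic and stochastic paths overlay sample-by-sample.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_end < dt:
        raise ValueError("t_end must be >= dt")
    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    S = np.empty(n_steps + 1)
    x = np.empty(n_steps + 1)
    S[0], x[0] = init.S, init.x

    def f(Sv, xv):
        mu = p.m * Sv / (p.a + Sv + p.K * Sv * Sv)
        return p.Q * (p.S0 - Sv) - mu * xv / p.delta, mu * xv - p.Q * xv

    for i in range(n_steps):
        Si, xi = S[i], x[i]
        k1S, k1x = f(Si, xi)
        k2S, k2x = f(Si + 0.5 * dt * k1S, xi + 0.5 * dt * k1x)
        k3S, k3x = f(Si + 0.5 * dt * k2S, xi + 0.5 * dt * k2x)
        k4S, k4x = f(Si + dt * k3S, xi + dt * k3x)
        S[i + 1] = Si + dt * (k1S + 2 * k2S + 2 * k3S + k4S) / 6.0
        x[i + 1] = xi + dt * (k1x + 2 * k2x + 2 * k3x + k4x) / 6.0
        if not (math.isfinite(S[i + 1]) and math.isfinite(x[i + 1])):
            raise OdeBlowup(times[i + 1])
    return Trajectory(times=times, S_path=S, x_path=x, scheme="rk4", dt=dt)
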