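"""Closed-form / numeric evaluation of the stationarity (ergodicity) and
extinction conditions for the stochastic chemostat.

Stationarity conditions.  With the effective dilution rate
``Qt = Q + sigma2^2/2`` and ``D = a + S0 + K S0^2`` (the response denominator
at the input concentration), define the downward quadratic

    G(S) = -(Q - sigma1 Qt K)(S - S0)^2
           + sigma1 (Qt - m + 2 Qt K S0)(S - S0)
           - sigma1 [m S0 - Qt D],

and ``C = sup_{S>0} G(S)/(a + S + K S^2)``.  A stationary distribution exists
and the process is ergodic when all four of

    sigma1 < G0,    sigma1^2 < min(-2C/S0, Q),
    Qt < m S0 / D,  sigma2^2 < 2 Q

hold, where ``G0`` is the threshold ``min(Q/(Qt K), 4Q[m S0 - Qt D] /
((Qt - m + 2 Qt K S0)^2 + 4 Qt K [m S0 - Qt D]))``.

Extinction conditions.  The biomass dies out exponentially almost surely
when either (i) ``Qt >= m`` or (ii) ``Qt < m`` and
``(1 - 4 a K) Qt^2 - 2 Qt m + m^2 < 0``; in both cases
``limsup (1/t) log x(t) <= sup_S [mu(S) - Qt] = m/(1 + 2 sqrt(aK)) - Qt``.

The supremum ``C`` is found numerically (grid scan plus bounded refinement);
everything else is closed-form.  For reconciliation with hand evaluations,
the ratio ``G(S)/(a+S+KS^2)`` evaluated at ``S = S0`` exactly is reported
alongside the supremum, and the ergodicity floor ``min(-2C/S0, Q)`` is
returned in both variants; the checker's verdict always uses the supremum
(the conservative reading of the condition).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .deterministic import growth_rate, growth_rate_peak, NoInteriorMaximum
from .params import ChemostatParams, NoiseParams

__all__ = [
    "effective_dilution",
    "response_denominator",
    "break_even_input",
    "G_of_S",
    "C_sup",
    "C_at_S0",
    "ErgodicityFloor",
    "ergodicity_floor",
    "G0_threshold",
    "lambda_margin",
    "ErgodicityReport",
    "check_stationarity",
    "ExtinctionReport",
    "check_extinction",
]


def effective_dilution(p: ChemostatParams, n: NoiseParams) -> float:
    """Noise-corrected removal rate ``Qt = Q + sigma2^2 / 2``."""
    return p.Q + 0.5 * n.sigma2**2


def response_denominator(p: ChemostatParams) -> float:
    """``D = a + S0 + K S0^2``, the Monod-Haldane denominator at S = S0."""
    return p.a + p.S0 + p.K * p.S0**2


def break_even_input(p: ChemostatParams) -> float:
    """Growth rate at the input concentration, ``mu(S0) = m S0 / D``.

    The dilution rate is compared against this value to decide washout.
    """
    return growth_rate(p.S0, p)


def G_of_S(S, p: ChemostatParams, n: NoiseParams):
    """The auxiliary quadratic ``G(S)`` underlying the stationarity check.

    Vectorised over ``S``; for sigma1 = 0 it reduces to ``-Q (S - S0)^2``.
    """
    qt = effective_dilution(p, n)
    D = response_denominator(p)
    A = p.Q - n.sigma1 * qt * p.K
    b = n.sigma1 * (qt - p.m + 2.0 * qt * p.K * p.S0)
    c = n.sigma1 * (p.m * p.S0 - qt * D)
    u = np.asarray(S, dtype=float) - p.S0
    out = -A * u * u + b * u - c
    return float(out) if np.isscalar(S) or out.ndim == 0 else out


def _ratio(S, p, n):
    return G_of_S(S, p, n) / (p.a + np.asarray(S, float) + p.K * np.asarray(S, float) ** 2)


def C_sup(p: ChemostatParams, n: NoiseParams, grid_points: int = 4000) -> tuple[float, float]:
    """Numeric supremum of ``G(S)/(a + S + K S^2)`` over S > 0.

    Returns ``(value, argmax)``.  The search domain is ``(1e-6, S_hi]`` with
    ``S_hi = max(10 S0, vertex of G + 5 S0)``; a coarse grid locates the
    maximum and a bounded scalar optimisation refines it.  The leading
    coefficient of G turns non-negative for very large sigma1, in which case
    the ratio no longer decays at infinity and a boundary warning is issued.
    """
    if n.sigma1 == 0:
        # G = -Q (S - S0)^2 <= 0 with its zero at S0: supremum 0 at S = S0.
        return 0.0, p.S0
    lo = 1e-6
    qt = effective_dilution(p, n)
    A = p.Q - n.sigma1 * qt * p.K
    hi = 10.0 * p.S0
    if A > 0:
        b = n.sigma1 * (qt - p.m + 2.0 * qt * p.K * p.S0)
        vertex = p.S0 + b / (2.0 * A)
        hi = max(hi, vertex + 5.0 * p.S0)
    grid = np.linspace(lo, hi, grid_points)
    vals = _ratio(grid, p, n)
    k = int(np.argmax(vals))
    best_val, best_arg = float(vals[k]), float(grid[k])
    if k in (0, grid_points - 1):
        warnings.warn(
            "supremum search hit the domain boundary; the reported C may "
            "not be the global supremum",
            stacklevel=2,
        )
    a_br = grid[max(k - 1, 0)]
    b_br = grid[min(k + 1, grid_points - 1)]
    res = minimize_scalar(
        lambda S: -_ratio(S, p, n), bounds=(a_br, b_br), method="bounded",
        options={"xatol": 1e-12},
    )
    if res.success and -res.fun > best_val:
        best_val, best_arg = float(-res.fun), float(res.x)
    return best_val, best_arg


def C_at_S0(p: ChemostatParams, n: NoiseParams) -> float:
    """The ratio ``G(S)/(a + S + K S^2)`` evaluated exactly at ``S = S0``.

    At S0 the quadratic and linear terms of G vanish, leaving
    ``-sigma1 (m S0 - Qt D) / D``.
    """
    return G_of_S(p.S0, p, n) / response_denominator(p)


@dataclass(frozen=True)
class ErgodicityFloor:
    """``min(-2C/S0, Q)`` under the two evaluations of C."""

    from_sup: float  # C = sup of the ratio (used by the checker verdict)
    at_S0: float     # C = ratio at S = S0 (closed form)


def ergodicity_floor(p: ChemostatParams, n: NoiseParams) -> ErgodicityFloor:
    """The bound that ``sigma1^2`` must stay below for stationarity."""
    c_sup, _ = C_sup(p, n)
    return ErgodicityFloor(
        from_sup=min(-2.0 * c_sup / p.S0, p.Q),
        at_S0=min(-2.0 * C_at_S0(p, n) / p.S0, p.Q),
    )


def G0_threshold(p: ChemostatParams, n: NoiseParams) -> float | None:
    """The noise threshold ``G0`` that ``sigma1`` must stay below.

    Returns ``None`` ("not applicable") when ``K = 0`` or ``m S0 <= Qt D``,
    in which case the second branch of the minimum is meaningless.
    """
    qt = effective_dilution(p, n)
    D = response_denominator(p)
    gap = p.m * p.S0 - qt * D
    if p.K <= 0 or gap <= 0:
        return None
    first = p.Q / (qt * p.K)
    b = qt - p.m + 2.0 * qt * p.K * p.S0
    second = 4.0 * p.Q * gap / (b * b + 4.0 * qt * p.K * gap)
    return min(first, second)


def lambda_margin(p: ChemostatParams, n: NoiseParams) -> float:
    """``lambda = -C - (S0/2) sigma1^2`` with C the true supremum.

    Positive exactly when the second stationarity inequality holds with room
    to spare; it is the drift margin that makes the Lyapunov argument close.
    """
    c_sup, _ = C_sup(p, n)
    return -c_sup - 0.5 * p.S0 * n.sigma1**2


@dataclass(frozen=True)
class ErgodicityReport:
    """Every quantity entering the stationarity check, with verdicts."""

    q_tilde: float
    D: float
    break_even: float
    G0: float | None
    C_sup: float
    C_argmax: float
    C_at_S0: float
    floor_from_sup: float
    floor_at_S0: float
    lambda_margin: float
    checks: dict
    verdict: bool
    reason: str | None = None

    def as_dict(self) -> dict:
        return {
            "q_tilde": self.q_tilde,
            "D": self.D,
            "break_even": self.break_even,
            "G0": self.G0,
            "C_sup": self.C_sup,
            "C_argmax": self.C_argmax,
            "C_at_S0": self.C_at_S0,
            "floor_from_sup": self.floor_from_sup,
            "floor_at_S0": self.floor_at_S0,
            "lambda_margin": self.lambda_margin,
            "checks": dict(self.checks),
            "verdict": self.verdict,
            "reason": self.reason,
        }


def check_stationarity(p: ChemostatParams, n: NoiseParams) -> ErgodicityReport:
    """Evaluate the four stationarity inequalities and their conjunction.

    The verdict uses the true supremum for C.  A "not applicable" ``G0``
    forces a false verdict with the reason recorded.
    """
    qt = effective_dilution(p, n)
    D = response_denominator(p)
    be = break_even_input(p)
    g0 = G0_threshold(p, n)
    c_sup, c_arg = C_sup(p, n)
    c_s0 = C_at_S0(p, n)
    floor_sup = min(-2.0 * c_sup / p.S0, p.Q)
    floor_s0 = min(-2.0 * c_s0 / p.S0, p.Q)
    lam = -c_sup - 0.5 * p.S0 * n.sigma1**2

    reason = None
    if g0 is None:
        checks = {
            "sigma1_lt_G0": False,
            "sigma1sq_lt_min": n.sigma1**2 < floor_sup,
            "qtilde_lt_breakeven": qt < be,
            "sigma2sq_lt_2Q": n.sigma2**2 < 2.0 * p.Q,
        }
        reason = "G0 not applicable (K = 0 or m*S0 <= Qt*D); verdict forced false"
    else:
        checks = {
            "sigma1_lt_G0": n.sigma1 < g0,
            "sigma1sq_lt_min": n.sigma1**2 < floor_sup,
            "qtilde_lt_breakeven": qt < be,
            "sigma2sq_lt_2Q": n.sigma2**2 < 2.0 * p.Q,
        }
    return ErgodicityReport(
        q_tilde=qt,
        D=D,
        break_even=be,
        G0=g0,
        C_sup=c_sup,
        C_argmax=c_arg,
        C_at_S0=c_s0,
        floor_from_sup=floor_sup,
        floor_at_S0=floor_s0,
        lambda_margin=lam,
        checks=checks,
        verdict=all(checks.values()) and g0 is not None,
        reason=reason,
    )


@dataclass(frozen=True)
class ExtinctionReport:
    """Extinction-criterion quantities and verdict.

    ``case`` is ``"i"`` (effective dilution at least the maximal growth
    rate), ``"ii"`` (the Haldane discriminant condition), or ``"none"``.
    ``rate_bound = sup_S mu(S) - Qt`` bounds the exponential decay rate of
    the biomass (it is reported regardless of the verdict).
    """

    q_tilde: float
    case: str
    haldane_discriminant: float
    rate_bound: float
    verdict: bool

    def as_dict(self) -> dict:
        return {
            "q_tilde": self.q_tilde,
            "case": self.case,
            "haldane_discriminant": self.haldane_discriminant,
            "rate_bound": self.rate_bound,
            "verdict": self.verdict,
        }


def check_extinction(p: ChemostatParams, n: NoiseParams) -> ExtinctionReport:
    """Decide almost-sure exponential extinction of the biomass."""
    qt = effective_dilution(p, n)
    disc = (1.0 - 4.0 * p.a * p.K) * qt * qt - 2.0 * qt * p.m + p.m * p.m
    try:
        _, mu_peak = growth_rate_peak(p)
    except NoInteriorMaximum:
        mu_peak = p.m  # K = 0: the supremum of mu is m (not attained)
    rate_bound = mu_peak - qt
    if qt >= p.m:
        case = "i"
    elif disc < 0:
        case = "ii"
    else:
        case = "none"
    return ExtinctionReport(
        q_tilde=qt,
        case=case,
        haldane_discriminant=disc,
        rate_bound=rate_bound,
        verdict=case != "none",
    )
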