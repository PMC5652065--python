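"""Domain types shared across the package.

The chemostat is a continuous-culture vessel: fresh medium with nutrient
concentration ``S0`` flows in at dilution rate ``Q`` and the mixed culture
flows out at the same rate.  Growth follows the Monod-Haldane (substrate
inhibition) law ``mu(S) = m S / (a + S + K S^2)``, which rises like Monod
kinetics at low substrate and is inhibited (decays) at high substrate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChemostatParams",
    "NoiseParams",
    "State",
    "Equilibrium",
    "Trajectory",
]


@dataclass(frozen=True)
class ChemostatParams:
    """Rate and shape constants of the deterministic chemostat.

    Parameters
    ----------
    Q : float
        Dilution rate (1/time); removal rate of both substrate and biomass.
    S0 : float
        Input substrate concentration (mass/volume).
    m : float
        Maximal specific growth rate (1/time).
    a : float
        Half-saturation (Michaelis-Menten) constant (mass/volume).
    K : float
        Substrate-inhibition coefficient (volume/mass); ``K = 0`` recovers
        plain Monod kinetics.
    delta : float
        Yield coefficient: biomass produced per unit nutrient consumed.
    """

    Q: float
    S0: float
    m: float
    a: float
    K: float
    delta: float

    def __post_init__(self) -> None:
        if not (self.Q > 0):
            raise ValueError(f"dilution rate Q must be > 0, got {self.Q}")
        if not (self.S0 > 0):
            raise ValueError(f"input concentration S0 must be > 0, got {self.S0}")
        if not (self.m > 0):
            raise ValueError(f"maximal growth rate m must be > 0, got {self.m}")
        if not (self.a > 0):
            raise ValueError(f"half-saturation a must be > 0, got {self.a}")
        if not (self.K >= 0):
            raise ValueError(f"inhibition coefficient K must be >= 0, got {self.K}")
        if not (self.delta > 0):
            raise ValueError(f"yield delta must be > 0, got {self.delta}")


@dataclass(frozen=True)
class NoiseParams:
    """White-noise intensities of the stochastic chemostat.

    ``sigma1`` multiplies ``S dB1`` in the substrate equation, ``sigma2``
    multiplies ``x dB2`` in the biomass equation; both have units 1/sqrt(time).
    """

    sigma1: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ValueError(
                f"noise intensities must be >= 0, got ({self.sigma1}, {self.sigma2})"
            )


@dataclass(frozen=True)
class State:
    """A point ``(S, x)``: substrate and microorganism concentrations."""

    S: float
    x: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.S) and math.isfinite(self.x)):
            raise ValueError(f"state must be finite, got ({self.S}, {self.x})")
        if self.S < 0 or self.x < 0:
            raise ValueError(f"state must be non-negative, got ({self.S}, {self.x})")


@dataclass(frozen=True)
class Equilibrium:
    """A steady state of the deterministic flow with its local linearisation.

    ``kind`` is ``"washout"`` (biomass absent, ``(S0, 0)``) or ``"interior"``
    (``0 < S* < S0``, ``x* > 0``); ``stability`` is one of ``stable node``,
    ``stable spiral``, ``saddle``, ``unstable node``, ``unstable spiral``,
    ``non-hyperbolic``.
    """

    S: float
    x: float
    kind: str
    eigenvalues: tuple[complex, complex]
    stability: str

    def as_dict(self) -> dict:
        return {
            "S": self.S,
            "x": self.x,
            "kind": self.kind,
            "stability": self.stability,
            "eigenvalues": [[ev.real, ev.imag] for ev in self.eigenvalues],
        }


@dataclass
class Trajectory:
    """A uniformly sampled path ``(t, S(t), x(t))``.

    ``scheme`` records how it was produced (``rk4``, ``euler_maruyama``,
    ``milstein`` or ``milstein_log``); ``floor_hits`` counts how many times a
    coordinate was clamped to the positivity floor (always 0 for ``rk4`` and
    ``milstein_log``).
    """

    times: np.ndarray
    S_path: np.ndarray
    x_path: np.ndarray
    scheme: str
    dt: float
    seed: int | None = None
    floor_hits: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.S_path = np.asarray(self.S_path, dtype=float)
        self.x_path = np.asarray(self.x_path, dtype=float)
        n = len(self.times)
        if len(self.S_path) != n or len(self.x_path) != n:
            raise ValueError("times, S_path and x_path must have equal length")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def horizon(self) -> float:
        return float(self.times[-1])

    def final_state(self) -> State:
        return State(float(self.S_path[-1]), float(self.x_path[-1]))

    def to_frame(self):
        """Return the path as a ``pandas.DataFrame`` with columns t, S, x."""
        import pandas as pd

        return pd.DataFrame({"t": self.times, "S": self.S_path, "x": self.x_path})

    def to_csv(self, path) -> None:
        """Write the path as CSV (header ``t,S,x``, full float precision)."""
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, scheme: str = "unknown", seed: int | None = None):
        import pandas as pd

        df = pd.read_csv(path)
        t = df["t"].to_numpy()
        dt = float(t[1] - t[0]) if len(t) > 1 else 0.0
        return cls(
            times=t,
            S_path=df["S"].to_numpy(),
            x_path=df["x"].to_numpy(),
            scheme=scheme,
            dt=dt,
            seed=seed,
        )
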