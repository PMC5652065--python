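"""Flat key=value configuration files.

Recognised keys: Q, S0, m, a, K, delta, sigma1, sigma2, S_init, x_init,
dt, t_end, seed.  Lines may use ``key = value`` or ``key=value``; blank
lines and ``#`` comments are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .params import ChemostatParams, NoiseParams, State

__all__ = ["RunConfig", "read_config", "write_config"]

_FLOAT_KEYS = (
    "Q", "S0", "m", "a", "K", "delta",
    "sigma1", "sigma2", "S_init", "x_init", "dt", "t_end",
)
_INT_KEYS = ("seed",)
_REQUIRED = ("Q", "S0", "m", "a", "K", "delta")


@dataclass(frozen=True)
class RunConfig:
    """Parsed configuration: model + noise + initial state + run controls."""

    params: ChemostatParams
    noise: NoiseParams
    init: State
    dt: float = 0.01
    t_end: float = 100.0
    seed: int = 0


def read_config(path) -> RunConfig:
    text = Path(path).read_text()
    raw: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        if key in _INT_KEYS:
            raw[key] = int(value)
        elif key in _FLOAT_KEYS:
            raw[key] = float(value)
        else:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    missing = [k for k in _REQUIRED if k not in raw]
    if missing:
        raise ValueError(f"{path}: missing required keys {missing}")
    params = ChemostatParams(
        Q=raw["Q"], S0=raw["S0"], m=raw["m"], a=raw["a"],
        K=raw["K"], delta=raw["delta"],
    )
    noise = NoiseParams(
        sigma1=raw.get("sigma1", 0.0), sigma2=raw.get("sigma2", 0.0)
    )
    init = State(
        S=raw.get("S_init", params.S0), x=raw.get("x_init", 1.0)
    )
    return RunConfig(
        params=params,
        noise=noise,
        init=init,
        dt=raw.get("dt", 0.01),
        t_end=raw.get("t_end", 100.0),
        seed=int(raw.get("seed", 0)),
    )


def write_config(cfg: RunConfig, path) -> None:
    p, n, s = cfg.params, cfg.noise, cfg.init
    lines = [
        f"Q = {p.Q!r}",
        f"S0 = {p.S0!r}",
        f"m = {p.m!r}",
        f"a = {p.a!r}",
        f"K = {p.K!r}",
        f"delta = {p.delta!r}",
        f"sigma1 = {n.sigma1!r}",
        f"sigma2 = {n.sigma2!r}",
        f"S_init = {s.S!r}",
        f"x_init = {s.x!r}",
        f"dt = {cfg.dt!r}",
        f"t_end = {cfg.t_end!r}",
        f"seed = {cfg.seed}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
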