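"""Time courses of the tumour-microenvironment phenotypic optimum.

Six regimes are supported, all moving only the first trait's optimum
(the remaining components stay at their initial values):

directional        z1_opt(t) = v1 * t
random             z1_opt(t) ~ N(0, delta^2), redrawn each generation
directional_random z1_opt(t) = v1 * t + N(0, delta^2)
cyclic             z1_opt(t) = (A/2) * (1 + sin(2 pi t / P - pi/2))
constant           z_opt(t)  = z0_opt
sudden             z_opt(t)  = z0_opt for t < tau, z1_opt for t >= tau
schedule           piecewise-constant targets (therapy dosing plans)

The random component is redrawn independently each generation (not a
random walk).  Draws come from a caller-supplied generator so that the
optimum realization is reproducible independently of population events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .landscape import as_phenotype

__all__ = ["TrajectoryConfig", "OptimumProcess", "optimum_at", "REGIMES"]

REGIMES = (
    "directional",
    "random",
    "directional_random",
    "cyclic",
    "constant",
    "sudden",
    "schedule",
)


@dataclass(frozen=True)
class TrajectoryConfig:
    """Parameters of one optimum-change regime.

    Only the fields of the active regime are consulted.  ``v`` may be a
    scalar (speed of the first trait) or an n-vector whose tail entries
    must be zero.  ``delta`` has no default: random regimes must state it.
    ``P`` defaults to 360 generations.  ``schedule`` is an ordered list of
    ``(start_generation, first-trait target)`` pairs.
    """

    regime: str = "constant"
    n: int = 2
    v: float | Sequence[float] = 0.0
    delta: float | None = None
    A: float = 0.0
    P: int = 360
    tau: int = 0
    z0_opt: Sequence[float] | None = None
    z1_opt: Sequence[float] | None = None
    schedule: Sequence[tuple[int, float]] = field(default_factory=tuple)

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown optimum regime {self.regime!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.P < 1:
            raise ValueError("period P must be >= 1")
        if self.A < 0:
            raise ValueError("amplitude A must be >= 0")
        if self.tau < 0:
            raise ValueError("switch generation tau must be >= 0")
        if self.regime in ("random", "directional_random"):
            if self.delta is None:
                raise ValueError(
                    f"regime {self.regime!r} requires delta (no default)"
                )
            if self.delta < 0:
                raise ValueError("delta must be >= 0")
        if self.regime == "schedule" and not self.schedule:
            raise ValueError("schedule regime requires a non-empty schedule")

    @property
    def v1(self) -> float:
        v = np.atleast_1d(np.asarray(self.v, dtype=float))
        if v.size > 1 and np.any(v[1:] != 0.0):
            raise ValueError("only the first trait's optimum may move")
        return float(v[0])

    def base_optimum(self) -> np.ndarray:
        if self.z0_opt is not None:
            return as_phenotype(self.z0_opt, self.n)
        return np.zeros(self.n)


def optimum_at(
    cfg: TrajectoryConfig, t: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Optimum vector at generation ``t``.

    Regimes with a random component require ``rng``; one normal deviate is
    consumed per call, so sequential calls over t = 0, 1, 2, ... replay an
    identical realization under a fixed seed.
    """
    if t < 0:
        raise ValueError("generation t must be >= 0")
    base = cfg.base_optimum()
    z = base.copy()
    regime = cfg.regime
    if regime == "constant":
        return z
    if regime == "directional":
        z[0] = cfg.v1 * t
        return z
    if regime in ("random", "directional_random"):
        if rng is None:
            raise ValueError(f"regime {regime!r} needs a random generator")
        eps = rng.normal(0.0, cfg.delta)
        z[0] = eps if regime == "random" else cfg.v1 * t + eps
        return z
    if regime == "cyclic":
        z[0] = 0.5 * cfg.A * (1.0 + np.sin(2.0 * np.pi * t / cfg.P - 0.5 * np.pi))
        return z
    if regime == "sudden":
        if t >= cfg.tau:
            if cfg.z1_opt is None:
                raise ValueError("sudden regime requires z1_opt")
            return as_phenotype(cfg.z1_opt, cfg.n).copy()
        return z
    if regime == "schedule":
        target = base[0]
        for start, value in cfg.schedule:
            if t >= start:
                target = value
        z[0] = target
        return z
    raise ValueError(f"unknown optimum regime {regime!r}")  # pragma: no cover


class OptimumProcess:
    """Stateful optimum stream for a simulation run.

    Owns a dedicated random stream so the TME realization does not depend
    on population size or cell-level events, and supports mid-run regime
    swaps (therapy).  ``at(t)`` must be called with non-decreasing t.
    """

    def __init__(self, cfg: TrajectoryConfig, rng: np.random.Generator):
        self.cfg = cfg
        self._rng = rng
        self._last_t = -1
        self._last_value: np.ndarray | None = None

    def at(self, t: int) -> np.ndarray:
        if t == self._last_t and self._last_value is not None:
            return self._last_value
        if t < self._last_t:
            raise ValueError("OptimumProcess consumed out of order")
        value = optimum_at(self.cfg, t, self._rng)
        self._last_t = t
        self._last_value = value
        return value

    def switch(self, cfg: TrajectoryConfig) -> None:
        """Replace the regime from the current generation onward."""
        self.cfg = cfg
        self._last_value = None
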