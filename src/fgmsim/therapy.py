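"""Anti-cancer therapy as scheduled changes of optimum and landscape.

A treatment starting at generation tau models genotoxic therapy or
immunotherapy as a sudden shift of the phenotypic optimum by Delta along
the first trait (the piecewise sudden-change regime), optionally
combined with a new landscape shape S' and, for resistance scenarios,
with interventions that expand the locus count (polygenic resistance,
e.g. L = 50), raise the mutation rate, or widen the peak (relaxed
selection, e.g. sigma^2 = 40).  Sequential / cyclic dosing is a
piecewise-constant schedule of optimum targets.

Cure means population extinction; relapse means post-treatment recovery
to at least a configurable fraction of the pre-treatment size.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .config import derive_seed
from .engine import SimConfig, run_simulation
from .trajectory import TrajectoryConfig

__all__ = ["TreatmentPlan", "apply_treatment", "run_treatment_experiment"]


@dataclass(frozen=True)
class TreatmentPlan:
    """Schedule of one treatment and optional resistance interventions."""

    tau: int = 0
    delta: float = 0.0
    sigma2_new: float | None = None
    S_new: object = None
    schedule: Sequence[tuple[int, float]] = ()
    L_new: int | None = None
    u_new: float | None = None

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError("treatment start tau must be >= 0")
        if not np.isfinite(self.delta):
            raise ValueError("optimum shift delta must be finite")

    @property
    def is_identity(self) -> bool:
        return (
            self.delta == 0.0
            and self.sigma2_new is None
            and self.S_new is None
            and not self.schedule
            and self.L_new is None
            and self.u_new is None
        )


def apply_treatment(cfg: SimConfig, plan: TreatmentPlan) -> SimConfig:
    """Configuration following the pre-treatment regime before tau and
    the treatment-modified optimum / landscape / genetics thereafter.

    The identity plan returns the configuration unchanged, so control
    and treated runs share a seed bit for bit.
    """
    if plan.is_identity:
        return cfg
    changes: dict = {}
    if plan.delta != 0.0:
        changes["optimum_shift"] = float(plan.delta)
    if plan.sigma2_new is not None:
        if plan.sigma2_new <= 0:
            raise ValueError("sigma2_new must be positive")
        changes["sigma2"] = float(plan.sigma2_new)
    if plan.S_new is not None:
        S = np.asarray(plan.S_new, dtype=float)
        if S.shape != (cfg.n, cfg.n):
            raise ValueError("S_new dimensions must match the trait count n")
        changes["S"] = S
    if plan.u_new is not None:
        changes["u"] = float(plan.u_new)
    if plan.L_new is not None:
        if plan.L_new < cfg.L:
            raise ValueError("L_new must not shrink the locus count")
        changes["L"] = int(plan.L_new)
    interventions = list(cfg.interventions)
    if changes:
        interventions.append((int(plan.tau), changes))
    if plan.schedule:
        traj = TrajectoryConfig(
            regime="schedule", n=cfg.n, schedule=tuple(plan.schedule)
        )
        interventions.append((int(plan.schedule[0][0]), {"trajectory": traj}))
    interventions.sort(key=lambda item: item[0])
    return replace(cfg, interventions=tuple(interventions))


def _classify(result, tau: int, relapse_fraction: float) -> dict:
    summary = result.summary
    pre = summary[summary["generation"] <= tau]
    post = summary[summary["generation"] >= tau]
    pre_size = int(pre["popsize"].iloc[-1]) if len(pre) else 0
    cured = bool(result.extinct)
    final_size = int(summary["popsize"].iloc[-1])
    recovered = bool(
        not cured
        and pre_size > 0
        and final_size >= relapse_fraction * pre_size
    )
    post_alive = post[post["popsize"] > 0]
    nadir_size = int(post["popsize"].min()) if len(post) else pre_size
    nadir_fitness = (
        float(post_alive["mean_fitness"].min()) if len(post_alive) else float("nan")
    )
    steps = result.steps
    post_steps = steps[steps["fixation_gen"] >= tau]
    de_novo = int((post_steps["origin_gen"] >= tau).sum())
    return {
        "cured": cured,
        "extinction_gen": result.extinction_generation,
        "pre_popsize": pre_size,
        "final_popsize": final_size,
        "nadir_popsize": nadir_size,
        "nadir_fitness": nadir_fitness,
        "recovered": recovered,
        "steps_post": int(len(post_steps)),
        "steps_de_novo": de_novo,
        "steps_preexisting": int(len(post_steps)) - de_novo,
    }


def run_treatment_experiment(
    cfg: SimConfig,
    plan: TreatmentPlan,
    replicates: int,
    seed: int | None = None,
    relapse_fraction: float = 1.0,
    include_control: bool = True,
) -> pd.DataFrame:
    """Matched control / treated replicates with outcome classification.

    Each replicate re-runs the same derived seed with and without the
    plan; post-treatment fixed drivers are tagged de novo
    (origin >= tau) or pre-existing.  ``relapse_fraction`` scales the
    pre-treatment population size that defines recovery.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    master = cfg.seed if seed is None else seed
    rows = []
    for rep in range(replicates):
        rep_seed = derive_seed(master, "treatment", rep)
        base = replace(cfg, seed=rep_seed)
        arms = [("treated", apply_treatment(base, plan))]
        if include_control:
            arms.append(("control", base))
        for arm, arm_cfg in arms:
            result = run_simulation(arm_cfg)
            row = {"replicate": rep, "arm": arm, "seed": rep_seed}
            row.update(_classify(result, plan.tau, relapse_fraction))
            rows.append(row)
    return pd.DataFrame(rows)
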