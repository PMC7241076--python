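"""Individual-based simulation on a bounded 3D cubic lattice.

Cells occupy at most one site each on a G^3 grid with a 26-site Moore
neighbourhood and absorbing walls.  Generations are discrete and
non-overlapping.  Each generation:

1. the phenotypic optimum advances to its value at generation t;
2. every cell's fitness is recomputed against that optimum;
3. every cell survives viability selection with probability equal to its
   fitness (death frees the site);
4. every survivor replicates: daughter 1 takes the parent's site,
   daughter 2 takes a uniformly random empty Moore-neighbour site if one
   exists and the population cap N_max allows;
5. daughters mutate (per-copy Bernoulli u) and undergo CIN (per-locus
   Bernoulli r_c); phenotypes update additively.

Once space or N_max saturates, reproduction can only fill sites freed by
deaths in the same generation, so clonal interference emerges from the
caps.  Survivors compete for cap headroom in uniformly random order.

Summary statistics are sampled every ``sampling_interval`` generations;
time is reported in years assuming a configurable doubling time (24 h by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import genetics
from .genetics import AlleleTable, CopyCounts, ancestral_genome
from .landscape import (
    SelectionMatrix,
    as_phenotype,
    mvn_factor,
    phenotype_from_fitness,
)
from .phylo import LineageRecorder
from .trajectory import OptimumProcess, TrajectoryConfig

__all__ = [
    "SimConfig",
    "SimulationState",
    "RunResult",
    "initialize",
    "step_generation",
    "run_simulation",
    "snapshot_frame",
    "SUMMARY_COLUMNS",
]

SUMMARY_COLUMNS = (
    "generation",
    "time_years",
    "popsize",
    "mean_fitness",
    "fitness_var",
    "adaptive_steps",
    "mean_step_s",
    "extinct",
)

STEP_COLUMNS = ("allele_id", "locus", "origin_gen", "fixation_gen", "s_at_fixation")


@dataclass(frozen=True)
class SimConfig:
    """Complete configuration of one simulation run.

    Desk-scale defaults (G = 50, N_max = 1e4, 2000 generations) keep a
    run in seconds; the full-scale regime (G = 300, N_max = 1e7) uses
    the same code but is cluster-sized.  ``seed`` is mandatory so every
    archived run is reproducible.
    """

    seed: int
    n: int = 2
    sigma2: float = 10.0
    S: Any = None  # explicit SelectionMatrix or array; overrides sigma2
    trajectory: TrajectoryConfig | None = None
    u: float = 4e-5
    sigma_m: float = 0.5
    M: Any = None  # explicit mutation covariance; overrides sigma_m
    L: int = 5
    c: int = 2
    r_c: float = 0.0
    K: int = 1
    w0: float = 1.0
    z0: Sequence[float] | None = None
    N_max: int = 10_000
    G: int = 50
    max_generations: int = 2000
    sampling_interval: int = 100
    doubling_time_hours: float = 24.0
    record_lineage: bool = False
    sample_tips: int | None = None
    interventions: tuple[tuple[int, dict[str, Any]], ...] = ()

    def __post_init__(self):
        if self.trajectory is None:
            object.__setattr__(self, "trajectory", TrajectoryConfig(n=self.n))
        if self.trajectory.n != self.n:
            raise ValueError("trajectory dimensionality must match n")
        for name in ("u", "r_c"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.N_max < self.K:
            raise ValueError("N_max must be >= K")
        if self.G < 3:
            raise ValueError("lattice side G must be >= 3")
        if self.L < 1 or self.c < 1:
            raise ValueError("L and c must be >= 1")
        if not (0.0 < self.w0 <= 1.0):
            raise ValueError("w0 must lie in (0, 1]")
        if self.sampling_interval < 1:
            raise ValueError("sampling_interval must be >= 1")
        if self.max_generations < 0:
            raise ValueError("max_generations must be >= 0")

    def selection_matrix(self) -> SelectionMatrix:
        if self.S is None:
            return SelectionMatrix.isotropic(self.sigma2, self.n)
        if isinstance(self.S, SelectionMatrix):
            if self.S.n != self.n:
                raise ValueError("S dimension must match n")
            return self.S
        return SelectionMatrix(np.asarray(self.S, dtype=float))

    def mutation_covariance(self) -> np.ndarray:
        if self.M is None:
            return self.sigma_m**2 * np.eye(self.n)
        return np.asarray(self.M, dtype=float)


# 26 Moore-neighbourhood offsets, deterministic order.
_MOORE = np.array(
    [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.int64,
)


@dataclass
class SimulationState:
    """Mutable runtime state of a simulation (array-of-cells layout)."""

    cfg: SimConfig
    S: SelectionMatrix
    traj: OptimumProcess
    rng: np.random.Generator
    rng_sample: np.random.Generator
    table: AlleleTable
    pflat: np.ndarray  # flat padded-lattice site per cell
    genome: np.ndarray  # (N, L, c) allele ids
    phen: np.ndarray  # (N, n)
    fit: np.ndarray  # (N,)
    cell_ids: np.ndarray
    node_ids: np.ndarray | None
    occf: np.ndarray  # flat padded occupancy, border = True
    mut_factor: np.ndarray
    u: float
    r_c: float
    L: int
    counts: CopyCounts = field(default_factory=CopyCounts)
    t: int = 0
    next_cell_id: int = 0
    fixed_base: dict[int, int] = field(default_factory=dict)
    steps: list[tuple] = field(default_factory=list)
    recorder: LineageRecorder | None = None
    pending: list[tuple[int, dict[str, Any]]] = field(default_factory=list)
    extinct: bool = False

    @property
    def popsize(self) -> int:
        return self.pflat.size

    def positions(self) -> np.ndarray:
        """(N, 3) lattice coordinates in [0, G)^3."""
        side = self.cfg.G + 2
        x, rem = np.divmod(self.pflat, side * side)
        y, z = np.divmod(rem, side)
        return np.stack([x - 1, y - 1, z - 1], axis=1)


def _encode(pos: np.ndarray, G: int) -> np.ndarray:
    side = G + 2
    p = pos + 1
    return (p[:, 0] * side + p[:, 1]) * side + p[:, 2]


def _central_sites(G: int, K: int) -> np.ndarray:
    """K sites around the lattice centre: shell by shell, deterministic.

    Sites sort by (Chebyshev shell, x, y, z).  Raises if K needs a shell
    that does not fit inside the lattice.
    """
    c = G // 2
    r = 0
    while (2 * r + 1) ** 3 < K:
        r += 1
    if c - r < 0 or c + r >= G:
        raise ValueError(f"K={K} exceeds the central shells of a G={G} lattice")
    axis = np.arange(-r, r + 1)
    xx, yy, zz = np.meshgrid(axis, axis, axis, indexing="ij")
    coords = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    shell = np.abs(coords).max(axis=1)
    order = np.lexsort((coords[:, 2], coords[:, 1], coords[:, 0], shell))
    return coords[order[:K]] + c


def initialize(cfg: SimConfig) -> SimulationState:
    """Place K ancestral cells at the lattice centre and set up streams."""
    ss = np.random.SeedSequence(cfg.seed)
    child_cells, child_tme, child_sample = ss.spawn(3)
    rng = np.random.default_rng(child_cells)
    rng_tme = np.random.default_rng(child_tme)
    rng_sample = np.random.default_rng(child_sample)

    S = cfg.selection_matrix()
    traj = OptimumProcess(cfg.trajectory, rng_tme)
    if cfg.z0 is not None:
        z0 = as_phenotype(cfg.z0, cfg.n)
    else:
        z0 = phenotype_from_fitness(cfg.w0, S, cfg.trajectory.base_optimum())

    pos = _central_sites(cfg.G, cfg.K)
    pflat = _encode(pos, cfg.G)

    side = cfg.G + 2
    occ = np.zeros((side, side, side), dtype=bool)
    occ[0, :, :] = occ[-1, :, :] = True
    occ[:, 0, :] = occ[:, -1, :] = True
    occ[:, :, 0] = occ[:, :, -1] = True
    occf = occ.ravel()
    occf[pflat] = True

    table = AlleleTable(cfg.L, cfg.n)
    state = SimulationState(
        cfg=cfg,
        S=S,
        traj=traj,
        rng=rng,
        rng_sample=rng_sample,
        table=table,
        pflat=pflat,
        genome=np.repeat(
            ancestral_genome(cfg.L, cfg.c)[None, :, :], cfg.K, axis=0
        ),
        phen=np.repeat(z0[None, :], cfg.K, axis=0),
        fit=np.zeros(cfg.K),
        cell_ids=np.arange(cfg.K, dtype=np.int64),
        node_ids=None,
        occf=occf,
        mut_factor=mvn_factor(cfg.mutation_covariance()),
        u=cfg.u,
        r_c=cfg.r_c,
        L=cfg.L,
        next_cell_id=cfg.K,
        fixed_base={l: l for l in range(cfg.L)},
        pending=sorted(
            [(int(g), dict(ch)) for g, ch in cfg.interventions],
            key=lambda item: item[0],
        ),
    )
    state.counts.resize(len(table))
    state.counts.add_genomes(state.genome)
    if cfg.record_lineage:
        state.recorder = LineageRecorder()
        state.node_ids = state.recorder.new_nodes(
            np.full(cfg.K, -1, dtype=np.int64), 0
        )
    _apply_interventions(state)
    _refresh_fitness(state)
    return state


_OFF_CACHE: dict[int, np.ndarray] = {}


def _moore_flat(G: int) -> np.ndarray:
    off = _OFF_CACHE.get(G)
    if off is None:
        side = G + 2
        off = (_MOORE[:, 0] * side + _MOORE[:, 1]) * side + _MOORE[:, 2]
        _OFF_CACHE[G] = off
    return off


def _refresh_fitness(state: SimulationState) -> np.ndarray:
    """Recompute every cell's fitness against the optimum at state.t."""
    opt = state.traj.at(state.t)
    dz = state.phen - opt
    q = np.einsum("ij,jk,ik->i", dz, state.S.inverse, dz)
    state.fit = np.exp(-q)
    return state.fit


def _apply_interventions(state: SimulationState) -> None:
    while state.pending and state.pending[0][0] <= state.t:
        _gen, changes = state.pending.pop(0)
        if "optimum_shift" in changes:
            base = state.traj.at(state.t).copy()
            base[0] += float(changes["optimum_shift"])
            state.traj.switch(
                TrajectoryConfig(regime="constant", n=state.cfg.n, z0_opt=tuple(base))
            )
        if "trajectory" in changes:
            state.traj.switch(changes["trajectory"])
        if "sigma2" in changes:
            state.S = SelectionMatrix.isotropic(float(changes["sigma2"]), state.cfg.n)
        if "S" in changes:
            S = changes["S"]
            state.S = S if isinstance(S, SelectionMatrix) else SelectionMatrix(S)
        if "u" in changes:
            state.u = float(changes["u"])
        if "r_c" in changes:
            state.r_c = float(changes["r_c"])
        if "sigma_m" in changes:
            state.mut_factor = mvn_factor(
                float(changes["sigma_m"]) ** 2 * np.eye(state.cfg.n)
            )
        if "M" in changes:
            state.mut_factor = mvn_factor(np.asarray(changes["M"], dtype=float))
        if "L" in changes:
            newL = int(changes["L"])
            if newL < state.L:
                raise ValueError("loci can only be expanded, not removed")
            if newL > state.L:
                new_ids = state.table.add_loci(newL - state.L)
                extra = np.empty(
                    (state.genome.shape[0], newL - state.L, state.cfg.c),
                    dtype=np.int64,
                )
                for j, aid in enumerate(new_ids):
                    extra[:, j, :] = aid
                state.genome = np.concatenate([state.genome, extra], axis=1)
                state.counts.resize(len(state.table))
                state.counts.view[new_ids] += state.genome.shape[0] * state.cfg.c
                for j, aid in enumerate(new_ids):
                    state.fixed_base[state.L + j] = aid
                state.L = newL


def _place_daughters(
    pflat: np.ndarray,
    occf: np.ndarray,
    off26: np.ndarray,
    headroom: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Assign empty Moore-neighbour sites to second daughters.

    Survivors are processed in uniformly random priority order, in chunks
    sized to the remaining cap headroom.  Within a chunk every active
    survivor proposes a uniformly random empty neighbour, the
    highest-priority proposer wins each contested site, and losers
    re-propose among the remaining empties.  Placement stops when the
    headroom is exhausted.  Returns (survivor indices, claimed sites).
    """
    S = pflat.size
    if S == 0 or headroom <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    priority = rng.random(S)
    order = np.argsort(priority, kind="stable")
    parents: list[np.ndarray] = []
    sites_out: list[np.ndarray] = []
    placed = 0
    start = 0
    while start < S and placed < headroom:
        width = max(64, 2 * (headroom - placed))
        active = order[start : start + width]
        start += width
        while active.size and placed < headroom:
            cand = pflat[active][:, None] + off26[None, :]
            empty = ~occf[cand]
            has = empty.any(axis=1)
            active = active[has]
            if active.size == 0:
                break
            cand = cand[has]
            empty = empty[has]
            scores = rng.random(cand.shape)
            scores[~empty] = -1.0
            pick = np.argmax(scores, axis=1)
            sites = cand[np.arange(cand.shape[0]), pick]
            pr = priority[active]
            sub = np.argsort(pr, kind="stable")
            _uniq, first = np.unique(sites[sub], return_index=True)
            winners = sub[first]
            if placed + winners.size > headroom:
                take = headroom - placed
                winners = winners[np.argsort(pr[winners], kind="stable")[:take]]
            win_sites = sites[winners]
            occf[win_sites] = True
            parents.append(active[winners])
            sites_out.append(win_sites)
            placed += winners.size
            mask = np.ones(active.size, dtype=bool)
            mask[winners] = False
            active = active[mask]
    if not parents:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(parents), np.concatenate(sites_out)


def _scan_fixation(state: SimulationState, generation: int) -> None:
    """Record newly fixed driver alleles, once each, at ``generation``."""
    table = state.table
    if state.genome.shape[0] == 0:
        return
    alive = state.counts.alive()
    alive_locus = table.locus_array()[alive]
    mean_phen: np.ndarray | None = None
    for locus in range(state.L):
        base = state.fixed_base[locus]
        present = alive[alive_locus == locus]
        if present.size == 1 and int(present[0]) == base:
            continue
        dca = genetics._deepest_common_ancestor(present, table)
        if dca == base:
            continue
        chain = table.ancestry(dca)
        newly = chain[: chain.index(base)]
        opt = state.traj.at(state.t)
        if mean_phen is None:
            mean_phen = state.phen.mean(axis=0)
        for aid in reversed(newly):
            r = table.displacement[aid]
            q_with = float(state.S.quadratic_form(mean_phen - opt))
            q_without = float(state.S.quadratic_form(mean_phen - r - opt))
            s_fix = float(np.expm1(q_without - q_with))
            state.steps.append(
                (aid, locus, table.origin_gen[aid], generation, s_fix)
            )
        state.fixed_base[locus] = dca


def step_generation(state: SimulationState) -> SimulationState:
    """Advance one synchronous generation (in place; returns state).

    Assumes ``state.fit`` is current for generation ``state.t`` (as left
    by :func:`initialize` or the previous step).
    """
    cfg = state.cfg
    rng = state.rng
    N = state.popsize
    if N == 0:
        state.extinct = True
        state.t += 1
        return state

    # (3) viability selection
    keep = rng.random(N) < state.fit
    state.occf[state.pflat[~keep]] = False
    state.counts.add_genomes(state.genome[~keep], -1)
    pflat = state.pflat[keep]
    genome = state.genome[keep]
    phen = state.phen[keep]
    node_ids = state.node_ids[keep] if state.node_ids is not None else None

    n_surv = pflat.size
    if n_surv == 0:
        state.pflat = pflat
        state.genome = genome
        state.phen = phen
        state.fit = np.empty(0)
        state.cell_ids = np.empty(0, dtype=np.int64)
        state.node_ids = node_ids
        state.extinct = True
        state.t += 1
        return state

    # (4) reproduction: daughter 2 into empty Moore sites, cap-limited
    off26 = _moore_flat(cfg.G)
    headroom = cfg.N_max - n_surv
    d2_idx, d2_sites = _place_daughters(pflat, state.occf, off26, headroom, rng)

    d2_genome = genome[d2_idx].copy()
    d2_phen = phen[d2_idx].copy()
    state.counts.add_genomes(d2_genome)

    next_gen = state.t + 1
    # (5) mutation and CIN, each daughter independently
    genetics.mutate_genomes(
        genome, phen, state.u, state.mut_factor, next_gen, state.table, rng,
        counts=state.counts,
    )
    genetics.apply_cin(genome, phen, state.r_c, state.table, rng, counts=state.counts)
    genetics.mutate_genomes(
        d2_genome, d2_phen, state.u, state.mut_factor, next_gen, state.table, rng,
        counts=state.counts,
    )
    genetics.apply_cin(
        d2_genome, d2_phen, state.r_c, state.table, rng, counts=state.counts
    )

    if state.recorder is not None:
        d2_parents = node_ids[d2_idx]
        node_ids = state.recorder.new_nodes(node_ids, next_gen)
        d2_nodes = state.recorder.new_nodes(d2_parents, next_gen)
        state.node_ids = np.concatenate([node_ids, d2_nodes])

    n_total = n_surv + d2_idx.size
    state.pflat = np.concatenate([pflat, d2_sites])
    state.genome = np.concatenate([genome, d2_genome], axis=0)
    state.phen = np.concatenate([phen, d2_phen], axis=0)
    state.cell_ids = np.arange(
        state.next_cell_id, state.next_cell_id + n_total, dtype=np.int64
    )
    state.next_cell_id += n_total

    # (6) advance the clock, then refresh fitness and record fixations
    state.t = next_gen
    _apply_interventions(state)
    _refresh_fitness(state)
    _scan_fixation(state, next_gen)
    return state


def _summary_row(state: SimulationState) -> tuple:
    cfg = state.cfg
    n = state.popsize
    steps = len(state.steps)
    mean_s = float(np.mean([s[4] for s in state.steps])) if steps else float("nan")
    return (
        state.t,
        state.t * cfg.doubling_time_hours / (24.0 * 365.0),
        n,
        float(state.fit.mean()) if n else float("nan"),
        float(state.fit.var()) if n else float("nan"),
        steps,
        mean_s,
        bool(n == 0),
    )


def _record_tips(state: SimulationState) -> None:
    rec = state.recorder
    if rec is None or state.popsize == 0:
        return
    k = state.cfg.sample_tips
    if k is None or k >= state.popsize:
        idx = np.arange(state.popsize)
    else:
        idx = np.sort(state.rng_sample.choice(state.popsize, size=k, replace=False))
    labels = [f"{state.cell_ids[i]}@{state.t}" for i in idx]
    rec.record_sample(state.node_ids[idx], labels)


@dataclass
class RunResult:
    """Outputs of one run: time series, driver log, final state."""

    config: SimConfig
    summary: pd.DataFrame
    steps: pd.DataFrame
    state: SimulationState
    recorder: LineageRecorder | None
    extinct: bool
    extinction_generation: int | None

    @property
    def table(self) -> AlleleTable:
        return self.state.table


def run_simulation(cfg: SimConfig) -> RunResult:
    """Run to ``max_generations`` or extinction, sampling summaries."""
    state = initialize(cfg)
    rows = [_summary_row(state)]
    _record_tips(state)
    extinction_gen: int | None = None
    while state.t < cfg.max_generations:
        step_generation(state)
        at_sample = state.t % cfg.sampling_interval == 0
        last = state.t >= cfg.max_generations
        if state.popsize == 0:
            extinction_gen = state.t
            rows.append(_summary_row(state))
            break
        if at_sample or last:
            rows.append(_summary_row(state))
        if at_sample:
            _record_tips(state)
    steps_df = pd.DataFrame(state.steps, columns=STEP_COLUMNS)
    if len(steps_df):
        effects = state.table.displacement[steps_df["allele_id"].to_numpy()]
        for j in range(cfg.n):
            steps_df[f"effect_{j}"] = effects[:, j]
    else:
        for j in range(cfg.n):
            steps_df[f"effect_{j}"] = pd.Series(dtype=float)
    summary = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return RunResult(
        config=cfg,
        summary=summary,
        steps=steps_df,
        state=state,
        recorder=state.recorder,
        extinct=state.popsize == 0,
        extinction_generation=extinction_gen,
    )


def snapshot_frame(state: SimulationState) -> pd.DataFrame:
    """3D snapshot: coordinates, fitness and fitness-quartile label.

    Quartile cut-offs follow the current fitness distribution (the
    four-colour scheme: top 25% .. lowest 25%).
    """
    pos = state.positions()
    fit = state.fit
    frame = pd.DataFrame(
        {
            "x": pos[:, 0],
            "y": pos[:, 1],
            "z": pos[:, 2],
            "cell_id": state.cell_ids,
            "fitness": fit,
        }
    )
    if len(frame):
        q25, q50, q75 = np.quantile(fit, [0.25, 0.5, 0.75])
        labels = np.full(len(frame), "top25", dtype=object)
        labels[fit <= q75] = "50-75"
        labels[fit <= q50] = "25-50"
        labels[fit <= q25] = "lowest25"
        frame["fitness_quartile"] = labels
    else:
        frame["fitness_quartile"] = pd.Series(dtype=object)
    return frame
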