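"""Configuration files, deterministic seeding, run outputs and manifests.

Run configurations load from YAML or JSON; a seed is mandatory so that a
manifest re-runs to byte-identical outputs.  One master seed drives
independent child streams (TME trajectory, cell events, tip sampling)
inside each run, and replicate/grid seeds derive deterministically from
(master seed, grid point, replicate index).
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import RunResult, SimConfig, run_simulation, snapshot_frame
from .phylo import (
    count_cherries,
    prune_genealogy,
    sackin_normalized,
    write_newick,
)
from .trajectory import TrajectoryConfig

__all__ = [
    "load_config",
    "config_from_dict",
    "config_to_dict",
    "derive_seed",
    "RunManifest",
    "write_run_outputs",
    "replicate_sweep",
    "tree_stats_per_sample",
]

_TRAJ_KEYS = {
    "regime",
    "n",
    "v",
    "delta",
    "A",
    "P",
    "tau",
    "z0_opt",
    "z1_opt",
    "schedule",
}
_CFG_KEYS = {
    "seed",
    "n",
    "sigma2",
    "S",
    "trajectory",
    "u",
    "sigma_m",
    "M",
    "L",
    "c",
    "r_c",
    "K",
    "w0",
    "z0",
    "N_max",
    "G",
    "max_generations",
    "sampling_interval",
    "doubling_time_hours",
    "record_lineage",
    "sample_tips",
    "interventions",
}


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending key."""


def _trajectory_from_dict(data: dict) -> TrajectoryConfig:
    unknown = set(data) - _TRAJ_KEYS
    if unknown:
        raise ConfigError(f"unknown trajectory key(s): {sorted(unknown)}")
    data = dict(data)
    if "schedule" in data and data["schedule"] is not None:
        data["schedule"] = tuple((int(g), float(v)) for g, v in data["schedule"])
    try:
        return TrajectoryConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"trajectory: {exc}") from exc


def config_from_dict(data: dict) -> SimConfig:
    unknown = set(data) - _CFG_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    if "seed" not in data or data["seed"] is None:
        raise ConfigError("missing required key: seed")
    data = dict(data)
    if isinstance(data.get("trajectory"), dict):
        data["trajectory"] = _trajectory_from_dict(data["trajectory"])
    if "interventions" in data:
        fixed = []
        for gen, changes in data["interventions"] or ():
            changes = dict(changes)
            if isinstance(changes.get("trajectory"), dict):
                changes["trajectory"] = _trajectory_from_dict(changes["trajectory"])
            fixed.append((int(gen), changes))
        data["interventions"] = tuple(fixed)
    try:
        return SimConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def _jsonable(obj):
    if isinstance(obj, TrajectoryConfig):
        return {k: _jsonable(v) for k, v in asdict(obj).items() if v is not None}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def config_to_dict(cfg: SimConfig) -> dict:
    out = {}
    for key in _CFG_KEYS:
        value = getattr(cfg, key)
        if key == "S" and value is not None:
            value = getattr(value, "entries", value)
        out[key] = _jsonable(value)
    return {k: v for k, v in out.items() if v is not None}


def load_config(path: str | Path, overrides: dict | None = None) -> SimConfig:
    """Read a YAML/JSON run configuration; overrides take precedence."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path} does not contain a configuration mapping")
    if overrides:
        data.update(overrides)
    return config_from_dict(data)


def derive_seed(master: int, *key) -> int:
    """Deterministic child seed in [0, 2^31) from (master, key...)."""
    digest = hashlib.sha256(repr((int(master),) + tuple(key)).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class RunManifest:
    """Resolved configuration + software version + output checksums."""

    config: dict
    seed: int
    version: str
    checksums: dict

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def tree_stats_per_sample(result: RunResult) -> pd.DataFrame:
    """(sampling generation, tips, normalized Sackin, cherries) table.

    Each row summarizes the serially sampled tree truncated at that
    sampling point (tips from all sampling points up to and including
    it); rows appear once at least two tips exist.
    """
    rec = result.recorder
    if rec is None:
        raise ValueError("run was not configured with record_lineage")
    parent, gen = rec.arrays()
    rows = []
    nodes_so_far: list[np.ndarray] = []
    labels_so_far: list[str] = []
    for nodes, labels in zip(rec.sampled_nodes, rec.sampled_labels):
        if nodes.size == 0:
            continue
        nodes_so_far.append(nodes)
        labels_so_far.extend(labels)
        tips = np.concatenate(nodes_so_far)
        if tips.size < 2:
            continue
        sample_gen = int(labels[0].rsplit("@", 1)[1])
        tree = prune_genealogy(parent, gen, tips, labels_so_far)
        rows.append(
            (
                sample_gen,
                tree.n_tips(),
                sackin_normalized(tree),
                count_cherries(tree),
            )
        )
    return pd.DataFrame(
        rows, columns=["generation", "tips", "sackin_normalized", "cherries"]
    )


def write_run_outputs(result: RunResult, outdir: str | Path) -> RunManifest:
    """Write summary TSV, driver log, snapshot CSV, trees and manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    summary_path = outdir / "summary.tsv"
    result.summary.to_csv(summary_path, sep="\t", index=False)
    written.append(summary_path)

    steps_path = outdir / "adaptive_steps.tsv"
    result.steps.to_csv(steps_path, sep="\t", index=False)
    written.append(steps_path)

    if result.state.popsize:
        snap_path = outdir / "snapshot.csv"
        snapshot_frame(result.state).to_csv(snap_path, index=False)
        written.append(snap_path)

    if result.recorder is not None:
        nodes, labels = result.recorder.all_sampled()
        if nodes.size >= 2:
            parent, gen = result.recorder.arrays()
            tree = prune_genealogy(parent, gen, nodes, labels)
            tree_path = outdir / "tree.nwk"
            tree_path.write_text(write_newick(tree) + "\n")
            written.append(tree_path)
            stats_path = outdir / "tree_stats.tsv"
            tree_stats_per_sample(result).to_csv(stats_path, sep="\t", index=False)
            written.append(stats_path)

    manifest = RunManifest(
        config=config_to_dict(result.config),
        seed=result.config.seed,
        version=__version__,
        checksums={p.name: _sha256(p) for p in written},
    )
    manifest.write(outdir / "manifest.json")
    return manifest


def _aligned_summary(result: RunResult, cfg: SimConfig) -> pd.DataFrame:
    """Summary reindexed on the full sampling grid; extinct tail -> 0."""
    grid = list(range(0, cfg.max_generations + 1, cfg.sampling_interval))
    if grid[-1] != cfg.max_generations:
        grid.append(cfg.max_generations)
    frame = result.summary.set_index("generation").reindex(grid)
    frame["popsize"] = frame["popsize"].fillna(0).astype(int)
    frame["mean_fitness"] = frame["mean_fitness"].where(frame["popsize"] > 0, 0.0)
    frame["extinct"] = frame["popsize"] == 0
    frame.index.name = "generation"
    return frame.reset_index()


def replicate_sweep(
    base_cfg: SimConfig,
    grid: dict[str, list],
    replicates: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Replicated runs over a parameter grid, aggregated per sampling point.

    Grid keys name SimConfig fields or ``trajectory.<field>``.  Returns
    mean +/- standard error of the mean fitness, extinction fraction and
    driver statistics per grid point per sampling generation.  With one
    replicate the SEM is undefined and reported as NaN.
    """
    if not grid:
        raise ValueError("parameter grid must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    master = base_cfg.seed if seed is None else seed
    names = list(grid)
    rows = []
    for point in itertools.product(*(grid[name] for name in names)):
        cfg = base_cfg
        for name, value in zip(names, point):
            if name.startswith("trajectory."):
                traj = replace(cfg.trajectory, **{name.split(".", 1)[1]: value})
                cfg = replace(cfg, trajectory=traj)
            else:
                cfg = replace(cfg, **{name: value})
        per_rep = []
        for rep in range(replicates):
            rep_cfg = replace(cfg, seed=derive_seed(master, tuple(point), rep))
            result = run_simulation(rep_cfg)
            frame = _aligned_summary(result, cfg)
            frame["replicate"] = rep
            per_rep.append(frame)
        stacked = pd.concat(per_rep, ignore_index=True)
        grouped = stacked.groupby("generation")
        agg = pd.DataFrame(
            {
                "mean_fitness_mean": grouped["mean_fitness"].mean(),
                "mean_fitness_sem": grouped["mean_fitness"].std(ddof=1)
                / np.sqrt(replicates),
                "popsize_mean": grouped["popsize"].mean(),
                "extinct_fraction": grouped["extinct"].mean(),
                "adaptive_steps_mean": grouped["adaptive_steps"].mean(),
                "mean_step_s_mean": grouped["mean_step_s"].mean(),
            }
        ).reset_index()
        if replicates == 1:
            agg["mean_fitness_sem"] = np.nan
        agg["replicates"] = replicates
        for name, value in zip(names, point):
            agg[name] = value
        rows.append(agg)
    return pd.concat(rows, ignore_index=True)
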