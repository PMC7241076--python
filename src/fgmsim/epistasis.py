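"""Epistasis between driver mutations and genotypic-landscape statistics.

Under the Gaussian fitness function, the epistasis coefficient of a pair
of mutations i, j with phenotypic effects r_i, r_j fixed at times when
the optimum sat at o_i, o_j is

    e_ij = log( w_ij * w_0 / (w_i * w_j) )            (log-ratio form)
         = -2 (r_i - o_i)^T S^-1 (r_j - o_j)          (geometric form)

where the double mutant carries phenotype z0 + r_i + r_j and adapts to
the additive optimum o_i + o_j.  The two forms agree exactly (expand the
quadratic form), which a test enforces on random anisotropic instances.

A genotypic landscape over k selected drivers assigns each of the 2^k
presence/absence combinations the fitness of phenotype z0 + sum(r_i)
against optimum sum(o_i).  Its ruggedness is summarized by the fraction
of sign epistasis (simple and reciprocal) over all locus pairs in all
backgrounds, and by the roughness-to-slope ratio of the best additive
fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd

from .landscape import SelectionMatrix, as_phenotype, evaluate_fitness

__all__ = [
    "GenotypicLandscape",
    "epistasis_log_ratio",
    "epistasis_geometric",
    "build_genotypic_landscape",
    "fraction_sign_epistasis",
    "roughness_to_slope",
    "landscape_from_steps",
]

SIGN_TOL = 1e-12  # fitness effects within this of 0 count as neutral


def epistasis_log_ratio(w0: float, wi: float, wj: float, wij: float) -> float:
    """e_ij = ln(w_ij w_0 / (w_i w_j)); zero for multiplicative fitness."""
    for name, w in (("w0", w0), ("wi", wi), ("wj", wj), ("wij", wij)):
        if not (0.0 < w <= 1.0):
            raise ValueError(f"{name} must lie in (0, 1], got {w}")
    return float(np.log(wij) + np.log(w0) - np.log(wi) - np.log(wj))


def epistasis_geometric(r_i, r_j, opt_i, opt_j, S) -> float:
    """e_ij = -2 (r_i - o_i)^T S^-1 (r_j - o_j)."""
    S = S if isinstance(S, SelectionMatrix) else SelectionMatrix(S)
    a = as_phenotype(r_i, S.n) - as_phenotype(opt_i, S.n)
    b = as_phenotype(r_j, S.n) - as_phenotype(opt_j, S.n)
    return float(-2.0 * a @ S.inverse @ b)


@dataclass(frozen=True)
class GenotypicLandscape:
    """Fitness of all 2^k combinations of k driver mutations.

    ``fitness[g]`` is indexed by the genotype bitmask ``g`` (bit i set =
    driver i present).  ``effects`` are the drivers' phenotypic
    displacements, ``optima`` the optimum vectors at their fixation
    times, ``z0`` the shared background phenotype.
    """

    effects: np.ndarray  # (k, n)
    optima: np.ndarray  # (k, n)
    z0: np.ndarray
    S: SelectionMatrix
    fitness: np.ndarray  # (2**k,)

    @property
    def k(self) -> int:
        return self.effects.shape[0]

    def genotype_fitness(self, bits: tuple[int, ...]) -> float:
        g = sum(b << i for i, b in enumerate(bits))
        return float(self.fitness[g])

    def to_frame(self) -> pd.DataFrame:
        """One row per genotype: bitstring (driver 1 first) and fitness."""
        rows = [
            ("".join(str((g >> i) & 1) for i in range(self.k)), float(w))
            for g, w in enumerate(self.fitness)
        ]
        return pd.DataFrame(rows, columns=["genotype", "fitness"])


def build_genotypic_landscape(drivers, z0, S) -> GenotypicLandscape:
    """Landscape over k >= 2 drivers given as (effect, optimum) pairs.

    Genotype fitness is evaluated at phenotype z0 + sum of selected
    effects against the sum of the selected drivers' optima (the
    additive-optimum convention of the changing-TME epistasis
    definition); the wild type faces the origin optimum.
    """
    S = S if isinstance(S, SelectionMatrix) else SelectionMatrix(S)
    effects = np.array([as_phenotype(r, S.n) for r, _ in drivers], dtype=float)
    optima = np.array([as_phenotype(o, S.n) for _, o in drivers], dtype=float)
    k = effects.shape[0]
    if k < 2:
        raise ValueError("a genotypic landscape needs at least 2 drivers")
    z0 = as_phenotype(z0, S.n)
    fitness = np.empty(2**k)
    for g in range(2**k):
        sel = [(g >> i) & 1 for i in range(k)]
        z = z0 + effects.T @ sel
        opt = optima.T @ sel
        fitness[g] = evaluate_fitness(z, opt, S)
    return GenotypicLandscape(effects=effects, optima=optima, z0=z0, S=S, fitness=fitness)


def landscape_from_steps(steps: pd.DataFrame, trajectory_optima, z0, S, k: int = 4,
                         selection: str = "first") -> GenotypicLandscape:
    """Landscape from a run's adaptive-step log.

    ``trajectory_optima`` maps fixation generation -> optimum vector
    (a callable).  ``selection='first'`` takes the first k fixed drivers,
    the default when a run yields more.
    """
    if len(steps) < 2:
        raise ValueError("need at least 2 adaptive steps to build a landscape")
    ordered = steps.sort_values("fixation_gen")
    if selection == "first":
        chosen = ordered.head(k)
    elif selection == "largest":
        chosen = ordered.reindex(
            ordered["s_at_fixation"].abs().sort_values(ascending=False).index
        ).head(k)
    else:
        raise ValueError(f"unknown driver selection rule {selection!r}")
    n = np.asarray(z0).size
    drivers = []
    for _, row in chosen.iterrows():
        r = np.array([row[f"effect_{j}"] for j in range(n)])
        o = trajectory_optima(int(row["fixation_gen"]))
        drivers.append((r, o))
    return build_genotypic_landscape(drivers, z0, S)


def _sign(x: float) -> int:
    if x > SIGN_TOL:
        return 1
    if x < -SIGN_TOL:
        return -1
    return 0


def _pair_background_classes(fitness: np.ndarray, k: int):
    """Yield (changes_i, changes_j) sign-change flags per pair-background.

    For each unordered pair (i, j) and each background of the remaining
    k-2 loci, a mutation 'changes sign' when its fitness effect is
    non-neutral both with and without the partner and the signs differ.
    """
    for i, j in combinations(range(k), 2):
        others = [x for x in range(k) if x not in (i, j)]
        for bg_bits in product((0, 1), repeat=len(others)):
            bg = sum(b << o for o, b in zip(others, bg_bits))
            w00 = fitness[bg]
            w10 = fitness[bg | (1 << i)]
            w01 = fitness[bg | (1 << j)]
            w11 = fitness[bg | (1 << i) | (1 << j)]
            di_without = _sign(w10 - w00)
            di_with = _sign(w11 - w01)
            dj_without = _sign(w01 - w00)
            dj_with = _sign(w11 - w10)
            ci = di_without != 0 and di_with != 0 and di_without != di_with
            cj = dj_without != 0 and dj_with != 0 and dj_without != dj_with
            yield ci, cj


def fraction_sign_epistasis(lsc: GenotypicLandscape | np.ndarray, k: int | None = None
                            ) -> tuple[float, float]:
    """(simple, reciprocal) sign-epistasis fractions over pair-backgrounds.

    Simple: exactly one of the pair reverses the sign of its fitness
    effect on the other's background; reciprocal (complex): both do.
    Fractions are over all C(k,2) * 2^(k-2) pair-background combinations.
    """
    if isinstance(lsc, GenotypicLandscape):
        fitness, k = lsc.fitness, lsc.k
    else:
        fitness = np.asarray(lsc, dtype=float)
        k = int(np.log2(fitness.size)) if k is None else k
        if 2**k != fitness.size:
            raise ValueError("fitness table size must be 2^k")
    total = simple = reciprocal = 0
    for ci, cj in _pair_background_classes(fitness, k):
        total += 1
        if ci and cj:
            reciprocal += 1
        elif ci or cj:
            simple += 1
    return simple / total, reciprocal / total


def roughness_to_slope(lsc: GenotypicLandscape | np.ndarray, k: int | None = None,
                       log_fitness: bool = False) -> float:
    """Roughness/slope ratio of the best additive model of the landscape.

    Fits fitness (or log fitness) on the k presence indicators plus an
    intercept by least squares; roughness is the RMS residual, slope the
    mean absolute additive coefficient.  0 for exactly additive
    landscapes; raises for the degenerate all-zero-slope case.
    """
    if isinstance(lsc, GenotypicLandscape):
        fitness, k = lsc.fitness, lsc.k
    else:
        fitness = np.asarray(lsc, dtype=float)
        k = int(np.log2(fitness.size)) if k is None else k
        if 2**k != fitness.size:
            raise ValueError("fitness table size must be 2^k")
    y = np.log(fitness) if log_fitness else fitness
    G = np.arange(2**k)
    X = np.column_stack(
        [np.ones(2**k)] + [((G >> i) & 1).astype(float) for i in range(k)]
    )
    coef, _res, _rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    roughness = float(np.sqrt(np.mean(resid**2)))
    slope = float(np.mean(np.abs(coef[1:])))
    if slope <= 1e-12 * max(1.0, float(np.abs(y).max())):
        raise ValueError("degenerate additive-null landscape: slope is 0")
    return roughness / slope
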