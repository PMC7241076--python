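"""Diploid L-locus genomes, allele genealogies and driver fixation.

Each cell carries ``L`` loci with ``c`` homologous copies (default the
diploid c = 2); every copy holds an allele id.  Alleles form per-locus
multifurcating trees rooted at the ancestral (zero-effect) allele of the
locus; each derived allele stores its own phenotypic displacement and the
cumulative displacement along its ancestry, so genome phenotypes are
additive over all copies at all loci.

During replication every allele copy in each daughter mutates
independently with probability ``u`` (per-locus mutation rate per genome
replication), and, independently, each locus of each daughter undergoes a
chromosome-instability (CIN) event with probability ``r_c``: one homolog,
chosen uniformly, overwrites the other copies (copy-neutral, ploidy is
preserved).

An allele is recorded as an *adaptive step* (positively selected driver)
at the first generation when every allele copy at its locus in every
living cell descends from it — i.e. its branch of the allele tree is the
sole survivor.  Once recorded a step is never retracted, even if the
optimum later moves and the driver becomes deleterious.
"""

from __future__ import annotations

import numpy as np

from .landscape import as_phenotype

__all__ = [
    "AlleleTable",
    "ancestral_genome",
    "replicate_genome",
    "compute_phenotype",
    "live_copy_counts",
    "record_adaptive_steps",
    "mutate_genomes",
    "apply_cin",
]


class _GrowArray:
    """Amortized-append 2-D float array (allele effect storage)."""

    def __init__(self, ncol: int, capacity: int = 64):
        self._data = np.zeros((capacity, ncol), dtype=float)
        self._size = 0

    def append(self, row: np.ndarray) -> int:
        if self._size == self._data.shape[0]:
            self._data = np.vstack([self._data, np.zeros_like(self._data)])
        self._data[self._size] = row
        self._size += 1
        return self._size - 1

    @property
    def view(self) -> np.ndarray:
        return self._data[: self._size]


class CopyCounts:
    """Live allele-copy tally, maintained incrementally by the engine.

    Mirrors :func:`live_copy_counts` without rescanning every genome each
    generation; a simulation invariant test holds the two equal.
    """

    def __init__(self, capacity: int = 64):
        self._data = np.zeros(capacity, dtype=np.int64)
        self._size = 0

    def resize(self, n_alleles: int) -> None:
        if n_alleles > self._data.size:
            grow = max(n_alleles, 2 * self._data.size)
            self._data = np.concatenate(
                [self._data, np.zeros(grow - self._data.size, dtype=np.int64)]
            )
        self._size = max(self._size, n_alleles)

    @property
    def view(self) -> np.ndarray:
        return self._data[: self._size]

    def add_genomes(self, genomes: np.ndarray, sign: int = 1) -> None:
        if genomes.size == 0:
            return
        delta = np.bincount(genomes.ravel(), minlength=self._size)
        self._data[: delta.size] += sign * delta.astype(np.int64)

    def alive(self) -> np.ndarray:
        return np.nonzero(self.view > 0)[0]


class AlleleTable:
    """Columnar store of all alleles of a run, all loci together.

    Ids ``0 .. L-1`` are the ancestral alleles (zero effect, no parent,
    one per locus); derived alleles append after them.
    """

    def __init__(self, L: int, n_traits: int):
        if L < 1 or n_traits < 1:
            raise ValueError("L and n_traits must be >= 1")
        self.L = L
        self.n_traits = n_traits
        self._locus_cache: np.ndarray | None = None
        self.locus: list[int] = list(range(L))
        self.parent: list[int] = [-1] * L
        self.origin_gen: list[int] = [0] * L
        self._disp = _GrowArray(n_traits)
        self._cum = _GrowArray(n_traits)
        zero = np.zeros(n_traits)
        for _ in range(L):
            self._disp.append(zero)
            self._cum.append(zero)

    def __len__(self) -> int:
        return len(self.locus)

    def add_loci(self, extra: int) -> list[int]:
        """Append ``extra`` new loci with fresh ancestral alleles.

        Supports the polygenic-resistance intervention (L expansion);
        returns the new ancestral allele ids.
        """
        ids = []
        zero = np.zeros(self.n_traits)
        for k in range(extra):
            self.locus.append(self.L + k)
            self.parent.append(-1)
            self.origin_gen.append(0)
            self._disp.append(zero)
            self._cum.append(zero)
            ids.append(len(self.locus) - 1)
        self.L += extra
        return ids

    def new_allele(
        self, locus: int, parent: int, origin_gen: int, displacement: np.ndarray
    ) -> int:
        if not (0 <= locus < self.L):
            raise KeyError(f"locus {locus} out of range")
        if not (0 <= parent < len(self)):
            raise KeyError(f"unknown parent allele {parent}")
        r = as_phenotype(displacement, self.n_traits)
        self.locus.append(locus)
        self.parent.append(parent)
        self.origin_gen.append(origin_gen)
        self._disp.append(r)
        self._cum.append(self._cum.view[parent] + r)
        return len(self.locus) - 1

    @property
    def displacement(self) -> np.ndarray:
        return self._disp.view

    @property
    def cumulative(self) -> np.ndarray:
        """Summed displacement along each allele's ancestry."""
        return self._cum.view

    def ancestry(self, allele_id: int) -> list[int]:
        """Chain of ids from ``allele_id`` up to its ancestral root."""
        if not (0 <= allele_id < len(self)):
            raise KeyError(f"unknown allele id {allele_id}")
        chain = [allele_id]
        while self.parent[chain[-1]] >= 0:
            chain.append(self.parent[chain[-1]])
        return chain

    def locus_array(self) -> np.ndarray:
        if self._locus_cache is None or self._locus_cache.size != len(self.locus):
            self._locus_cache = np.asarray(self.locus, dtype=np.int64)
        return self._locus_cache


def ancestral_genome(L: int, c: int = 2) -> np.ndarray:
    """Genome of all-ancestral alleles: (L, c) array of allele ids."""
    return np.repeat(np.arange(L, dtype=np.int64)[:, None], c, axis=1)


def compute_phenotype(genome: np.ndarray, z_base, table: AlleleTable) -> np.ndarray:
    """z_base plus the summed cumulative effect of every allele copy."""
    genome = np.asarray(genome)
    z = as_phenotype(z_base, table.n_traits)
    if genome.min(initial=0) < 0 or genome.max(initial=0) >= len(table):
        raise KeyError("genome refers to unknown allele ids")
    return z + table.cumulative[genome.ravel()].sum(axis=0)


def replicate_genome(
    genome: np.ndarray,
    u: float,
    cin_rate: float,
    M: np.ndarray,
    t: int,
    table: AlleleTable,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Replicate one genome into two daughters with mutation and CIN.

    Reference single-genome contract; the simulation engine uses the
    vectorized :func:`mutate_genomes` / :func:`apply_cin` path, which a
    test holds to the same per-copy event distribution.
    """
    from .landscape import mvn_factor

    if not (0.0 <= u <= 1.0 and 0.0 <= cin_rate <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    A = mvn_factor(M)
    L, c = genome.shape
    new_ids: list[int] = []
    daughters = []
    for _ in range(2):
        d = np.array(genome, dtype=np.int64, copy=True)
        for locus in range(L):
            for copy in range(c):
                if rng.random() < u:
                    r = A @ rng.standard_normal(A.shape[0])
                    aid = table.new_allele(locus, int(d[locus, copy]), t, r)
                    d[locus, copy] = aid
                    new_ids.append(aid)
            if cin_rate > 0 and rng.random() < cin_rate:
                src = int(rng.integers(c))
                d[locus, :] = d[locus, src]
        daughters.append(d)
    return daughters[0], daughters[1], new_ids


def mutate_genomes(
    genomes: np.ndarray,
    phen: np.ndarray,
    u: float,
    factor: np.ndarray,
    t: int,
    table: AlleleTable,
    rng: np.random.Generator,
    counts: "CopyCounts | None" = None,
) -> list[int]:
    """Per-copy Bernoulli(u) mutation over a (D, L, c) genome batch, in place.

    Draws the total event count binomially and scatters events over
    distinct copies — the same joint law as independent per-copy
    Bernoulli trials.  Updates ``phen`` additively with each displacement
    and, when given, the live copy tally ``counts``.
    """
    D = genomes.shape[0]
    if D == 0 or u <= 0.0:
        return []
    total = genomes.size
    k = int(rng.binomial(total, u))
    if k == 0:
        return []
    flat = rng.choice(total, size=k, replace=False)
    cells, rem = np.divmod(flat, genomes.shape[1] * genomes.shape[2])
    loci, copies = np.divmod(rem, genomes.shape[2])
    disp = rng.standard_normal((k, factor.shape[0])) @ factor.T
    new_ids = []
    parents = []
    for i in range(k):
        cell, locus, copy = int(cells[i]), int(loci[i]), int(copies[i])
        parent = int(genomes[cell, locus, copy])
        aid = table.new_allele(locus, parent, t, disp[i])
        genomes[cell, locus, copy] = aid
        phen[cell] += disp[i]
        new_ids.append(aid)
        parents.append(parent)
    if counts is not None:
        counts.resize(len(table))
        np.add.at(counts.view, parents, -1)
        counts.view[new_ids] += 1
    return new_ids


def apply_cin(
    genomes: np.ndarray,
    phen: np.ndarray,
    cin_rate: float,
    table: AlleleTable,
    rng: np.random.Generator,
    counts: "CopyCounts | None" = None,
) -> int:
    """Per-locus Bernoulli(r_c) homolog replacement over a batch, in place.

    One uniformly chosen homolog overwrites its sisters at the hit locus;
    phenotypes are adjusted by the cumulative-effect difference.  Returns
    the number of CIN events applied.
    """
    D, L, c = genomes.shape
    if D == 0 or cin_rate <= 0.0:
        return 0
    total = D * L
    k = int(rng.binomial(total, cin_rate))
    if k == 0:
        return 0
    flat = rng.choice(total, size=k, replace=False)
    cells, loci = np.divmod(flat, L)
    src = rng.integers(0, c, size=k)
    cum = table.cumulative
    # events hit distinct (cell, locus) pairs, so updates are independent
    old = genomes[cells, loci, :].copy()  # (k, c)
    kept = old[np.arange(k), src]  # (k,)
    genomes[cells, loci, :] = kept[:, None]
    delta = c * cum[kept] - cum[old].sum(axis=1)  # (k, n)
    np.add.at(phen, cells, delta)
    if counts is not None:
        counts.resize(len(table))
        view = counts.view
        dec = np.bincount(old.ravel(), minlength=view.size)
        inc = np.bincount(kept, minlength=view.size) * c
        view += inc - dec
    return k


def live_copy_counts(genomes: np.ndarray, table: AlleleTable) -> np.ndarray:
    """Copy count of every allele across all living genomes.

    Conservation: the counts at each locus sum to c times the number of
    living cells.
    """
    genomes = np.asarray(genomes)
    if genomes.size and genomes.max() >= len(table):
        raise KeyError("genomes refer to unknown allele ids")
    return np.bincount(genomes.ravel(), minlength=len(table))


def _deepest_common_ancestor(present: np.ndarray, table: AlleleTable) -> int:
    """Deepest allele of which every present allele is a descendant."""
    chain0 = table.ancestry(int(present[0]))  # deep -> root
    pos = {aid: i for i, aid in enumerate(chain0)}
    cut = 0
    for aid in present[1:]:
        a = int(aid)
        while True:
            idx = pos.get(a)
            if idx is not None and idx >= cut:
                cut = idx
                break
            a = table.parent[a]
            if a < 0:  # disjoint roots: different loci mixed up
                raise ValueError("present alleles do not share an ancestral root")
    return chain0[cut]


def record_adaptive_steps(
    genomes: np.ndarray,
    table: AlleleTable,
    fixed_base: dict[int, int],
    generation: int,
) -> list[tuple[int, int, int]]:
    """Newly fixed driver alleles at ``generation``, per locus.

    ``fixed_base`` maps locus -> deepest allele already recorded as fixed
    (initially the ancestral allele); it is updated in place.  Returns
    ``(allele_id, locus, generation)`` tuples ordered oldest branch first.
    An allele fixes when it and its descendants are the locus's only
    surviving branch across all living cells.
    """
    genomes = np.asarray(genomes)
    if genomes.ndim != 3:
        raise ValueError("genomes must be a (N, L, c) array")
    steps: list[tuple[int, int, int]] = []
    if genomes.shape[0] == 0:
        return steps
    for locus in range(genomes.shape[1]):
        base = fixed_base.get(locus, locus)
        present = np.unique(genomes[:, locus, :])
        if np.any(table.locus_array()[present] != locus):
            raise ValueError(f"allele at wrong locus in genomes (locus {locus})")
        if present.size == 1 and int(present[0]) == base:
            continue
        dca = _deepest_common_ancestor(present, table)
        if dca == base:
            continue
        chain = table.ancestry(dca)  # dca .. root
        if base not in chain:
            # fixed set can only deepen along one branch
            raise ValueError("fixation base is not ancestral to the population")
        newly = chain[: chain.index(base)]  # deep -> shallow, excluding base
        for aid in reversed(newly):
            steps.append((aid, locus, generation))
        fixed_base[locus] = dca
    return steps
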