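"""Genomes, mutation, CIN, allele genealogies and fixation detection."""

import numpy as np
import pytest

from fgmsim.genetics import (
    AlleleTable,
    CopyCounts,
    ancestral_genome,
    apply_cin,
    compute_phenotype,
    live_copy_counts,
    mutate_genomes,
    record_adaptive_steps,
    replicate_genome,
)

L, C, NTRAITS = 5, 2, 2
M = 0.25 * np.eye(NTRAITS)


def brute_force_phenotype(genome, z_base, table):
    """Independent oracle: explicit ancestry-chain enumeration per copy."""
    z = np.array(z_base, dtype=float)
    for locus in range(genome.shape[0]):
        for copy in range(genome.shape[1]):
            aid = int(genome[locus, copy])
            while aid >= 0:
                z = z + table.displacement[aid]
                aid = table.parent[aid]
    return z


def brute_force_fixed(genomes, table, locus):
    """All derived alleles from which every live copy at the locus descends."""

    def descends(a, anc):
        while a >= 0:
            if a == anc:
                return True
            a = table.parent[a]
        return False

    present = np.unique(genomes[:, locus, :])
    return [
        a
        for a in range(len(table))
        if table.locus[a] == locus
        and table.parent[a] >= 0
        and all(descends(int(p), a) for p in present)
    ]


class TestReplicateGenome:
    def test_no_mutation_no_cin_copies_parent(self, rng):
        table = AlleleTable(L, NTRAITS)
        g = ancestral_genome(L, C)
        d1, d2, new = replicate_genome(g, 0.0, 0.0, M, 1, table, rng)
        assert np.array_equal(d1, g) and np.array_equal(d2, g)
        assert new == [] and len(table) == L

    def test_certain_mutation_renews_every_copy(self, rng):
        table = AlleleTable(L, NTRAITS)
        g = ancestral_genome(L, C)
        d1, d2, new = replicate_genome(g, 1.0, 0.0, M, 3, table, rng)
        assert len(new) == 2 * L * C
        assert not np.any(d1 < L) and not np.any(d2 < L)
        assert all(table.origin_gen[a] == 3 for a in new)
        # parents recorded as the copied allele
        assert all(table.parent[a] >= 0 or table.parent[a] == -1 for a in new)

    def test_certain_cin_makes_every_locus_homozygous(self, rng):
        table = AlleleTable(L, NTRAITS)
        g = ancestral_genome(L, C)
        # give the parent distinct homologs first
        for locus in range(L):
            g[locus, 1] = table.new_allele(locus, locus, 0, rng.normal(size=NTRAITS))
        d1, d2, new = replicate_genome(g, 0.0, 1.0, M, 1, table, rng)
        assert new == []
        for d in (d1, d2):
            for locus in range(L):
                assert len(set(d[locus])) == 1
                assert d[locus, 0] in set(g[locus])

    def test_mutation_rate_expectation(self):
        # vectorized path at a rate large enough for a tight Monte-Carlo
        rng = np.random.default_rng(2)
        table = AlleleTable(L, NTRAITS)
        D, u = 100_000, 0.01
        genomes = np.repeat(ancestral_genome(L, C)[None], D, axis=0)
        phen = np.zeros((D, NTRAITS))
        new = mutate_genomes(genomes, phen, u, np.linalg.cholesky(M), 1, table, rng)
        expected = u * L * C
        assert abs(len(new) / D - expected) / expected < 0.05
        # and at the literature per-locus rate, against a 4-sigma binomial band
        rng = np.random.default_rng(3)
        table = AlleleTable(L, NTRAITS)
        D, u = 1_000_000, 4e-5
        genomes = np.repeat(ancestral_genome(L, C)[None], D, axis=0)
        phen = np.zeros((D, NTRAITS))
        new = mutate_genomes(genomes, phen, u, np.linalg.cholesky(M), 1, table, rng)
        mean = u * L * C
        sd4 = 4 * np.sqrt(D * L * C * u) / D
        assert abs(len(new) / D - mean) < max(0.05 * mean, sd4)

    def test_rates_outside_unit_interval_rejected(self, rng):
        table = AlleleTable(L, NTRAITS)
        g = ancestral_genome(L, C)
        with pytest.raises(ValueError):
            replicate_genome(g, 1.5, 0.0, M, 0, table, rng)


class TestComputePhenotype:
    def test_ancestral_genome_is_base(self):
        table = AlleleTable(L, NTRAITS)
        z = compute_phenotype(ancestral_genome(L, C), [1.0, -2.0], table)
        assert np.allclose(z, [1.0, -2.0])

    def test_single_derived_allele_adds_displacement(self):
        table = AlleleTable(L, NTRAITS)
        r = np.array([0.3, -0.1])
        aid = table.new_allele(2, 2, 5, r)
        g = ancestral_genome(L, C)
        g[2, 0] = aid
        assert np.allclose(compute_phenotype(g, np.zeros(2), table), r)

    def test_matches_brute_force_on_random_genomes(self, rng):
        table = AlleleTable(L, NTRAITS)
        g = ancestral_genome(L, C)
        for _ in range(6):  # grow nested ancestry chains
            g, _, _ = replicate_genome(g, 0.4, 0.2, M, 1, table, rng)[:3]
        z_base = np.array([0.5, 0.5])
        assert np.allclose(
            compute_phenotype(g, z_base, table),
            brute_force_phenotype(g, z_base, table),
            atol=1e-12,
        )

    def test_unknown_allele_errors(self):
        table = AlleleTable(L, NTRAITS)
        g = ancestral_genome(L, C)
        g[0, 0] = 99
        with pytest.raises(KeyError):
            compute_phenotype(g, np.zeros(2), table)


class TestConservation:
    def test_copy_counts_sum_to_c_times_population(self, rng):
        table = AlleleTable(L, NTRAITS)
        genomes = np.repeat(ancestral_genome(L, C)[None], 40, axis=0)
        phen = np.zeros((40, NTRAITS))
        mutate_genomes(genomes, phen, 0.2, np.linalg.cholesky(M), 1, table, rng)
        apply_cin(genomes, phen, 0.3, table, rng)
        counts = live_copy_counts(genomes, table)
        locus_of = table.locus_array()
        for locus in range(L):
            assert counts[locus_of == locus].sum() == C * 40

    def test_incremental_counts_match_rescan(self, rng):
        table = AlleleTable(L, NTRAITS)
        genomes = np.repeat(ancestral_genome(L, C)[None], 30, axis=0)
        phen = np.zeros((30, NTRAITS))
        counts = CopyCounts()
        counts.resize(len(table))
        counts.add_genomes(genomes)
        for _ in range(5):
            mutate_genomes(
                genomes, phen, 0.05, np.linalg.cholesky(M), 1, table, rng,
                counts=counts,
            )
            apply_cin(genomes, phen, 0.2, table, rng, counts=counts)
        rescan = live_copy_counts(genomes, table)
        assert np.array_equal(counts.view, rescan)

    def test_no_mutation_no_cin_pool_never_grows(self, rng):
        table = AlleleTable(L, NTRAITS)
        g = ancestral_genome(L, C)
        for _ in range(10):
            g, _, new = replicate_genome(g, 0.0, 0.0, M, 1, table, rng)
            assert new == []
        assert len(table) == L


class TestAdaptiveSteps:
    def test_monomorphic_derived_allele_is_one_step(self):
        table = AlleleTable(L, NTRAITS)
        aid = table.new_allele(1, 1, 4, np.array([0.2, 0.0]))
        genomes = np.repeat(ancestral_genome(L, C)[None], 3, axis=0)
        genomes[:, 1, :] = aid
        base = {l: l for l in range(L)}
        steps = record_adaptive_steps(genomes, table, base, 9)
        assert steps == [(aid, 1, 9)]
        assert base[1] == aid

    def test_surviving_ancestral_copy_blocks_fixation(self):
        table = AlleleTable(L, NTRAITS)
        aid = table.new_allele(1, 1, 4, np.array([0.2, 0.0]))
        genomes = np.repeat(ancestral_genome(L, C)[None], 3, axis=0)
        genomes[:, 1, 0] = aid  # heterozygous everywhere
        base = {l: l for l in range(L)}
        assert record_adaptive_steps(genomes, table, base, 9) == []

    def test_fixation_generation_matches_brute_force_scan(self):
        # a derived allele's descendants occupy all copies at generation 7
        table = AlleleTable(L, NTRAITS)
        a = table.new_allele(0, 0, 2, np.array([0.1, 0.0]))
        b = table.new_allele(0, a, 4, np.array([0.1, 0.0]))
        c = table.new_allele(0, a, 5, np.array([-0.1, 0.0]))
        genomes = np.repeat(ancestral_genome(L, C)[None], 3, axis=0)
        genomes[:, 0, :] = [[a, b], [b, c], [c, a]]
        base = {l: l for l in range(L)}
        steps = record_adaptive_steps(genomes, table, base, 7)
        assert steps == [(a, 0, 7)]
        assert brute_force_fixed(genomes, table, 0) == [a]

    def test_chain_fixation_records_each_allele_once_oldest_first(self):
        table = AlleleTable(L, NTRAITS)
        a = table.new_allele(3, 3, 1, np.array([0.1, 0.0]))
        b = table.new_allele(3, a, 2, np.array([0.1, 0.0]))
        genomes = np.repeat(ancestral_genome(L, C)[None], 2, axis=0)
        genomes[:, 3, :] = b
        base = {l: l for l in range(L)}
        steps = record_adaptive_steps(genomes, table, base, 6)
        assert [s[0] for s in steps] == [a, b]
        assert set(brute_force_fixed(genomes, table, 3)) == {a, b}
        # monotone: an already-recorded step is not re-recorded when a
        # deeper descendant fixes later
        d = table.new_allele(3, b, 5, np.array([0.0, 0.1]))
        genomes[:, 3, :] = d
        steps2 = record_adaptive_steps(genomes, table, base, 8)
        assert steps2 == [(d, 3, 8)]

    def test_inconsistent_population_raises(self):
        table = AlleleTable(L, NTRAITS)
        genomes = np.repeat(ancestral_genome(L, C)[None], 2, axis=0)
        genomes[0, 0, 0] = 2  # allele of locus 2 stored at locus 0
        with pytest.raises(ValueError):
            base = {l: l for l in range(L)}
            record_adaptive_steps(genomes, table, base, 1)


def test_add_loci_extends_table_with_fresh_roots():
    table = AlleleTable(2, NTRAITS)
    new = table.add_loci(3)
    assert table.L == 5 and len(new) == 3
    for aid in new:
        assert table.parent[aid] == -1
        assert np.all(table.cumulative[aid] == 0.0)
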