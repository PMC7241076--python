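"""Epistasis coefficients and genotypic-landscape statistics."""

import itertools

import numpy as np
import pytest

from fgmsim.engine import SimConfig, run_simulation
from fgmsim.epistasis import (
    build_genotypic_landscape,
    epistasis_geometric,
    epistasis_log_ratio,
    fraction_sign_epistasis,
    landscape_from_steps,
    roughness_to_slope,
)
from fgmsim.landscape import SelectionMatrix, evaluate_fitness
from fgmsim.trajectory import TrajectoryConfig, optimum_at


class TestLogRatio:
    def test_multiplicative_fitness_has_zero_epistasis(self):
        w0, wi, wj = 0.9, 0.7, 0.6
        assert epistasis_log_ratio(w0, wi, wj, wi * wj / w0) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_log_arithmetic(self):
        e = epistasis_log_ratio(1.0, np.exp(-0.1), np.exp(-0.1), np.exp(-0.4))
        assert e == pytest.approx(-0.2, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_fitness_domain_errors(self, bad):
        with pytest.raises(ValueError):
            epistasis_log_ratio(bad, 0.5, 0.5, 0.5)


class TestGeometric:
    def test_orthogonal_effects_static_origin_optimum(self):
        S = SelectionMatrix.isotropic(10.0, 2)
        e = epistasis_geometric([1.0, 0.0], [0.0, 1.0], [0, 0], [0, 0], S)
        assert e == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("sigma2", [1.0, 10.0, 40.0])
    def test_parallel_effects(self, sigma2):
        S = SelectionMatrix.isotropic(sigma2, 2)
        e = epistasis_geometric([1.0, 0.0], [1.0, 0.0], [0, 0], [0, 0], S)
        assert e == pytest.approx(-2.0 / sigma2, abs=1e-12)

    def test_identity_with_log_ratio_form(self, rng, random_spd_factory):
        """The geometric form equals the four-fitness log ratio exactly
        under the double-mutant construction (additive optimum)."""
        for _ in range(1000):
            n = int(rng.integers(2, 4))
            S = random_spd_factory(n, scale=float(rng.uniform(2, 20)))
            z0 = rng.normal(scale=1.0, size=n)
            ri, rj = rng.normal(scale=1.0, size=(2, n))
            oi, oj = rng.normal(scale=1.0, size=(2, n))
            w0 = evaluate_fitness(z0, np.zeros(n), S)
            wi = evaluate_fitness(z0 + ri, oi, S)
            wj = evaluate_fitness(z0 + rj, oj, S)
            wij = evaluate_fitness(z0 + ri + rj, oi + oj, S)
            e_ratio = epistasis_log_ratio(w0, wi, wj, wij)
            e_geo = epistasis_geometric(ri, rj, oi, oj, S)
            assert abs(e_ratio - e_geo) < 1e-10


class TestGenotypicLandscape:
    def test_zero_effect_drivers_give_flat_landscape(self):
        S = SelectionMatrix.isotropic(10.0, 2)
        z0 = np.array([1.0, 0.0])
        drivers = [(np.zeros(2), np.zeros(2))] * 2
        lsc = build_genotypic_landscape(drivers, z0, S)
        assert np.allclose(lsc.fitness, evaluate_fitness(z0, np.zeros(2), S))

    def test_sixteen_genotypes_and_wild_type_entry(self, rng):
        S = SelectionMatrix.isotropic(10.0, 2)
        z0 = np.array([0.5, -0.5])
        drivers = [(rng.normal(size=2), rng.normal(size=2)) for _ in range(4)]
        lsc = build_genotypic_landscape(drivers, z0, S)
        assert lsc.fitness.shape == (16,)
        assert lsc.genotype_fitness((0, 0, 0, 0)) == pytest.approx(
            evaluate_fitness(z0, np.zeros(2), S)
        )
        frame = lsc.to_frame()
        assert len(frame) == 16 and frame["genotype"].is_unique

    def test_pairwise_log_ratio_matches_geometric_in_all_backgrounds(self, rng):
        S = SelectionMatrix(np.array([[8.0, 2.0], [2.0, 5.0]]))
        z0 = np.array([0.3, 0.1])
        drivers = [(rng.normal(size=2), rng.normal(size=2)) for _ in range(4)]
        lsc = build_genotypic_landscape(drivers, z0, S)
        for i, j in itertools.combinations(range(4), 2):
            e_geo = epistasis_geometric(
                lsc.effects[i], lsc.effects[j], lsc.optima[i], lsc.optima[j], S
            )
            others = [x for x in range(4) if x not in (i, j)]
            for bits in itertools.product((0, 1), repeat=2):
                bg = sum(b << o for o, b in zip(others, bits))
                w0 = lsc.fitness[bg]
                wi = lsc.fitness[bg | (1 << i)]
                wj = lsc.fitness[bg | (1 << j)]
                wij = lsc.fitness[bg | (1 << i) | (1 << j)]
                assert abs(epistasis_log_ratio(w0, wi, wj, wij) - e_geo) < 1e-10

    def test_too_few_drivers_error(self):
        S = SelectionMatrix.isotropic(10.0, 2)
        with pytest.raises(ValueError):
            build_genotypic_landscape([(np.zeros(2), np.zeros(2))], np.zeros(2), S)


def brute_force_sign_classifier(fitness, k, tol=1e-12):
    """Independent enumeration over pair-backgrounds."""
    def sgn(x):
        return 0 if abs(x) <= tol else (1 if x > 0 else -1)

    total = simple = recip = 0
    for i, j in itertools.combinations(range(k), 2):
        others = [x for x in range(k) if x not in (i, j)]
        for bits in itertools.product((0, 1), repeat=len(others)):
            bg = sum(b << o for o, b in zip(others, bits))
            flips = 0
            for a, partner in ((i, j), (j, i)):
                d_without = fitness[bg | (1 << a)] - fitness[bg]
                d_with = (
                    fitness[bg | (1 << a) | (1 << partner)]
                    - fitness[bg | (1 << partner)]
                )
                sa, sb = sgn(d_without), sgn(d_with)
                flips += sa != 0 and sb != 0 and sa != sb
            total += 1
            simple += flips == 1
            recip += flips == 2
    return simple / total, recip / total


class TestSignEpistasis:
    def test_additive_fitness_landscape_has_none(self):
        k = 3
        coefs = np.array([0.05, -0.02, 0.08])
        G = np.arange(2**k)
        X = np.stack([((G >> i) & 1) for i in range(k)], axis=1)
        fitness = 0.5 + X @ coefs
        assert fraction_sign_epistasis(fitness, k) == (0.0, 0.0)
        assert roughness_to_slope(fitness, k) == pytest.approx(0.0, abs=1e-12)

    def test_hand_built_reciprocal_pair(self):
        # both mutations beneficial alone, deleterious on the other's back
        fitness = np.array([1.0, 1.2, 1.2, 1.1])
        simple, recip = fraction_sign_epistasis(fitness, 2)
        assert (simple, recip) == (0.0, 1.0)

    def test_hand_built_simple_pair(self):
        fitness = np.array([1.0, 1.2, 1.1, 1.15])
        # mutation i: +0.2 alone, +0.05 with j (no flip);
        # mutation j: +0.1 alone, -0.05 with i (flip) -> simple
        simple, recip = fraction_sign_epistasis(fitness, 2)
        assert (simple, recip) == (1.0, 0.0)

    def test_random_landscapes_match_brute_force(self, rng):
        for _ in range(50):
            fitness = rng.uniform(0.05, 1.0, size=8)
            assert fraction_sign_epistasis(fitness, 3) == pytest.approx(
                brute_force_sign_classifier(fitness, 3)
            )


class TestRoughnessToSlope:
    def test_matches_balanced_design_closed_form(self):
        # in a full 2^k factorial the additive coefficients are the
        # differences of the per-locus means -- an independent oracle
        fitness = np.array([1.0, 1.1, 1.2, 1.5])
        k = 2
        G = np.arange(4)
        X = np.stack([((G >> i) & 1) for i in range(k)], axis=1)
        coefs = [
            fitness[X[:, i] == 1].mean() - fitness[X[:, i] == 0].mean()
            for i in range(k)
        ]
        intercept = fitness.mean() - 0.5 * sum(coefs)
        fit = intercept + X @ np.array(coefs)
        roughness = np.sqrt(np.mean((fitness - fit) ** 2))
        expected = roughness / np.mean(np.abs(coefs))
        assert roughness_to_slope(fitness, k) == pytest.approx(expected, abs=1e-12)

    def test_scale_invariance(self, rng):
        fitness = rng.uniform(0.1, 1.0, size=16)
        a = roughness_to_slope(fitness, 4)
        b = roughness_to_slope(3.7 * fitness, 4)
        assert a == pytest.approx(b, rel=1e-10)

    def test_degenerate_additive_null_errors(self):
        with pytest.raises(ValueError):
            roughness_to_slope(np.full(8, 0.5), 3)

    def test_log_fitness_switch(self):
        # multiplicative landscape is additive in logs: ratio 0 there
        w = np.array([0.9, 0.6, 0.45, 0.3])  # w11 = wi*wj/w0 exactly
        assert roughness_to_slope(w, 2, log_fitness=True) == pytest.approx(
            0.0, abs=1e-10
        )
        assert roughness_to_slope(w, 2) > 0.0


class TestFromSimulation:
    def test_reciprocal_sign_epistasis_attainable_under_cyclic_optimum(self):
        """Across replicate cyclic-TME runs, run-derived driver landscapes
        exhibit sign epistasis, including the reciprocal kind."""
        found_sign = found_recip = 0
        traj = TrajectoryConfig(regime="cyclic", A=4.0)
        for seed in range(1, 13):
            cfg = SimConfig(seed=seed, max_generations=2000, N_max=300, G=30,
                            r_c=0.01, trajectory=traj)
            result = run_simulation(cfg)
            if len(result.steps) < 2:
                continue
            lsc = landscape_from_steps(
                result.steps,
                lambda t: optimum_at(traj, t),
                np.zeros(2),
                cfg.selection_matrix(),
                k=4,
            )
            simple, recip = fraction_sign_epistasis(lsc)
            found_sign += (simple + recip) > 0
            found_recip += recip > 0
        assert found_sign >= 1
        assert found_recip >= 1
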