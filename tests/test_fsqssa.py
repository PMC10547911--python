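import math

import numpy as np
import pytest
from scipy import stats

from scfse.fsqssa import (
    ACORN,
    HICKORY,
    NORMAL,
    FsqssaConfig,
    SearchState,
    Squirrel,
    assign_roles,
    binarize,
    glide_update,
    init_population,
    levy_relocate,
    levy_steps,
    run_fsqssa,
    s_min,
    seasonal_constant,
)


CFG = FsqssaConfig()


class TestBinarize:
    @pytest.mark.parametrize(
        "theta,bit",
        [(0.0, 0), (np.pi / 2, 1), (np.pi / 4, 1), (np.pi / 8, 0), (3 * np.pi / 8, 1)],
    )
    def test_threshold_inclusive_at_quarter_pi(self, theta, bit):
        assert binarize(np.array([theta]))[0] == bit

    def test_qbit_amplitudes_normalized(self):
        rng = np.random.default_rng(0)
        theta = rng.uniform(0, np.pi / 2, 1000)
        np.testing.assert_allclose(
            np.cos(theta) ** 2 + np.sin(theta) ** 2, 1.0, atol=1e-12)


class TestInit:
    def test_degenerate_bounds_collapse(self):
        cfg = FsqssaConfig(theta_low=0.3, theta_high=0.3 + 1e-15)
        state = init_population(cfg, 5, np.random.default_rng(0))
        for s in state.population:
            np.testing.assert_allclose(s.theta, 0.3, atol=1e-12)

    def test_angles_within_bounds(self):
        state = init_population(CFG, 20, np.random.default_rng(1))
        for s in state.population:
            assert np.all(s.theta >= 0) and np.all(s.theta <= np.pi / 2)

    def test_same_seed_identical_population(self):
        s1 = init_population(CFG, 10, np.random.default_rng(42))
        s2 = init_population(CFG, 10, np.random.default_rng(42))
        for a, b in zip(s1.population, s2.population):
            np.testing.assert_array_equal(a.theta, b.theta)

    def test_tiny_dimension_rejected(self):
        with pytest.raises(ValueError):
            init_population(CFG, 1, np.random.default_rng(0))


def _state_with_fitness(fits, D=4):
    pop = [Squirrel(theta=np.full(D, 0.1)) for _ in fits]
    for s, f in zip(pop, fits):
        s.fitness = f
    return SearchState(population=pop)


class TestAssignRoles:
    def test_distinct_fitness_ranking(self):
        cfg = FsqssaConfig(pop_size=6, n_acorn=3)
        state = _state_with_fitness([0.5, 0.9, 0.6, 0.7, 0.8, 0.4])
        assign_roles(state, cfg)
        roles = [s.role for s in state.population]
        assert roles == [NORMAL, HICKORY, ACORN, ACORN, ACORN, NORMAL]

    def test_ties_broken_by_gene_count_then_index(self):
        cfg = FsqssaConfig(pop_size=5, n_acorn=3)
        pop = [Squirrel(theta=np.full(4, 1.0)) for _ in range(5)]  # all bits on
        pop[2] = Squirrel(theta=np.array([1.0, 1.0, 0.1, 0.1]))  # 2 genes only
        for s in pop:
            s.fitness = 0.5
        state = SearchState(population=pop)
        assign_roles(state, cfg)
        assert state.population[2].role == HICKORY  # fewest genes wins the tie
        assert state.population[0].role == ACORN  # then lowest index

    def test_default_role_counts(self):
        state = _state_with_fitness(list(np.linspace(0, 1, 50)))
        assign_roles(state, CFG)
        roles = [s.role for s in state.population]
        assert (roles.count(HICKORY), roles.count(ACORN), roles.count(NORMAL)) == (1, 3, 46)

    def test_unset_fitness_rejected(self):
        state = _state_with_fitness([0.1, None, 0.3, 0.2, 0.5])
        with pytest.raises(ValueError, match="roles"):
            assign_roles(state, FsqssaConfig(pop_size=5, n_acorn=3))


class TestGlide:
    def test_fixed_point_when_source_is_target(self):
        cfg = FsqssaConfig(pdp=0.0)
        src = np.array([0.2, 0.8, 1.1])
        out = glide_update(src, src.copy(), cfg, np.random.default_rng(0))
        np.testing.assert_allclose(out, src, atol=1e-15)

    def test_pdp_zero_always_glides(self):
        cfg = FsqssaConfig(pdp=0.0)
        rng = np.random.default_rng(1)
        src = np.full(6, 0.2)
        tgt = np.full(6, 1.0)
        for _ in range(50):
            out = glide_update(src, tgt, cfg, rng)
            # glide factor dg*Gc in [0.57, 1.33]: always moves past src toward tgt
            assert np.all(out > src)

    def test_pdp_one_always_escapes_to_uniform(self):
        cfg = FsqssaConfig(pdp=1.0)
        rng = np.random.default_rng(2)
        src = np.full(500, 0.2)
        out = glide_update(src, src.copy(), cfg, rng)
        assert np.all((out >= 0) & (out <= np.pi / 2))
        assert np.ptp(out) > 0.5  # fresh uniform draw, not the fixed point

    def test_output_clipped_to_bounds(self):
        cfg = FsqssaConfig(pdp=0.0)
        rng = np.random.default_rng(3)
        out = glide_update(np.array([1.5]), np.array([0.0]), cfg, rng)
        assert 0 <= out[0] <= np.pi / 2


class TestSeasonal:
    def test_identical_positions_zero(self):
        theta = np.array([0.4, 0.9])
        assert seasonal_constant(theta, theta) == 0.0

    def test_hand_evaluation(self):
        assert seasonal_constant(
            np.array([0.5, 0.5]), np.array([0.2, 0.1])
        ) == pytest.approx(0.25, abs=1e-12)

    def test_nonnegative(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            assert seasonal_constant(rng.random(5), rng.random(5)) >= 0

    def test_s_min_limits_and_monotonicity(self):
        assert s_min(0, 100) == pytest.approx(1e-6)
        assert s_min(100, 100) == pytest.approx(1e-6 / 365**2.5, rel=1e-9)
        vals = [s_min(t, 100) for t in range(1, 101)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_s_min_invalid_tm(self):
        with pytest.raises(ValueError):
            s_min(1, 0)


class TestLevy:
    def test_relocation_within_bounds_and_deterministic(self):
        out1 = levy_relocate(CFG, 50, np.random.default_rng(5))
        out2 = levy_relocate(CFG, 50, np.random.default_rng(5))
        np.testing.assert_array_equal(out1, out2)
        assert np.all((out1 >= 0) & (out1 <= np.pi / 2))

    def test_steps_are_heavy_tailed(self):
        steps = levy_steps(1.5, 100_000, np.random.default_rng(6))
        # excess kurtosis of a Gaussian is 0; Levy-stable tails blow it up
        assert stats.kurtosis(np.abs(steps)) > 10


def _size_fitness(D):
    return lambda mask: 1.0 - mask.sum() / D


class TestRunFsqssa:
    def test_elitist_trace_non_decreasing(self):
        cfg = FsqssaConfig(pop_size=10, max_iter=20)
        res = run_fsqssa(15, cfg, _size_fitness(15), np.random.default_rng(0))
        best = [r.best_fitness for r in res.trace]
        assert all(a <= b for a, b in zip(best, best[1:]))

    def test_single_iteration_trace_length(self):
        cfg = FsqssaConfig(pop_size=10, max_iter=1)
        res = run_fsqssa(8, cfg, _size_fitness(8), np.random.default_rng(1))
        assert len(res.trace) == 2  # initial evaluation + one update round

    def test_deterministic_given_seed(self):
        cfg = FsqssaConfig(pop_size=10, max_iter=10)
        r1 = run_fsqssa(12, cfg, _size_fitness(12), np.random.default_rng(7))
        r2 = run_fsqssa(12, cfg, _size_fitness(12), np.random.default_rng(7))
        np.testing.assert_array_equal(r1.mask, r2.mask)
        assert r1.fitness == r2.fitness
        assert [t.best_fitness for t in r1.trace] == [t.best_fitness for t in r2.trace]

    def test_role_counts_conserved_every_iteration(self):
        cfg = FsqssaConfig(pop_size=12, n_acorn=3, max_iter=15)
        res = run_fsqssa(10, cfg, _size_fitness(10), np.random.default_rng(2))
        for rec in res.trace:
            assert rec.role_counts == (1, 3, 8)

    def test_best_mask_never_empty(self):
        cfg = FsqssaConfig(pop_size=10, max_iter=30)
        res = run_fsqssa(6, cfg, _size_fitness(6), np.random.default_rng(3))
        assert res.mask.sum() >= 1

    def test_degenerate_size_objective_shrinks_mask(self):
        # the optimum of fitness = 1 - |S|/D is the smallest admissible mask
        cfg = FsqssaConfig(max_iter=100)
        res = run_fsqssa(30, cfg, _size_fitness(30), np.random.default_rng(4))
        assert res.trace[-1].n_selected_best < res.trace[0].n_selected_best
        assert res.trace[-1].n_selected_best <= 5

    def test_all_evaluations_failing_aborts(self):
        def broken(mask):
            raise RuntimeError("no fitness here")

        cfg = FsqssaConfig(pop_size=10, max_iter=2)
        with pytest.raises(RuntimeError, match="entire population"):
            run_fsqssa(8, cfg, broken, np.random.default_rng(5))

    def test_random_search_no_better_than_default(self):
        """Pdp=1 degenerates to random search; on a planted two-cluster
        problem its mean best fitness over seeds must not exceed the
        default algorithm's."""
        from scfse import FixtureSpec, generate, normalize_log, filter_zero_genes
        from scfse.pipeline import select_genes

        cm, _, _ = generate(FixtureSpec(n_cells=60, n_genes=30, n_informative=8, seed=0))
        expr = normalize_log(filter_zero_genes(cm))
        cfg_default = FsqssaConfig(pop_size=12, max_iter=15)
        cfg_random = FsqssaConfig(pop_size=12, max_iter=15, pdp=1.0)
        f_def, f_rnd = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            f_def.append(select_genes(expr, 2, cfg_default, rng).fitness)
            rng = np.random.default_rng(seed)
            f_rnd.append(select_genes(expr, 2, cfg_random, rng).fitness)
        assert np.mean(f_rnd) <= np.mean(f_def)
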