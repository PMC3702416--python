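"""Differential evolution: operators, invariants, archives, restarts."""

import numpy as np
import pandas as pd
import pytest

from phenofit.evolve import (
    GREEDY,
    NON_GREEDY,
    DESettings,
    _rng_for,
    best_member,
    crossover,
    mutate,
    resample_restart,
    run_de,
    select,
)
from phenofit.protocol import ProtocolSettings
from phenofit.sampling import Hypercube, lh_sample


class TestMutate:
    def test_printed_arithmetic(self):
        v = mutate(
            np.array([1.0, 2.0]), np.array([1.5, 2.5]), np.array([0.5, 1.5]), F=0.1
        )
        assert np.allclose(v, [1.1, 2.1])

    def test_identical_coparents_give_parent(self):
        x = np.array([0.2, 3.0])
        xp = np.array([1.0, 1.0])
        assert np.array_equal(mutate(x, xp, xp, F=0.3), x)

    def test_f_to_zero_limit(self):
        x = np.array([0.2, 3.0])
        v = mutate(x, np.array([5.0, 5.0]), np.array([0.0, 0.0]), F=1e-12)
        assert np.allclose(v, x, atol=1e-10)

    def test_negative_components_clamped_to_zero(self):
        v = mutate(np.array([0.1]), np.array([0.0]), np.array([10.0]), F=0.5)
        assert v[0] == 0.0

    def test_frozen_indices_untouched(self):
        v = mutate(
            np.array([1.0, 2.0]),
            np.array([9.0, 9.0]),
            np.array([0.0, 0.0]),
            F=0.5,
            frozen_idx=np.array([1]),
        )
        assert v[1] == 2.0 and v[0] != 1.0


class TestCrossover:
    def test_c_zero_keeps_parent(self):
        rng = np.random.default_rng(0)
        x, v = np.array([1.0, 2.0, 3.0]), np.array([9.0, 9.0, 9.0])
        assert np.array_equal(crossover(x, v, 0.0, rng), x)

    def test_c_one_takes_mutant(self):
        rng = np.random.default_rng(0)
        x, v = np.array([1.0, 2.0, 3.0]), np.array([9.0, 9.0, 9.0])
        assert np.array_equal(crossover(x, v, 1.0, rng), v)

    def test_replay_of_generator_stream(self):
        # the draw-by-draw replay oracle: same stream, same componentwise rule
        x = np.arange(6, dtype=float)
        v = 100.0 + x
        u = crossover(x, v, 0.5, np.random.default_rng(1234))
        draws = np.random.default_rng(1234).uniform(size=6)
        expected = np.where(draws <= 0.5, v, x)
        assert np.array_equal(u, expected)


class TestSelect:
    def test_strictly_better_offspring_wins_greedy(self):
        assert select(72, 80, GREEDY) is True

    def test_equal_scores_greedy_keeps_parent(self):
        assert select(5, 5, GREEDY) is False

    def test_equal_scores_non_greedy_takes_offspring(self):
        assert select(5, 5, NON_GREEDY) is True

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            DESettings(N=3, generations=1)
        with pytest.raises(ValueError):
            DESettings(N=5, generations=1, F=1.5)
        with pytest.raises(ValueError):
            DESettings(N=5, generations=1, selection="elitist")


@pytest.fixture(scope="module")
def de_population(request):
    import phenofit

    model, wt = phenofit.make_wt()
    model.strains = phenofit.make_panel()
    cube = Hypercube(wt, 0.4, frozenset(model.fixed_names))
    return model, lh_sample(cube, 8, seed=99)


class TestRunDE:
    def test_zero_generations_returns_input(self, de_population, protocol_settings):
        model, population = de_population
        settings = DESettings(N=8, generations=0, seed=1)
        result = run_de(population, model, settings, protocol_settings)
        assert all(
            np.array_equal(a.values, b.values)
            for a, b in zip(result.population, population)
        )
        assert len(result.archive) == 8  # only the initial parents

    @pytest.mark.parametrize("rule", [GREEDY, NON_GREEDY])
    def test_per_lineage_objective_nondecreasing(self, de_population, protocol_settings, rule):
        model, population = de_population
        settings = DESettings(N=8, generations=6, seed=5, selection=rule)
        result = run_de(population, model, settings, protocol_settings)
        parents = result.archive[result.archive["role"] == "parent"]
        for _, lineage_rows in parents.groupby("lineage"):
            o = lineage_rows.sort_values("generation")["O_sel"].to_numpy()
            assert (np.diff(o) >= 0).all()
        best = result.trace["best_O_sel"].to_numpy()
        assert (np.diff(best) >= 0).all()

    def test_archive_row_count_formula(self, de_population, protocol_settings):
        model, population = de_population
        G = 5
        settings = DESettings(N=8, generations=G, seed=2)
        result = run_de(population, model, settings, protocol_settings)
        assert len(result.archive) == 8 * (2 * G + 1)
        offspring = result.archive[result.archive["role"] == "offspring"]
        assert len(offspring) == 8 * G
        # one offspring per parent per generation
        assert (
            offspring.groupby(["generation", "lineage"]).size() == 1
        ).all()

    def test_seeded_replay_bit_identical(self, de_population, protocol_settings):
        model, population = de_population
        settings = DESettings(N=8, generations=4, seed=123)
        a = run_de(population, model, settings, protocol_settings)
        b = run_de(population, model, settings, protocol_settings)
        pd.testing.assert_frame_equal(a.archive, b.archive)
        pd.testing.assert_frame_equal(a.trace, b.trace)

    def test_converged_population_is_fixed_point(self, de_population, protocol_settings):
        model, population = de_population
        clones = [population[0].copy() for _ in range(8)]
        settings = DESettings(N=8, generations=3, seed=7, selection=NON_GREEDY)
        result = run_de(clones, model, settings, protocol_settings)
        for v in result.population:
            assert np.array_equal(v.values, population[0].values)
        assert result.trace["best_O_sel"].nunique() == 1

    def test_population_size_mismatch_rejected(self, de_population, protocol_settings):
        model, population = de_population
        with pytest.raises(ValueError):
            run_de(population[:5], model, DESettings(N=8, generations=1), protocol_settings)

    def test_substreams_depend_on_generation_and_lineage(self):
        a = _rng_for(0, 1, 2).uniform()
        b = _rng_for(0, 2, 1).uniform()
        c = _rng_for(0, 1, 2).uniform()
        assert a == c and a != b


class TestRestart:
    def test_restart_population_size_and_center(self, de_population, protocol_settings):
        model, population = de_population
        settings = DESettings(N=8, generations=2, seed=11)
        result = run_de(population, model, settings, protocol_settings)
        newpop = resample_restart(result.archive, generation=2, fraction=1e-9, n=8, seed=1)
        assert len(newpop) == 8
        center, o_best = best_member(result.archive, 2)
        for v in newpop:
            assert np.allclose(v.values, center.values, rtol=1e-6)

    def test_best_member_tie_breaks_by_lowest_lineage(self, de_population, protocol_settings):
        model, population = de_population
        settings = DESettings(N=8, generations=1, seed=3)
        result = run_de(population, model, settings, protocol_settings)
        parents = result.archive[
            (result.archive["generation"] == 1) & (result.archive["role"] == "parent")
        ]
        top = parents["O_sel"].max()
        expected_lineage = parents[parents["O_sel"] == top]["lineage"].min()
        center, _ = best_member(result.archive, 1)
        row = parents[parents["lineage"] == expected_lineage].iloc[0]
        names = result.archive.attrs["param_names"]
        assert np.array_equal(center.values, row[names].to_numpy(dtype=float))

    def test_frozen_names_survive_restart(self, de_population, protocol_settings):
        model, population = de_population
        settings = DESettings(N=8, generations=1, seed=13)
        result = run_de(population, model, settings, protocol_settings)
        newpop = resample_restart(result.archive, 1, fraction=0.4, n=8, seed=2)
        center, _ = best_member(result.archive, 1)
        for v in newpop:
            for name in model.fixed_names:
                assert v[name] == center[name]
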