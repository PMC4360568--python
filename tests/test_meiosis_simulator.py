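"""Forward synergy simulator: transmission, zygote formation, viability,
generational equilibrium."""

import numpy as np
import pytest

from genload import (ModelParams, GenomeArchitecture, Individual,
                     SelectionRule, run_generations, equilibrium_summary)
from genload.meiosis_simulator import (transmit_gamete, form_zygote,
                                       classify_viability, stats_to_frame)
from genload.errors import ParameterError, ContractError, ExtinctionError

ARCH = GenomeArchitecture()
NO_SELECTION = SelectionRule(lethal_threshold=float("inf"),
                             postnatal_death_prob={})


class TestTransmitGamete:
    def test_empty_parent_gives_empty_gamete(self):
        parent = Individual(np.zeros(10, dtype=int), sex="female")
        rng = np.random.default_rng(0)
        assert transmit_gamete(parent, rng).sum() == 0

    def test_half_of_load_transmitted_on_average(self):
        # parent load 8: binomial expectation 4, 3*SE band at 1e5 draws
        parent = Individual(np.array([8] + [0] * 9), sex="male")
        rng = np.random.default_rng(1)
        draws = np.array([transmit_gamete(parent, rng).sum()
                          for _ in range(20_000)])
        se = np.sqrt(8 * 0.25 / len(draws))
        assert abs(draws.mean() - 4.0) < 3 * se


class TestFormZygote:
    def test_empty_gametes_no_influx(self):
        params = ModelParams(M=0, N=0)
        rng = np.random.default_rng(0)
        z = form_zygote(np.zeros(10, int), np.zeros(10, int), params, ARCH, rng)
        assert z.total_load == 0

    def test_poisson_influx_mean(self):
        params = ModelParams(M=7, N=1)
        rng = np.random.default_rng(2)
        empty = np.zeros(10, int)
        added = np.array([form_zygote(empty, empty, params, ARCH, rng).total_load
                          for _ in range(20_000)])
        se = np.sqrt(1.0 / len(added))
        assert abs(added.mean() - 1.0) < 3 * se

    def test_new_mutations_assigned_by_system_size(self):
        arch = GenomeArchitecture(system_sizes=(6000, 2000, 2000))
        params = ModelParams(M=0, N=2)
        rng = np.random.default_rng(3)
        empty = np.zeros(3, int)
        totals = np.zeros(3)
        reps = 20_000
        for _ in range(reps):
            totals += form_zygote(empty, empty, params, arch, rng).per_system_counts
        freqs = totals / totals.sum()
        expected = arch.weights
        se = np.sqrt(expected * (1 - expected) / totals.sum())
        assert (np.abs(freqs - expected) < 3 * se).all()

    def test_architecture_mismatch_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ContractError):
            form_zygote(np.zeros(3, int), np.zeros(3, int),
                        ModelParams(), ARCH, rng)


class TestClassifyViability:
    def test_four_in_one_system_is_lethal(self):
        ind = Individual(np.array([4] + [0] * 9), sex="male")
        rng = np.random.default_rng(0)
        assert classify_viability(ind, SelectionRule(), rng) == "lethal_conception"

    def test_all_counts_at_most_one_always_survives(self):
        ind = Individual(np.ones(10, dtype=int), sex="female")
        rng = np.random.default_rng(0)
        for _ in range(100):
            assert classify_viability(ind, SelectionRule(), rng) == "survivor"

    def test_three_with_certain_death_prob_dies_postnatally(self):
        rule = SelectionRule(postnatal_death_prob={3: 1.0, 2: 0.0})
        ind = Individual(np.array([3] + [0] * 9), sex="male")
        rng = np.random.default_rng(0)
        assert classify_viability(ind, rule, rng) == "postnatal_death"

    def test_nonessential_systems_ignored(self):
        arch = GenomeArchitecture(system_sizes=(2000, 2000),
                                  essential_flags=(True, False))
        ind = Individual(np.array([0, 5]), sex="male")
        rng = np.random.default_rng(0)
        assert classify_viability(ind, SelectionRule(), rng, arch) == "survivor"


class TestSelectionRule:
    def test_nonmonotone_death_probs_rejected(self):
        with pytest.raises(ParameterError):
            SelectionRule(postnatal_death_prob={2: 0.5, 3: 0.1})

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ParameterError):
            SelectionRule(lethal_threshold=0)


class TestRunGenerations:
    def test_no_selection_load_grows_by_N_per_generation(self):
        # E[mean load at g] = M0 + g*N; seeded run, generous MC band
        series = run_generations(ModelParams(M=4, N=1), ARCH, NO_SELECTION,
                                 pop_size=500, n_generations=50, seed=11)
        assert series[-1].mean_adult_load == pytest.approx(4 + 50, abs=3.0)
        assert all(s.zygote_loss_fraction == 0 for s in series)

    def test_default_rule_reaches_stationary_load(self):
        from scipy import stats as sstats
        series = run_generations(ModelParams(), ARCH, SelectionRule(),
                                 pop_size=2000, n_generations=150, seed=7)
        loads = [s.mean_adult_load for s in series[-50:]]
        fit = sstats.linregress(range(len(loads)), loads)
        # stationary: no trend distinguishable from noise, and bounded well
        # below the no-selection drift M0 + g*N
        assert fit.pvalue > 0.01 or abs(fit.slope) < 0.01
        assert series[-1].mean_adult_load < 7 + 150 * 1

    def test_fractions_valid_every_generation(self):
        series = run_generations(ModelParams(), ARCH, SelectionRule(),
                                 pop_size=200, n_generations=10, seed=5)
        for s in series:
            assert 0.0 <= s.zygote_loss_fraction <= 1.0
            assert 0.0 <= s.postnatal_death_fraction <= 1.0

    def test_identical_seeds_identical_series(self):
        kw = dict(pop_size=200, n_generations=20)
        a = run_generations(ModelParams(), ARCH, SelectionRule(), seed=9, **kw)
        b = run_generations(ModelParams(), ARCH, SelectionRule(), seed=9, **kw)
        assert stats_to_frame(a).equals(stats_to_frame(b))

    def test_small_population_rejected(self):
        with pytest.raises(ParameterError):
            run_generations(ModelParams(), ARCH, SelectionRule(),
                            pop_size=10, n_generations=5, seed=0)

    def test_extinction_flagged_with_partial_stats(self):
        # every zygote carries >= lethal_threshold with overwhelming odds
        rule = SelectionRule(lethal_threshold=1)
        with pytest.raises(ExtinctionError) as err:
            run_generations(ModelParams(M=50, N=5), ARCH, rule,
                            pop_size=100, n_generations=5, seed=0)
        assert isinstance(err.value.partial_stats, list)


class TestEquilibriumSummary:
    def test_constant_series_returns_constants(self):
        from genload.meiosis_simulator import GenerationStats
        series = [GenerationStats(g, 7.0, 0.2, 0.1, 1000)
                  for g in range(120)]
        summary = equilibrium_summary(series)
        assert summary["M_eq"] == pytest.approx(7.0)
        assert summary["loss_eq"] == pytest.approx(0.2)
        assert summary["postnatal_eq"] == pytest.approx(0.1)
        assert summary["M_eq_se"] == pytest.approx(0.0)

    def test_short_series_rejected(self):
        from genload.meiosis_simulator import GenerationStats
        series = [GenerationStats(g, 7.0, 0.2, 0.1, 1000) for g in range(50)]
        with pytest.raises(ContractError):
            equilibrium_summary(series)

    def test_bounded_below_no_selection_drift(self):
        series = run_generations(ModelParams(), ARCH, SelectionRule(),
                                 pop_size=500, n_generations=120, seed=3)
        summary = equilibrium_summary(series)
        assert summary["M_eq"] < 7 + 1 * 120
        assert summary["loss_eq_se"] > 0
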