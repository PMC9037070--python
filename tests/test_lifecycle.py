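"""Viability, mate choice, reproduction and the generation engine."""

import numpy as np
import pytest

from littsim.genetics import Cohort, make_founder_brood
from littsim.landscape import MigrationKernel, build_landscape
from littsim.lifecycle import (SimParams, SimState, choice_probabilities,
                               fitness, generation_step, mate_deme_no_cost,
                               mate_deme_with_cost, psi_fnd, reproduce_pair,
                               run_replicate, survival_probability,
                               unmated_probability, viability_survival)

# preference values of the worked mate-choice example: one candidate at
# 1e-3 and nine at 1e-4, summing to S = 0.0019
EXAMPLE_PSI = np.array([1e-3] + [1e-4] * 9)


class TestFitness:
    def test_unity_at_optimum(self):
        assert fitness(0.5, 0.5, 0.45) == 1.0

    def test_weak_selection_closed_form(self):
        assert fitness(1.0, 0.0, 1.0) == pytest.approx(np.exp(-0.5))

    def test_strong_selection_closed_form(self):
        assert fitness(1.0, 0.0, 0.15) == pytest.approx(np.exp(-1 / 0.045))

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            fitness(0.5, 0.5, 0.0)


class TestViability:
    def test_equilibrium_probability_at_capacity(self):
        # w = 1, N = K, b = 50: V = 1/25 = 2/b, so a pair's 50 offspring
        # leave two expected survivors -- exact replacement
        assert survival_probability(1.0, 1000, 50, 1000) == pytest.approx(0.04)

    def test_density_free_limit(self):
        assert survival_probability(1.0, 1, 50, 1e12) == pytest.approx(1.0)

    def test_halving_fitness_doubles_odds(self):
        v1 = survival_probability(0.8, 500, 50, 1000)
        v2 = survival_probability(0.4, 500, 50, 1000)
        odds = lambda v: (1 - v) / v
        assert odds(v2) == pytest.approx(2 * odds(v1))

    def test_zero_fitness_is_lethal(self):
        assert survival_probability(0.0, 10, 50, 1000) == 0.0

    def test_prefactor_mode(self):
        v = survival_probability(0.5, 1000, 50, 1000, mode="prefactor")
        assert v == pytest.approx(0.5 / 25)

    def test_draws_match_probability(self, rng):
        hits = viability_survival(np.ones(20000), np.full(20000, 1000), 50,
                                  1000.0, rng)
        assert abs(hits.mean() - 0.04) < 3 * np.sqrt(0.04 * 0.96 / 20000)

    def test_rejects_empty_deme_count(self, rng):
        with pytest.raises(ValueError):
            viability_survival(1.0, 0, 50, 1000, rng)


class TestPsiFnd:
    def test_random_mater_always_one(self):
        for D in (0.0, 0.3, 1.0):
            assert psi_fnd(0.5, D, 0.05) == 1.0

    def test_preferred_partner_symmetry(self):
        # fully positive at D = 0 and fully negative at D = D_max both
        # accept with certainty
        assert psi_fnd(1.0, 0.0, 0.05) == 1.0
        assert psi_fnd(0.0, 1.0, 0.05) == 1.0

    def test_maximal_rejection_closed_form(self):
        assert psi_fnd(1.0, 1.0, 0.05) == pytest.approx(np.exp(-200.0))

    def test_negative_branch_closed_form(self):
        assert psi_fnd(0.0, 0.0, 0.05) == pytest.approx(np.exp(-200.0))

    def test_bounded_in_unit_interval(self):
        c = np.linspace(0, 1, 21)[:, None]
        D = np.linspace(0, 1, 21)[None, :]
        psi = psi_fnd(c, D, 0.1)
        assert np.all((psi >= 0) & (psi <= 1))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            psi_fnd(0.7, 1.5, 0.05)
        with pytest.raises(ValueError):
            psi_fnd(0.7, 0.5, 0.0)


class TestWorkedMatingExample:
    def test_no_cost_normalisation(self):
        p = choice_probabilities(EXAMPLE_PSI)
        assert EXAMPLE_PSI.sum() == pytest.approx(0.0019)
        assert p[0] == pytest.approx(1e-3 / 0.0019)
        assert round(p[0], 2) == 0.53
        assert p.sum() == pytest.approx(1.0)

    def test_with_cost_unmated_probability(self):
        q = unmated_probability(EXAMPLE_PSI)
        assert q == pytest.approx((1 - 1e-3) * (1 - 1e-4) ** 9)
        assert q > 0.998

    def test_underflow_falls_back_to_uniform(self):
        p = choice_probabilities(np.zeros(10))
        np.testing.assert_allclose(p, 0.1)


class TestMateChoiceNoCost:
    def test_every_male_mates_once(self, rng):
        x_m, c_m = rng.random(20), rng.random(20)
        x_f = rng.random(7)
        mi, fi = mate_deme_no_cost(x_m, c_m, x_f, 0.1, 10, rng)
        assert len(mi) == 20 and sorted(mi) == list(range(20))
        assert fi.max() < 7

    def test_random_mater_chooses_uniformly(self):
        rng = np.random.default_rng(3)
        counts = np.zeros(5)
        for _ in range(2000):
            _, fi = mate_deme_no_cost([0.5], [0.5], np.linspace(0, 1, 5),
                                      0.05, 10, rng)
            counts[fi[0]] += 1
        p = counts / counts.sum()
        assert np.all(np.abs(p - 0.2) < 3 * np.sqrt(0.2 * 0.8 / 2000))

    def test_choosy_male_prefers_similar(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(1000):
            # fully choosy male at x = 0: candidates at 0 and 1
            _, fi = mate_deme_no_cost([0.0], [1.0], np.array([0.0, 1.0]),
                                      0.05, 10, rng)
            hits += fi[0] == 0
        assert hits > 990

    def test_empirical_example_frequencies(self):
        # engineered deme reproducing the worked example: selection of the
        # close candidate ~ 0.53
        rng = np.random.default_rng(5)
        sigma_a = 0.1
        c_male, x_male = 1.0, 0.0
        # distances giving psi = 1e-3 and 1e-4 at C = 1, sigma_a = 0.1
        d1 = np.sqrt(-2 * sigma_a**2 * np.log(1e-3))
        d2 = np.sqrt(-2 * sigma_a**2 * np.log(1e-4))
        x_f = np.array([d1] + [d2] * 9)
        wins = 0
        n = 3000
        for _ in range(n):
            _, fi = mate_deme_no_cost([x_male], [c_male], x_f, sigma_a, 10, rng)
            wins += fi[0] == 0
        p = 1e-3 / 0.0019
        assert abs(wins / n - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestMateChoiceWithCost:
    def test_certain_acceptance_always_mates(self, rng):
        mi, fi = mate_deme_with_cost(np.full(50, 0.5), np.full(50, 0.5),
                                     np.full(10, 0.5), 0.1, 10, rng)
        assert len(mi) == 50

    def test_zero_psi_never_mates(self, rng):
        # fully choosy males at distance 1 from every candidate: psi ~ 1e-87
        mi, _ = mate_deme_with_cost(np.zeros(50), np.ones(50), np.ones(10),
                                    0.05, 10, rng)
        assert len(mi) == 0

    def test_unmated_fraction_matches_example(self):
        # the worked example: P(no mating) = (1-1e-3)(1-1e-4)^9 ~ 0.9981
        rng = np.random.default_rng(6)
        sigma_a = 0.1
        d1 = np.sqrt(-2 * sigma_a**2 * np.log(1e-3))
        d2 = np.sqrt(-2 * sigma_a**2 * np.log(1e-4))
        x_f = np.array([d1] + [d2] * 9)
        n = 4000
        unmated = 0
        for _ in range(n):
            mi, _ = mate_deme_with_cost([0.0], [1.0], x_f, sigma_a, 10, rng)
            unmated += len(mi) == 0
        q = (1 - 1e-3) * (1 - 1e-4) ** 9
        assert abs(unmated / n - q) < 4 * np.sqrt(q * (1 - q) / n)

    def test_success_non_increasing_in_choosiness(self):
        # fixed partner distribution: choosier males mate no more often
        rng = np.random.default_rng(7)
        x_f = np.linspace(0, 1, 10)
        rates = []
        for c in (0.5, 0.7, 0.9, 1.0):
            mi, _ = mate_deme_with_cost(np.full(2000, 0.0), np.full(2000, c),
                                        x_f, 0.1, 10, rng)
            rates.append(len(mi) / 2000)
        assert all(a >= b - 0.03 for a, b in zip(rates, rates[1:]))


class TestReproduction:
    def _parts(self, eco_val, L=4):
        eco = np.full((L, 2), eco_val, np.uint8)
        mate = np.zeros((L, 2), np.uint8)
        msat = np.full((8, 2), 100, np.int32)
        return eco, mate, msat

    def test_poisson_brood_size(self):
        rng = np.random.default_rng(8)
        sizes = [reproduce_pair(self._parts(1), self._parts(0), 50, rng).n
                 for _ in range(2000)]
        mean = np.mean(sizes)
        assert abs(mean - 50) < 3 * np.sqrt(50 / 2000)
        assert abs(np.var(sizes) - 50) < 0.15 * 50

    def test_zero_mean_no_offspring(self, rng):
        assert reproduce_pair(self._parts(1), self._parts(0), 0.0, rng).n == 0

    def test_mendelian_certainty_for_opposite_homozygotes(self, rng):
        brood = reproduce_pair(self._parts(1), self._parts(0), 50, rng)
        # every offspring heterozygous at every ecological locus: x = 0.5
        np.testing.assert_allclose(brood.x, 0.5)
        assert (brood.eco.sum(axis=2) == 1).all()


class TestGenerationEngine:
    def _single_deme_params(self, K=2000, **kw):
        kw.setdefault("sigma_s", 1000.0)  # effectively neutral
        kw.setdefault("kernel", MigrationKernel(1.0, 0.0, 0.0))
        kw.setdefault("scale", K / 3750.0)
        return SimParams(T=0, L=4, **kw)

    def test_beverton_holt_census_equilibrium(self):
        # neutral single-deme dynamics settle at juvenile census ~ K
        K = 2000
        params = self._single_deme_params(K=K)
        lsc = build_landscape("galician", scale=params.scale)
        final_census = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            state = SimState(make_founder_brood(50, 4, rng))
            track = []
            for _ in range(200):
                state = generation_step(state, params, lsc, rng)
                track.append(state.cohort.n)
            final_census.append(np.mean(track[-100:]))
        assert abs(np.mean(final_census) - K) / K < 0.05

    def test_neutral_drift_preserves_expected_frequency(self):
        # mu = mu0 = 0, no selection, one deme: allele frequencies drift
        # but their expectation stays at the starting value
        import numpy as np
        from littsim.genetics import Cohort
        params = SimParams(T=0, L=4, mu=0.0, mu0=0.0, sigma_s=1000.0,
                           scale=2000 / 3750.0, kernel=MigrationKernel(1, 0, 0))
        lsc = build_landscape("galician", scale=params.scale)
        p0 = 0.3
        n0 = 1000
        freqs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            eco = (rng.random((n0, 4, 2)) < p0).astype(np.uint8)
            mate = np.zeros((n0, 4, 2), np.uint8)
            mate[:, :2] = 1
            msat = np.full((n0, 8, 2), 100, np.int32)
            cohort = Cohort(eco, mate, msat, rng.integers(0, 2, n0),
                            np.zeros(n0, np.int32))
            state = SimState(cohort)
            for _ in range(10):
                state = generation_step(state, params, lsc, rng)
            freqs.append(state.cohort.eco.mean())
        se = np.std(freqs, ddof=1) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - p0) < 4 * se + 0.01

    def test_no_females_leads_to_extinction(self, rng):
        brood = make_founder_brood(20, 4, rng)
        brood.sex[:] = 0  # all male
        params = self._single_deme_params()
        lsc = build_landscape("galician", scale=params.scale)
        state = generation_step(SimState(brood), params, lsc, rng)
        assert state.extinct and state.cohort.n == 0

    def test_offspring_stay_within_kernel_support(self, rng):
        # founder brood in deme 0 with the default kernel: offspring can
        # only be born in demes 0-2
        params = SimParams(T=0, L=4, sigma_s=1000.0, scale=0.1)
        lsc = build_landscape("galician", scale=0.1)
        state = generation_step(SimState(make_founder_brood(50, 4, rng)),
                                params, lsc, rng)
        assert state.cohort.n > 0
        assert set(np.unique(state.cohort.deme)) <= {0, 1, 2}

    def test_neutral_middle_fitness_is_one(self):
        params = SimParams(T=0, middle_selective=False)
        lsc = params.make_landscape()
        assert not lsc.selective[20:22].any()


class TestRunReplicate:
    def test_zero_generations_founder_summary(self):
        res = run_replicate(SimParams(T=0, seed=1))
        up = res.summary.habitats["upper_sheltered"]
        assert up.mean_x == 1.0
        assert up.mean_c == 0.5
        assert up.census == 50
        assert not res.summary.extinct

    def test_same_seed_bit_identical(self):
        p = SimParams(T=120, scale=0.05, thin=40, seed=42, middle_selective=False)
        r1, r2 = run_replicate(p), run_replicate(p)
        assert r1.series.equals(r2.series)
        assert r1.summary.to_dict() == r2.summary.to_dict()

    def test_different_seed_differs(self):
        p1 = SimParams(T=120, scale=0.05, thin=40, seed=1)
        p2 = SimParams(T=120, scale=0.05, thin=40, seed=2)
        assert not run_replicate(p1).series.equals(run_replicate(p2).series)

    def test_series_has_final_generation(self):
        p = SimParams(T=130, scale=0.05, thin=50, seed=3)
        res = run_replicate(p)
        assert res.series["generation"].iloc[-1] == 130
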