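"""Mating-market model: Gini machinery, matching equilibria, reproduction."""

import numpy as np
import pytest
from scipy.stats import norm

from repskew import (
    MatingMarketConfig,
    ValidationError,
    female_fitness,
    gini,
    match_ideal_free,
    match_imposed_monogamy,
    polygyny_metrics,
    sample_resources,
    simulate_reproduction,
    sweep,
)
from repskew.mating import (
    enumerate_stable_assignments,
    is_bilaterally_stable,
    lognormal_sigma_for_gini,
    male_accepts,
)
from repskew.skew import compute_M_values


class TestGini:
    def test_equal_vector_is_zero(self):
        assert gini([5, 5, 5, 5]) == pytest.approx(0.0)

    def test_two_point_population_formula(self):
        assert gini([0, 1]) == pytest.approx(0.5)

    def test_scale_invariance(self, rng):
        x = rng.uniform(1, 9, size=100)
        assert gini(x) == pytest.approx(gini(17.3 * x))

    def test_matches_brute_force_pairwise_sum(self, rng):
        x = rng.lognormal(0, 1, size=200)
        brute = np.abs(x[:, None] - x[None, :]).sum() / (2 * x.size**2 * x.mean())
        assert gini(x) == pytest.approx(brute)

    def test_lognormal_closed_form(self, rng):
        # for sigma = 1 the population Gini is 2*Phi(1/sqrt(2)) - 1 ~ 0.5205
        x = rng.lognormal(0.0, 1.0, size=400_000)
        assert gini(x) == pytest.approx(2 * norm.cdf(1 / np.sqrt(2)) - 1, abs=0.01)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            gini([0.0, 0.0])


class TestSampleResources:
    def test_target_zero_gives_constant_vector(self):
        x = sample_resources(100, 0.0, 1)
        assert np.allclose(x, 1.0)

    @pytest.mark.parametrize("target", [0.12, 0.5])
    def test_realized_gini_hits_target(self, target):
        x = sample_resources(100_000, target, 2)
        assert gini(x) == pytest.approx(target, abs=0.01)
        assert x.mean() == pytest.approx(1.0)

    def test_sigma_inversion_roundtrip(self):
        sigma = lognormal_sigma_for_gini(0.64)
        assert 2 * norm.cdf(sigma / np.sqrt(2)) - 1 == pytest.approx(0.64)

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ValidationError):
            sample_resources(10, 0.99)


class TestFemaleFitness:
    def test_pure_rival_limit(self):
        assert female_fitness(6.0, 3, 2.0, mu=1.0) == pytest.approx(2.0)

    def test_pure_nonrival_limit(self):
        # with mu = 0 fitness ignores cowife number entirely
        assert female_fitness(6.0, 1, 2.0, mu=0.0) == female_fitness(6.0, 5, 2.0, mu=0.0) == 2.0

    def test_cobb_douglas_arithmetic(self):
        assert female_fitness(4.0, 1, 1.0, mu=0.5) == pytest.approx(2.0)

    def test_zero_wives_rejected(self):
        with pytest.raises(ValidationError):
            female_fitness(4.0, 0, 1.0, mu=0.5)


class TestMaleDemand:
    def test_costless_male_always_accepts(self):
        assert male_accepts(1.0, 1.0, 5, mu=0.5, cost=0.0)

    def test_first_wife_always_welcome(self):
        assert male_accepts(1.0, 1.0, 0, mu=0.95, cost=0.5)

    def test_entry_cost_blocks_polygyny_when_rival_resources_vital(self):
        # second wife adds 2^(1-mu)-1 recruitment; at high mu that is below
        # the entry cost for every male, rich or poor
        assert not male_accepts(50.0, 1.0, 1, mu=0.9, cost=0.23)
        assert male_accepts(1.0, 1.0, 1, mu=0.3, cost=0.23)

    def test_entry_threshold_independent_of_resources(self):
        for R in (0.1, 1.0, 100.0):
            assert bool(male_accepts(R, 1.0, 1, mu=0.8, cost=0.23)) is False
            assert bool(male_accepts(R, 1.0, 1, mu=0.5, cost=0.23)) is True


def random_market(rng, n_m=None, n_f=None):
    n_m = n_m or int(rng.integers(2, 6))
    n_f = n_f or int(rng.integers(2, 6))
    cfg = MatingMarketConfig(
        n_males=n_m, n_females=n_f,
        gini_R=float(rng.uniform(0.05, 0.7)), gini_G=0.12,
        mu=float(rng.uniform(0.1, 0.95)),
        male_cost=float(rng.choice([0.0, 0.05, 0.2])),
        seed=int(rng.integers(2**31)),
    )
    R = sample_resources(n_m, cfg.gini_R, rng)
    G = sample_resources(n_m, cfg.gini_G, rng)
    return cfg, R, G


class TestIdealFreeMatching:
    def test_two_by_two_market_agrees_with_enumeration(self):
        cfg = MatingMarketConfig(n_males=2, n_females=2, mu=0.15, male_cost=0.0)
        R = np.array([9.0, 1.0])
        G = np.array([1.0, 1.0])
        state = match_ideal_free(cfg, R, G, 0)
        stable = enumerate_stable_assignments(R, G, cfg.mu, cfg.male_cost, 2)
        assert state.converged
        assert any(np.array_equal(state.husband, s) for s in stable)

    def test_nonrival_only_world_collapses_onto_best_male(self):
        # mu = 0: rival division is costless, so every female prefers max G
        cfg = MatingMarketConfig(n_males=4, n_females=4, mu=0.0, male_cost=0.0)
        R = np.ones(4)
        G = np.array([1.0, 3.0, 2.0, 0.5])
        state = match_ideal_free(cfg, R, G, 1)
        assert (state.husband == 1).all()
        stable = enumerate_stable_assignments(R, G, 0.0, 0.0, 4)
        assert all((s == 1).all() for s in stable)

    def test_wrong_rule_rejected(self):
        cfg = MatingMarketConfig(mating_rule="imposed_monogamy", n_males=4)
        with pytest.raises(ValidationError, match="ideal_free"):
            match_ideal_free(cfg, np.ones(4), np.ones(4))
        cfg2 = MatingMarketConfig(mating_rule="ideal_free", n_males=4)
        with pytest.raises(ValidationError, match="imposed_monogamy"):
            match_imposed_monogamy(cfg2, np.ones(4), np.ones(4))

    def test_random_small_markets_agree_with_brute_force(self, rng):
        # full-scale version of this oracle runs in the acceptance suite
        n_checked = 0
        for _ in range(120):
            cfg, R, G = random_market(rng)
            state = match_ideal_free(cfg, R, G, rng)
            if not state.converged:
                continue
            assert is_bilaterally_stable(state)
            stable = enumerate_stable_assignments(R, G, cfg.mu, cfg.male_cost, cfg.n_f)
            assert any(np.array_equal(state.husband, s) for s in stable)
            n_checked += 1
        assert n_checked >= 100

    def test_nash_certificate_on_medium_market(self, rng):
        cfg = MatingMarketConfig(n_males=100, gini_R=0.5, mu=0.25, seed=5)
        R = sample_resources(100, cfg.gini_R, rng)
        G = sample_resources(100, cfg.gini_G, rng)
        state = match_ideal_free(cfg, R, G, rng)
        assert state.converged
        assert is_bilaterally_stable(state)


class TestImposedMonogamy:
    def test_no_polygyny_anywhere(self, rng):
        cfg = MatingMarketConfig(n_males=50, gini_R=0.6, mu=0.2,
                                 mating_rule="imposed_monogamy")
        R = sample_resources(50, 0.6, rng)
        G = sample_resources(50, 0.12, rng)
        state = match_imposed_monogamy(cfg, R, G, rng)
        assert polygyny_metrics(state) == (0.0, 0.0)
        assert (state.wife_count == 1).all()  # pigeonhole with equal numbers
        assert np.allclose(state.per_wife_share, R)

    def test_single_pair_market(self):
        cfg = MatingMarketConfig(n_males=1, n_females=1, mating_rule="imposed_monogamy")
        state = match_imposed_monogamy(cfg, np.array([2.0]), np.array([1.0]))
        assert state.husband.tolist() == [0]


class TestPolygynyMetrics:
    def _state(self, husband, n_m):
        from repskew.mating import MatchingState

        husband = np.asarray(husband)
        k = np.bincount(husband[husband >= 0], minlength=n_m)
        return MatchingState(husband, k, np.ones(n_m), np.ones(n_m), 0.5, 0.0, "ideal_free")

    def test_all_monogamous(self):
        assert polygyny_metrics(self._state([0, 1, 2], 3)) == (0.0, 0.0)

    def test_mixed_market_arithmetic(self):
        # wife counts (2, 1, 0): 1 of 2 married men polygynous, 2 of 3 women with cowives
        pm, pw = polygyny_metrics(self._state([0, 0, 1], 3))
        assert pm == pytest.approx(50.0)
        assert pw == pytest.approx(200 / 3)

    def test_single_harem(self):
        assert polygyny_metrics(self._state([0, 0, 0], 3)) == (100.0, 100.0)

    def test_empty_matching_rejected(self):
        with pytest.raises(ValidationError):
            polygyny_metrics(self._state([-1, -1], 2))


class TestReproduction:
    def test_offspring_conservation_and_fertility_scale(self, rng):
        cfg = MatingMarketConfig(n_males=2000, gini_R=0.5, mu=0.3, fertility_scale=2.0)
        R = sample_resources(2000, 0.5, rng)
        G = sample_resources(2000, 0.12, rng)
        state = match_ideal_free(cfg, R, G, rng)
        recs = simulate_reproduction(state, cfg, rng)
        by_sex = recs.groupby("sex")["rs"].sum()
        assert by_sex["male"] == by_sex["female"]
        matched = state.husband >= 0
        mean_f = recs[recs["sex"] == "female"]["rs"].to_numpy()[matched].mean()
        assert mean_f == pytest.approx(2.0, abs=0.15)

    def test_monogamous_equal_market_is_null_consistent(self, rng):
        # equal resources, imposed monogamy: only Poisson noise remains
        cfg = MatingMarketConfig(n_males=300, gini_R=0.0, gini_G=0.0, mu=0.5,
                                 mating_rule="imposed_monogamy")
        Ms = []
        for seed in range(40):
            state = match_imposed_monogamy(cfg, np.ones(300), np.ones(300), seed)
            recs = simulate_reproduction(state, cfg, np.random.default_rng(seed + 1000))
            rs = recs[recs["sex"] == "female"]["rs"].to_numpy()
            Ms.append(compute_M_values(rs, None, method="analytic"))
        Ms = np.asarray(Ms)
        assert abs(Ms.mean()) < 3 * Ms.std() / np.sqrt(Ms.size)

    def test_single_harem_gives_strong_male_skew(self, rng):
        from repskew.mating import MatchingState

        n = 30
        husband = np.zeros(n, dtype=int)
        k = np.bincount(husband, minlength=n)
        state = MatchingState(husband, k, np.ones(n), np.ones(n), 0.5, 0.0, "ideal_free")
        cfg = MatingMarketConfig(n_males=n, fertility_scale=2.0)
        recs = simulate_reproduction(state, cfg, rng)
        rs_m = recs[recs["sex"] == "male"]["rs"].to_numpy()
        assert compute_M_values(rs_m, None, method="analytic") > 5

    def test_expected_mode_is_deterministic(self, rng):
        cfg = MatingMarketConfig(n_males=50, gini_R=0.4, mu=0.3, offspring_mode="expected")
        R = sample_resources(50, 0.4, rng)
        G = sample_resources(50, 0.12, rng)
        state = match_ideal_free(cfg, R, G, rng)
        a = simulate_reproduction(state, cfg, 1)
        b = simulate_reproduction(state, cfg, 2)
        assert np.allclose(a["rs"], b["rs"])


class TestSweep:
    def test_tiny_sweep_structure(self):
        cfg = MatingMarketConfig(n_males=60, replicates=3, seed=9)
        table = sweep([0.2, 0.6], [0.2, 0.8], config=cfg)
        assert len(table) == 8  # 2 x 2 x 2 rules
        mono = table[table["mating_rule"] == "imposed_monogamy"]
        assert (mono["pct_polygynous_men"] == 0).all()
        assert (mono["pct_women_with_cowives"] == 0).all()
        free = table[table["mating_rule"] == "ideal_free"].set_index(["gini_R", "mu"])
        # polygyny grows with rival inequality when rival importance is low
        assert (free.loc[(0.6, 0.2), "pct_polygynous_men"]
                > free.loc[(0.2, 0.2), "pct_polygynous_men"])
        assert table["n_converged"].ge(1).all()

    def test_sweep_deterministic_given_seed(self):
        cfg = MatingMarketConfig(n_males=40, replicates=2, seed=3)
        a = sweep([0.3], [0.5], rules=("ideal_free",), config=cfg)
        b = sweep([0.3], [0.5], rules=("ideal_free",), config=cfg)
        assert a.equals(b)
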