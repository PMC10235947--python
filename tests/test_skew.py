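"""The multinomial index: examples, null calibration, invariance properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repskew import (
    NullModelSpec,
    PublishedSkewStat,
    SkewUndefinedError,
    ValidationError,
    bootstrap_M,
    compute_M,
    convert_published,
    expected_null_I,
    opportunity_for_selection,
    sex_difference,
    signed_sqrt,
    skew_table,
)
from repskew.skew import GroupSkewEstimate, compute_M_values, simulate_null_I
from .conftest import make_records


class TestOpportunityForSelection:
    def test_no_variance_gives_zero(self):
        assert opportunity_for_selection([2, 2, 2, 2]) == 0.0

    def test_two_individuals_arithmetic(self):
        # mean 2, population variance 4 -> I = 1
        assert opportunity_for_selection([4, 0]) == pytest.approx(1.0)

    def test_all_zero_is_undefined(self):
        with pytest.raises(SkewUndefinedError):
            opportunity_for_selection([0, 0, 0])

    def test_single_individual_rejected(self):
        with pytest.raises(ValidationError):
            opportunity_for_selection([3])


class TestNullExpectation:
    def test_equal_share_closed_form_matches_simulation(self, rng):
        # independent Monte Carlo oracle for Multinomial(30, uniform over 6)
        draws = rng.multinomial(30, np.full(6, 1 / 6), size=100_000).astype(float)
        I_sim = (draws.var(axis=1) / draws.mean(axis=1) ** 2).mean()
        assert expected_null_I(6, 30) == pytest.approx(5 / 30)
        assert I_sim == pytest.approx(5 / 30, abs=3 * 0.08 / np.sqrt(100_000))

    def test_unequal_exposure_closed_form_matches_simulation(self, rng):
        q = np.array([0.5, 0.2, 0.2, 0.1])
        I_sim = simulate_null_I(4, 40, q, 200_000, rng).mean()
        assert expected_null_I(4, 40, q) == pytest.approx(I_sim, rel=0.01)


class TestComputeM:
    def test_equal_counts_give_negative_M_of_null_magnitude(self):
        # I_obs = 0, so M = -(n/(n-1)) E_null[I] = -n/K = -0.2 for n=6, K=30;
        # E_null[I] = 1/6 is verified against brute-force simulation above
        est = compute_M(np.array([5, 5, 5, 5, 5, 5]), NullModelSpec(replicates=20_000, seed=1))
        assert est.M == pytest.approx(-6 / 30, abs=0.01)
        est_exact = compute_M(np.array([5, 5, 5, 5, 5, 5]), method="analytic")
        assert est_exact.M == pytest.approx(-6 / 30, abs=1e-12)

    def test_total_concentration_is_positive(self):
        rs = np.zeros(20, dtype=int)
        rs[0] = 100
        assert compute_M(rs, NullModelSpec(seed=2)).M > 0

    def test_null_generated_groups_average_to_zero(self, rng):
        Ms = []
        for _ in range(300):
            rs = rng.multinomial(100, np.full(50, 1 / 50))
            Ms.append(compute_M_values(rs, None, method="analytic"))
        Ms = np.asarray(Ms)
        assert abs(Ms.mean()) < 3 * Ms.std() / np.sqrt(Ms.size)

    def test_mc_and_analytic_agree(self, rng):
        rs = rng.poisson(3.0, size=40)
        exposure = rng.uniform(0.5, 2.0, size=40)
        m_mc = compute_M_values(rs, exposure, NullModelSpec(replicates=50_000, seed=3))
        m_an = compute_M_values(rs, exposure, method="analytic")
        assert m_mc == pytest.approx(m_an, abs=0.01)

    def test_no_offspring_is_undefined_not_invalid(self):
        with pytest.raises(SkewUndefinedError):
            compute_M(np.zeros(5, dtype=int))

    def test_fewer_than_two_individuals_rejected(self):
        with pytest.raises(ValidationError):
            compute_M(np.array([3]))

    def test_estimate_records_provenance(self, tiny_records):
        males = tiny_records[tiny_records["sex"] == "male"]
        est = compute_M(males, NullModelSpec(replicates=500, seed=9))
        assert (est.group_id, est.sex, est.n, est.K) == ("g1", "male", 2, 3)
        assert est.null_reps == 500 and est.seed == 9


class TestInvarianceProperties:
    """The index's headline claims: no bias from mean rate, sample size, or exposure."""

    @staticmethod
    def _mean_M(rng, n_groups, n, mean_rs, shape):
        out = np.empty(n_groups)
        for i in range(n_groups):
            rates = rng.gamma(shape, mean_rs / shape, size=n)
            rs = rng.poisson(rates)
            if rs.sum() < 1:
                rs[0] = 1
            out[i] = compute_M_values(rs, None, method="analytic")
        return out

    def test_mean_rate_invariance(self, rng):
        a = self._mean_M(rng, 150, 50, 2.0, 1.0)
        b = self._mean_M(rng, 150, 50, 4.0, 1.0)
        se = np.sqrt(a.var() / a.size + b.var() / b.size)
        assert abs(a.mean() - b.mean()) < 3 * se

    def test_sample_size_invariance(self, rng):
        from scipy.stats import linregress

        ns, Ms = [], []
        for n in (10, 25, 50, 100, 200):
            vals = self._mean_M(rng, 80, n, 2.0, 1.0)
            ns.extend([n] * vals.size)
            Ms.extend(vals)
        fit = linregress(ns, Ms)
        assert abs(fit.slope) < 3 * fit.stderr

    def test_exposure_adjustment(self, rng):
        # offspring exactly proportional to exposure: no skew beyond exposure
        exposure = rng.uniform(1.0, 10.0, size=40)
        rs = np.round(3 * exposure).astype(int)
        m_adj = compute_M_values(rs, exposure, method="analytic")
        m_ignored = compute_M_values(rs, None, method="analytic")
        assert m_adj <= 0
        assert m_ignored > m_adj

    def test_null_with_heterogeneous_exposure_calibrated(self, rng):
        Ms = []
        for _ in range(200):
            exposure = rng.uniform(1.0, 10.0, size=50)
            q = exposure / exposure.sum()
            rs = rng.multinomial(150, q)
            Ms.append(compute_M_values(rs, exposure, method="analytic"))
        Ms = np.asarray(Ms)
        assert abs(Ms.mean()) < 3 * Ms.std() / np.sqrt(Ms.size)


class TestSignedSqrt:
    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (0.25, 0.5), (-4.0, -2.0),
                                            (1.0, 1.0), (-1.0, -1.0)])
    def test_examples(self, x, expected):
        assert signed_sqrt(x) == pytest.approx(expected)

    @given(st.floats(-1e6, 1e6, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_odd(self, x):
        assert signed_sqrt(-x) == pytest.approx(-signed_sqrt(x), abs=1e-12)

    @given(st.floats(-1e6, 1e6), st.floats(-1e6, 1e6))
    @settings(max_examples=200, deadline=None)
    def test_monotone(self, a, b):
        lo, hi = sorted([a, b])
        assert signed_sqrt(lo) <= signed_sqrt(hi)


class TestConvertPublished:
    def test_variance_and_cv_map_to_I(self):
        # variance 4 at mean 2 -> I = 1; cv 0.5 -> I = 0.25
        v = convert_published(PublishedSkewStat("g", "male", "variance", 4.0, 30, 2.0))
        assert v.M == pytest.approx(30 / 29 * (1.0 - expected_null_I(30, 60)))
        c = convert_published(PublishedSkewStat("g", "male", "cv", 0.5, 30, 2.0))
        assert c.M == pytest.approx(30 / 29 * (0.25 - expected_null_I(30, 60)))
        assert v.source == c.source == "converted"

    def test_self_consistency_with_direct_computation(self, rng):
        rs = rng.poisson(rng.gamma(1.0, 2.0, size=80))
        direct = compute_M_values(rs, None, method="analytic")
        stat = PublishedSkewStat("g", "male", "variance", float(rs.var()),
                                 rs.size, float(rs.mean()))
        via_summary = convert_published(stat).M
        assert via_summary == pytest.approx(direct, abs=0.02)

    def test_mc_standardization_agrees_with_analytic(self):
        stat = PublishedSkewStat("g", "male", "opportunity_I", 0.8, 40, 2.5)
        an = convert_published(stat, method="analytic").M
        mc = convert_published(stat, NullModelSpec(replicates=50_000, seed=5), method="mc").M
        assert mc == pytest.approx(an, abs=0.01)

    def test_nonacs_B_relation(self, rng):
        # B is the observed-minus-expected variance of reproductive shares;
        # computed from first principles it must invert to M = n^2 * B.
        rs = rng.poisson(rng.gamma(0.8, 3.0, size=60)).astype(float)
        n, K = rs.size, rs.sum()
        p = rs / K
        B = p.var() - (1 / K) * (1 / n) * (1 - 1 / n)
        est = convert_published(PublishedSkewStat("g", "male", "nonacs_B", float(B), n))
        direct = compute_M_values(rs, None, method="analytic")
        assert est.M == pytest.approx(direct, abs=1e-9)

    def test_M_passes_through(self):
        est = convert_published(PublishedSkewStat("g", "female", "M", 0.42, 25))
        assert est.M == 0.42

    def test_missing_mean_rs_rejected(self):
        with pytest.raises(ValidationError, match="mean_rs"):
            convert_published(PublishedSkewStat("g", "male", "variance", 4.0, 30))


class TestBootstrap:
    def test_identical_individuals_degenerate(self):
        se, lo, hi = bootstrap_M(np.full(20, 3), reps=200, seed=1)
        assert se == pytest.approx(0.0, abs=1e-12)
        assert lo == pytest.approx(hi, abs=1e-12)

    def test_se_stable_under_doubled_reps(self, rng):
        rs = rng.poisson(2.0, size=60)
        se1, *_ = bootstrap_M(rs, reps=2000, seed=2)
        se2, *_ = bootstrap_M(rs, reps=4000, seed=3)
        assert se1 == pytest.approx(se2, rel=0.15)

    def test_interval_covers_zero_for_null_data(self, rng):
        hits = 0
        n_groups = 120
        for _ in range(n_groups):
            rs = rng.multinomial(120, np.full(40, 1 / 40))
            _, lo, hi = bootstrap_M(rs, reps=400, seed=int(rng.integers(2**31)))
            hits += lo <= 0.0 <= hi
        # percentile bootstrap is approximate; allow a generous band around 89%
        assert 0.78 <= hits / n_groups <= 0.98

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValidationError):
            bootstrap_M(np.array([3]), reps=200)


class TestSexDifference:
    def _est(self, gid, sex, M):
        return GroupSkewEstimate(group_id=gid, sex=sex, M=M, n=10, K=20)

    def test_equal_skew_gives_zero(self):
        m = self._est("g", "male", 0.16)
        f = self._est("g", "female", 0.16)
        assert sex_difference(m, f) == 0.0

    def test_difference_on_transformed_scale(self):
        m = self._est("g", "male", 0.25)   # M* = 0.5
        f = self._est("g", "female", 0.04)  # M* = 0.2
        assert sex_difference(m, f) == pytest.approx(0.3)

    def test_antisymmetry(self):
        m = self._est("g", "male", 0.3)
        f = self._est("g", "female", 0.1)
        d = sex_difference(m, f)
        m2 = self._est("g", "male", 0.1)
        f2 = self._est("g", "female", 0.3)
        assert sex_difference(m2, f2) == pytest.approx(-d)

    def test_group_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="mismatch"):
            sex_difference(self._est("g1", "male", 0.1), self._est("g2", "female", 0.1))


class TestSkewTable:
    def test_groups_with_no_offspring_are_excluded(self, caplog):
        df = make_records([
            ("a", "g1", "male", 2, 1.0), ("b", "g1", "male", 0, 1.0),
            ("c", "g2", "male", 0, 1.0), ("d", "g2", "male", 0, 1.0),
        ])
        table = skew_table(df, NullModelSpec(replicates=200, seed=1))
        assert list(table["group_id"]) == ["g1"]

    def test_mstar_column_consistent(self, tiny_records, rng):
        df = make_records([
            ("a", "g1", "male", 4, 1.0), ("b", "g1", "male", 1, 1.0),
            ("c", "g1", "female", 2, 1.0), ("d", "g1", "female", 2, 1.0),
        ])
        table = skew_table(df, NullModelSpec(replicates=500, seed=2), bootstrap_reps=200)
        assert np.allclose(table["M_star"], np.sign(table["M"]) * np.sqrt(np.abs(table["M"])))
        assert (table.loc[table["se"].notna(), "ci_low"]
                <= table.loc[table["se"].notna(), "ci_high"]).all()
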