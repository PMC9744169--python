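import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridkit import quantgen, simdata
from hybridkit.errors import AnalysisError, InputError


class TestKSNormality:
    def test_perfect_normal_quantiles_high_p(self):
        x = stats.norm.ppf(np.linspace(0.005, 0.995, 100))
        _, p = quantgen.ks_normality(x)
        assert p > 0.9

    def test_exponential_rejected_by_lilliefors(self):
        rng = np.random.default_rng(1)
        x = rng.exponential(size=200)
        _, p = quantgen.ks_normality(x, variant="lilliefors")
        assert p < 0.05

    def test_constant_vector_is_error(self):
        with pytest.raises(InputError, match="standard deviation"):
            quantgen.ks_normality(np.ones(20))

    def test_too_few_values(self):
        with pytest.raises(InputError, match=">= 8"):
            quantgen.ks_normality([1.0, 2.0, 3.0])

    def test_unknown_variant(self):
        with pytest.raises(InputError):
            quantgen.ks_normality(np.arange(20.0), variant="bogus")


class TestMoments:
    def test_symmetric_sample_zero_skew(self):
        _, _, skew, _ = quantgen.moments([-2, -1, 0, 1, 2])
        assert skew == 0.0

    def test_right_skew_sign(self):
        _, _, skew, _ = quantgen.moments([0, 0, 0, 1])
        assert skew > 0

    def test_standard_normal_sample_near_zero(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(5000)
        _, _, skew, kurt = quantgen.moments(x)
        assert abs(skew) < 0.1
        assert abs(kurt) < 0.2

    def test_negation_flips_skew_keeps_kurtosis(self):
        rng = np.random.default_rng(3)
        x = rng.exponential(size=100)
        _, _, s1, k1 = quantgen.moments(x)
        _, _, s2, k2 = quantgen.moments(-x)
        assert s1 == pytest.approx(-s2)
        assert k1 == pytest.approx(k2)

    def test_zero_variance_error(self):
        with pytest.raises(InputError, match="variance"):
            quantgen.moments([5.0, 5.0, 5.0])


class TestCV:
    def test_constant_values(self):
        assert quantgen.cv([3.0, 3.0, 3.0]) == 0.0

    def test_hand_computed(self):
        # mean 15, sample SD sqrt(50) = 7.0711
        assert quantgen.cv([10.0, 20.0]) == pytest.approx(0.47140, abs=1e-4)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(1, 5, 50)
        assert quantgen.cv(x) == pytest.approx(quantgen.cv(7.3 * x))

    def test_zero_mean_error(self):
        with pytest.raises(InputError, match="mean"):
            quantgen.cv([-1.0, 1.0])


class TestCorrelationMatrix:
    def test_self_correlation(self):
        rng = np.random.default_rng(5)
        t = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})
        long = quantgen.correlation_matrix(t)
        row = long[(long.trait_a == "a") & (long.trait_b == "a")].iloc[0]
        assert row.r == 1.0 and row.tier == "***"

    def test_antilinear_pair(self):
        t = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [5.0, 4, 3, 2, 1]})
        long = quantgen.correlation_matrix(t)
        row = long[(long.trait_a == "a") & (long.trait_b == "b")].iloc[0]
        assert row.r == pytest.approx(-1.0)

    def test_known_correlation_recovered(self):
        # Fisher-z 99% interval for rho=0.9, n=30 is about [0.75, 0.97]
        rng = np.random.default_rng(6)
        x = rng.standard_normal(30)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.standard_normal(30)
        t = pd.DataFrame({"a": x, "b": y})
        row = quantgen.correlation_matrix(t).query("trait_a=='a' and trait_b=='b'").iloc[0]
        assert 0.75 <= row.r <= 0.97
        assert row.p <= 0.01 and row.tier == "***"

    def test_constant_trait_reported_missing(self):
        t = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [7.0, 7, 7, 7]})
        row = quantgen.correlation_matrix(t).query("trait_a=='a' and trait_b=='b'").iloc[0]
        assert np.isnan(row.r) and row.tier == "none"

    def test_tiers_monotone_in_p(self):
        tiers = [quantgen._tier(p) for p in (0.001, 0.03, 0.08, 0.5)]
        assert tiers == ["***", "**", "*", "none"]

    def test_pairwise_complete_handling(self):
        t = pd.DataFrame({
            "a": [1.0, 2, 3, 4, np.nan],
            "b": [2.0, 4, 6, 8, 10],
        })
        row = quantgen.correlation_matrix(t).query("trait_a=='a' and trait_b=='b'").iloc[0]
        assert row.n == 4 and row.r == pytest.approx(1.0)


class TestHeterosis:
    def test_printed_reproductive_tiller_row(self):
        assert quantgen.mid_parent_heterosis(63.81, 17.67, 41.33) == pytest.approx(116.31, abs=0.005)
        assert quantgen.heterobeltiosis(63.81, 17.67, 41.33) == pytest.approx(54.39, abs=0.005)

    def test_printed_tiller_height_row(self):
        assert quantgen.mid_parent_heterosis(126.94, 109.40, 128.67) == pytest.approx(6.64, abs=0.005)
        assert quantgen.heterobeltiosis(126.94, 109.40, 128.67) == pytest.approx(-1.34, abs=0.005)

    def test_fixed_points(self):
        assert quantgen.mid_parent_heterosis(10.0, 8.0, 12.0) == 0.0
        assert quantgen.heterobeltiosis(12.0, 8.0, 12.0) == 0.0

    def test_scale_invariance(self):
        a = quantgen.mid_parent_heterosis(5.0, 2.0, 4.0)
        b = quantgen.mid_parent_heterosis(50.0, 20.0, 40.0)
        assert a == pytest.approx(b)

    def test_hb_le_mph_for_positive_parents(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            mo, fa, f1 = rng.uniform(0.5, 100, 3)
            mph = quantgen.mid_parent_heterosis(f1, mo, fa)
            hb = quantgen.heterobeltiosis(f1, mo, fa)
            assert hb <= mph + 1e-9

    def test_table_with_missing_parent_trait(self):
        f1 = pd.DataFrame({"x": [1.0, 2, 3], "y": [2.0, 3, 4]})
        parents = pd.DataFrame(
            {"mother_mean": [1.0], "father_mean": [3.0]}, index=["x"]
        )
        table = quantgen.heterosis_table(f1, parents)
        assert np.isnan(table.loc["y", "mph_pct"])
        assert table.loc["x", "mph_pct"] == pytest.approx(0.0)

    def test_sign_means(self):
        table = pd.DataFrame({"mph_pct": [10.0, -5.0, 30.0], "hb_pct": [-2.0, -4.0, 6.0]})
        sm = quantgen.heterosis_sign_means(table)
        assert sm.loc["positive_mean", "mph_pct"] == pytest.approx(20.0)
        assert sm.loc["negative_mean", "hb_pct"] == pytest.approx(-3.0)

    def test_parameter_recovery_from_simdata(self):
        spec = simdata.default_trait_spec()
        t = simdata.simulate_traits(spec, 5000, seed=8)
        table = quantgen.heterosis_table(t, simdata.parent_means_frame(spec))
        mp = (spec.mother_means + spec.father_means) / 2
        se_pct = 100 * t.std(ddof=1).to_numpy() / np.sqrt(len(t)) / mp
        target_pct = 100 * spec.mph_targets
        assert (np.abs(table["mph_pct"].to_numpy() - target_pct) < 3 * se_pct).all()


class TestSelfFertility:
    def test_rate_arithmetic(self):
        records = pd.DataFrame({
            "unit_id": ["a", "b"],
            "level": ["parent_spike", "f1_plant"],
            "seeds": [0, 5],
            "spikelets": [20, 200],
        })
        res = quantgen.self_fertility(records)
        assert res.records.set_index("unit_id").loc["a", "rate"] == 0.0
        assert res.records.set_index("unit_id").loc["b", "rate"] == pytest.approx(2.5)

    def test_zero_spikelets_rejected_not_fatal(self):
        records = pd.DataFrame({
            "unit_id": ["a", "b"],
            "level": ["parent_spike", "parent_spike"],
            "seeds": [1, 1],
            "spikelets": [0, 10],
        })
        res = quantgen.self_fertility(records)
        assert list(res.rejected["unit_id"]) == ["a"]
        assert len(res.records) == 1

    def test_welch_separates_parent_from_f1(self):
        # parent rates an order of magnitude above F1 plant rates
        records = pd.DataFrame({
            "unit_id": [f"p{i}" for i in range(5)] + [f"f{i}" for i in range(5)],
            "level": ["parent_spike"] * 5 + ["f1_plant"] * 5,
            "seeds": [38, 18, 25, 30, 21, 3, 1, 2, 4, 2],
            "spikelets": [1000] * 10,
        })
        res = quantgen.self_fertility(records)
        # oracle: scipy Welch test on the same rate vectors
        t, p = stats.ttest_ind(
            res.records.query("level=='parent_spike'")["rate"],
            res.records.query("level=='f1_plant'")["rate"],
            equal_var=False,
        )
        assert res.welch_p == pytest.approx(p)
        assert res.welch_p < 0.01

    def test_summary_columns(self):
        records = pd.DataFrame({
            "unit_id": ["a", "b", "c"],
            "level": ["parent_spike"] * 3,
            "seeds": [3, 2, 1],
            "spikelets": [100, 100, 100],
        })
        s = quantgen.self_fertility(records).summary
        assert s.loc["parent_spike", "max"] == pytest.approx(3.0)
        assert s.loc["parent_spike", "min"] == pytest.approx(1.0)
        assert s.loc["parent_spike", "mean"] == pytest.approx(2.0)


class TestPurityCrossCheck:
    def test_within(self):
        assert quantgen.purity_cross_check(3.25, 1.79, 3.76) == quantgen.WITHIN_RANGE

    def test_above(self):
        assert quantgen.purity_cross_check(4.20, 1.79, 3.76) == quantgen.ABOVE_RANGE

    def test_boundary_counts_as_within(self):
        assert quantgen.purity_cross_check(1.79, 1.79, 3.76) == quantgen.WITHIN_RANGE
        assert quantgen.purity_cross_check(3.76, 1.79, 3.76) == quantgen.WITHIN_RANGE

    def test_below(self):
        assert quantgen.purity_cross_check(0.5, 1.79, 3.76) == quantgen.BELOW_RANGE

    def test_inverted_range_error(self):
        with pytest.raises(InputError):
            quantgen.purity_cross_check(2.0, 3.0, 1.0)


class TestCombinationSummary:
    def test_chained_rates(self):
        records = pd.DataFrame([
            {"cross": "A x B", "seeds": 300, "survived": 147,
             "overwintered": 123, "fertile": 117},
        ])
        out = quantgen.combination_summary(records)
        assert out.loc["A x B", "survival_pct"] == pytest.approx(49.00)
        assert out.loc["A x B", "overwintering_pct"] == pytest.approx(83.67)
        assert out.loc["A x B", "fertile_pct"] == pytest.approx(95.12)

    def test_zero_fertile(self):
        records = pd.DataFrame([
            {"cross": "C", "seeds": 100, "survived": 50, "overwintered": 40, "fertile": 0},
        ])
        assert quantgen.combination_summary(records).loc["C", "fertile_pct"] == 0.0

    def test_below_threshold_not_evaluated(self):
        records = pd.DataFrame([
            {"cross": "D", "seeds": 30, "survived": 10, "overwintered": 5, "fertile": 2},
        ])
        out = quantgen.combination_summary(records, min_seeds=50)
        assert not out.loc["D", "evaluated"]
        assert np.isnan(out.loc["D", "survival_pct"])
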