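import numpy as np
import pytest
from scipy import stats as sps

from dwihist.stats import (auc_mann_whitney, analyze_cohort, compare_groups,
                           delong_components, delong_test, icc_band,
                           interobserver_agreement, roc_analysis)
from dwihist.phantom import simulate_feature_cohort

from _oracles import (brute_force_auc, delong_variance_oracle,
                      exhaustive_youden, icc21_anova)


def random_cohort(rng, n_pos=8, n_neg=10, ties=False):
    vals = rng.normal(size=n_pos + n_neg)
    if ties:
        vals = np.round(vals, 1)
    labels = np.array(["hard"] * n_pos + ["soft"] * n_neg)
    return vals, labels


class TestCompareGroups:
    def test_identical_groups_never_significant(self):
        gc = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert gc.test_used == "t-test"
        assert gc.p_value == pytest.approx(1.0)

    def test_separated_groups_significant_with_extreme_u(self):
        gc = compare_groups([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert gc.p_value < 0.05
        # U = 0: every hard value exceeds every soft value
        u = sps.mannwhitneyu([1, 2, 3], [101, 102, 103],
                             alternative="two-sided").statistic
        assert u == 0.0

    def test_large_shifted_normals_reject_strongly(self, rng):
        a = rng.normal(0, 1, 1000)
        b = rng.normal(1, 1, 1000)
        gc = compare_groups(a, b)
        assert gc.p_value < 1e-10

    def test_normality_gate_routes_to_mann_whitney(self, rng):
        skewed = np.exp(rng.normal(size=80) * 2)
        gc = compare_groups(skewed, rng.normal(size=80))
        assert gc.test_used == "mann-whitney"

    def test_constant_identical_groups_flagged_p_one(self):
        gc = compare_groups([2.0] * 5, [2.0] * 5)
        assert gc.p_value == 1.0 and gc.flagged

    def test_summaries_always_computed_both_ways(self):
        gc = compare_groups([1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0])
        s = gc.group_summaries["soft"]
        assert s["mean"] == 2.5 and s["median"] == 2.5 and s["iqr"] == 1.5

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])


class TestRoc:
    def test_perfect_classifier(self):
        d = roc_analysis([1, 2, 3, 4], ["soft", "soft", "hard", "hard"])
        assert d.auc == 1.0 and d.youden == 1.0
        assert d.sensitivity == 1.0 and d.specificity == 1.0
        assert d.cutoff == 3.0 and d.orientation == "higher-is-hard"

    def test_brute_force_pair_count(self):
        d = roc_analysis([1, 3, 2, 4], ["soft", "soft", "hard", "hard"])
        assert d.auc == 0.75

    def test_all_ties_gives_half(self):
        d = roc_analysis([5, 5, 5, 5], ["soft", "soft", "hard", "hard"])
        assert d.auc == 0.5 and d.flagged

    def test_auc_equals_mann_whitney_and_flip_identity(self, rng):
        for ties in (False, True):
            for _ in range(200):
                vals, labels = random_cohort(rng, ties=ties)
                y = labels == "hard"
                assert auc_mann_whitney(vals, y) == pytest.approx(
                    brute_force_auc(vals, y), abs=1e-12)
                assert auc_mann_whitney(vals, y) + \
                    auc_mann_whitney(-vals, y) == pytest.approx(1.0)

    def test_youden_cutoff_matches_exhaustive_search(self, rng):
        for _ in range(100):
            vals, labels = random_cohort(rng, ties=True)
            d = roc_analysis(vals, labels)
            scores = vals if d.orientation == "higher-is-hard" else -vals
            oracle = exhaustive_youden(scores, labels == "hard")
            assert d.youden == pytest.approx(oracle["youden"], abs=1e-12)

    def test_orientation_flip_for_lower_is_hard_feature(self, rng):
        vals = np.concatenate([np.full(5, 1.0), np.full(5, 2.0)])
        labels = np.array(["hard"] * 5 + ["soft"] * 5)
        d = roc_analysis(vals, labels)
        assert d.orientation == "lower-is-hard"
        assert d.auc == 1.0 and d.cutoff == 1.0

    def test_ci_brackets_auc(self, rng):
        vals, labels = random_cohort(rng, 12, 15)
        d = roc_analysis(vals, labels)
        assert d.auc_ci_low <= d.auc <= d.auc_ci_high
        assert d.youden == pytest.approx(d.sensitivity + d.specificity - 1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2], ["hard", "hard"])


class TestDeLong:
    def test_self_comparison_is_null(self, rng):
        vals, labels = random_cohort(rng)
        r = delong_test(vals, vals, labels)
        assert r.z == 0.0 and r.p_value == 1.0 and r.flagged

    def test_structural_component_auc_equals_trapezoidal(self, rng):
        for _ in range(100):
            vals, labels = random_cohort(rng, ties=True)
            auc, v10, v01 = delong_components(vals, labels == "hard")
            assert auc == pytest.approx(
                auc_mann_whitney(vals, labels == "hard"), abs=1e-12)
            assert v01.mean() == pytest.approx(auc, abs=1e-12)

    def test_variance_matches_enumeration_oracle_small_n(self, rng):
        # n = 6 (3 hard / 3 soft): everything enumerable by hand loops
        labels = np.array(["hard"] * 3 + ["soft"] * 3)
        for _ in range(50):
            a = rng.normal(size=6)
            b = a + rng.normal(size=6)
            r = delong_test(a, b, labels)
            oracle = delong_variance_oracle(a, b, labels == "hard")
            assert r.auc_a == pytest.approx(oracle["auc_a"], abs=1e-12)
            assert r.var_diff == pytest.approx(oracle["var"], abs=1e-10)

    def test_p_values_in_unit_interval(self, rng):
        for _ in range(50):
            a, labels = random_cohort(rng)
            b = a + rng.normal(size=a.size)
            r = delong_test(a, b, labels)
            assert 0.0 <= r.p_value <= 1.0


class TestAgreement:
    def test_identical_raters(self):
        r = interobserver_agreement([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert r.icc == 1.0 and r.icc_band == "excellent"
        assert r.bland_altman_bias == 0.0
        assert (r.loa_low, r.loa_high) == (0.0, 0.0)

    def test_constant_shift_bias(self):
        r = interobserver_agreement([1.0, 2, 3, 4, 5],
                                    [3.5, 4.5, 5.5, 6.5, 7.5])
        assert r.bland_altman_bias == pytest.approx(2.5)
        assert r.loa_low == pytest.approx(2.5) and \
            r.loa_high == pytest.approx(2.5)

    def test_icc_matches_anova_mean_squares_5x2(self):
        r1 = [9.0, 10.5, 12.0, 8.0, 14.5]
        r2 = [9.5, 10.0, 12.5, 8.5, 13.0]
        res = interobserver_agreement(r1, r2)
        assert res.icc == pytest.approx(icc21_anova(r1, r2), abs=1e-10)

    def test_icc3_option(self):
        r1 = [9.0, 10.5, 12.0, 8.0, 14.5]
        r2 = [9.5, 10.0, 12.5, 8.5, 13.0]
        a2 = interobserver_agreement(r1, r2, icc_form="icc2")
        a3 = interobserver_agreement(r1, r2, icc_form="icc3")
        assert a3.icc != a2.icc and a3.icc_form == "icc3"

    def test_band_boundaries_closed_as_printed(self):
        assert icc_band(0.20) == "poor"
        assert icc_band(0.205) == "poor"      # between printed bounds
        assert icc_band(0.21) == "fair"
        assert icc_band(0.41) == "moderate"
        assert icc_band(0.61) == "good"
        assert icc_band(0.81) == "excellent"
        assert icc_band(-0.4) == "poor"
        assert icc_band(1.0) == "excellent"

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            interobserver_agreement([1.0, 2.0], [1.0, 2.0])


class TestAnalyzeCohort:
    def test_separated_feature_detected_and_delong_emitted(self):
        stats = {"alpha_p90": {"soft": (0.85, 0.05), "hard": (0.93, 0.05)},
                 "noise": {"soft": (0.5, 0.1), "hard": (0.5, 0.1)}}
        df = simulate_feature_cohort(stats, 30, 17, seed=2)
        res = analyze_cohort(df)
        assert res.n_features_tested == 2
        sig = [d.feature_name for d in res.diagnostics]
        assert "alpha_p90" in sig
        assert all(0.5 <= d.auc <= 1.0 for d in res.diagnostics)

    def test_feature_subset_restricts_tables(self):
        df = simulate_feature_cohort(n_soft=10, n_hard=10, seed=0)
        res = analyze_cohort(df, features=["alpha_p90"])
        assert res.n_features_tested == 1

    def test_single_class_cohort_rejected(self):
        df = simulate_feature_cohort(n_soft=5, n_hard=5, seed=0)
        with pytest.raises(ValueError):
            analyze_cohort(df[df.label == "soft"])
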