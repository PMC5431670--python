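"""Cumulative curves, bootstrap SEM, KS tests, correlations, binary rules
and error-corrected fractions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from savkit import (
    MethodConfig,
    SAV,
    ScoredSAV,
    bootstrap_sem,
    classify_binary,
    cumulative_effect_curve,
    effect_auc,
    error_correct_fractions,
    grouped_distribution_summary,
    ks_two_sample,
    normalize_for_correlation,
    pearson_with_se,
    se_of_r,
    threshold_accuracy_curve,
)
from savkit.score_statistics import (
    EmptyInputError,
    METHOD_DEFAULTS,
    StatisticsError,
)


from _oracles import brute_force_ks_d


class TestCumulativeCurve:
    def test_direct_counts(self):
        curve = cumulative_effect_curve([0, 50, 100], n_boot=0)
        assert curve.at(50) == pytest.approx(2 / 3)
        assert curve.at(-100) == 1.0
        assert curve.at(100) == pytest.approx(1 / 3)

    def test_step_at_common_value(self):
        curve = cumulative_effect_curve([75, 75, 75], n_boot=0)
        assert curve.at(75) == 1.0
        assert curve.at(76) == 0.0

    def test_monotone_and_anchored(self, rng):
        scores = rng.uniform(-100, 100, size=500)
        curve = cumulative_effect_curve(scores, n_boot=0)
        assert np.all(np.diff(curve.fraction) <= 0)
        assert curve.fraction[0] == 1.0

    def test_two_implementation_agreement(self, rng):
        """Sorted searchsorted counting equals a naive linear scan."""
        scores = rng.uniform(-100, 100, size=200)
        curve = cumulative_effect_curve(scores, n_boot=0)
        for t in (-100, -42, 0, 50, 75, 100):
            naive = np.mean([s >= t for s in scores])
            assert curve.at(t) == pytest.approx(naive)

    def test_band_is_score_axis_shift(self, rng):
        scores = rng.normal(0, 30, size=300).clip(-100, 100)
        curve = cumulative_effect_curve(scores, n_boot=50, seed=4)
        low, high = curve.band_curves()
        assert np.allclose(high - low, 6 * curve.sem)

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            cumulative_effect_curve([])


class TestBootstrapSem:
    def test_constant_data_gives_zero(self):
        for seed in (0, 1, 99):
            assert bootstrap_sem([5, 5, 5, 5], seed=seed) == 0.0

    def test_matches_analytic_sem(self, rng):
        """On a large normal sample the bootstrap SEM approximates
        sigma/sqrt(n) within 15% (noise at n_boot=100)."""
        sigma, n = 20.0, 10_000
        scores = rng.normal(0, sigma, size=n)
        sem = bootstrap_sem(scores, n_boot=100, seed=8)
        analytic = scores.std(ddof=1) / np.sqrt(n)
        assert abs(sem - analytic) / analytic < 0.15

    def test_deterministic_per_seed(self, rng):
        scores = rng.normal(size=50)
        assert bootstrap_sem(scores, seed=3) == bootstrap_sem(scores, seed=3)

    def test_n_boot_validation(self):
        with pytest.raises(StatisticsError):
            bootstrap_sem([1.0, 2.0], n_boot=1)


class TestKS:
    def test_identical_samples(self, rng):
        a = rng.normal(size=40)
        res = ks_two_sample(a, a)
        assert res.D == 0.0

    def test_disjoint_supports(self):
        res = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert res.D == 1.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n, m = rng.integers(1, 13, size=2)
            a = rng.normal(size=n).round(1)  # rounding forces ties
            b = rng.normal(size=m).round(1)
            res = ks_two_sample(a, b)
            assert res.D == pytest.approx(brute_force_ks_d(a, b)), (a, b)

    def test_p_floor_formatting(self, rng):
        a = rng.normal(0, 1, size=20_000)
        b = rng.normal(3, 1, size=20_000)
        res = ks_two_sample(a, b)
        assert res.p_text == "< 2.2e-16"


class TestCorrelation:
    @pytest.mark.parametrize(
        "r, n, expected",
        [(0.36, 18_876, 6.8e-3), (0.57, 209_928, 1.8e-3), (0.53, 209_928, 1.9e-3)],
    )
    def test_se_r_worked_examples(self, r, n, expected):
        assert se_of_r(r, n) == pytest.approx(expected, rel=0.05)

    def test_se_r_degenerate_case(self):
        assert se_of_r(0.0, 3) == 1.0

    def test_se_r_monotone_in_n(self):
        values = [se_of_r(0.5, n) for n in (10, 100, 1000, 10_000)]
        assert values == sorted(values, reverse=True)

    def test_missing_pairs_dropped(self):
        res = pearson_with_se([1, 2, 3, None, 5], [2, 4, 6, 8, float("nan")])
        assert res.n == 3
        assert res.r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(StatisticsError):
            pearson_with_se([1, 1, 1], [1, 2, 3])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(StatisticsError):
            pearson_with_se([1, 2], [3, 4])


class TestEffectAuc:
    @pytest.mark.parametrize(
        "scores, expected",
        [([50, 50], 1.0), ([-50, -50], 0.0), ([-10, -10, 10, 10], 0.5)],
    )
    def test_mass_above_zero(self, scores, expected):
        assert effect_auc(scores) == expected

    def test_complement_identity(self, rng):
        scores = rng.uniform(-100, 100, size=300)
        assert effect_auc(scores) + np.mean(scores <= 0) == 1.0


class TestAccuracyCurve:
    labeled = [(80.0, "effect"), (60.0, "effect"), (-10.0, "effect"),
               (-80.0, "neutral"), (70.0, "neutral")]

    def _at(self, curve, t):
        (i,) = np.where(curve.thresholds == t)
        return curve, int(i[0])

    def test_effect_accuracy_counts(self):
        curve = threshold_accuracy_curve(self.labeled)
        i = int(np.where(curve.thresholds == 50)[0][0])
        assert curve.tp[i] == 2 and curve.fp[i] == 1
        assert curve.effect_accuracy[i] == pytest.approx(2 / 3)

    def test_clean_separation(self):
        curve = threshold_accuracy_curve(
            [(80.0, "effect"), (60.0, "effect"), (-80.0, "neutral")]
        )
        i = int(np.where(curve.thresholds == 50)[0][0])
        assert curve.effect_accuracy[i] == 1.0

    def test_neutral_accuracy_counts(self):
        curve = threshold_accuracy_curve(self.labeled)
        i = int(np.where(curve.thresholds == -42)[0][0])
        assert curve.tn[i] == 1 and curve.fn[i] == 0
        assert curve.neutral_accuracy[i] == 1.0

    def test_tp_plus_fp_equals_scores_at_or_above(self):
        curve = threshold_accuracy_curve(self.labeled)
        scores = np.array([s for s, _ in self.labeled])
        for i, t in enumerate(curve.thresholds):
            assert curve.tp[i] + curve.fp[i] == np.sum(scores >= t)

    def test_undefined_is_nan_not_zero(self):
        curve = threshold_accuracy_curve(
            [(-50.0, "effect"), (-60.0, "neutral")]
        )
        i = int(np.where(curve.thresholds == 80)[0][0])
        assert np.isnan(curve.effect_accuracy[i])

    def test_single_label_rejected(self):
        with pytest.raises(StatisticsError):
            threshold_accuracy_curve([(1.0, "effect")])


class TestBinaryRules:
    def _scored(self, method, value):
        return ScoredSAV(SAV("p", 1, "A", "C"), {method: value})

    @pytest.mark.parametrize(
        "method, value, expected",
        [
            ("SNAP2", 0.0, "neutral"),
            ("SNAP2", 0.5, "effect"),
            ("SNAP2", -99.0, "neutral"),
            ("CADD", 3.0, "neutral"),
            ("CADD", 3.01, "effect"),
            ("SIFT", "tolerated", "neutral"),
            ("SIFT", "deleterious", "effect"),
            ("PolyPhen-2", "probably_damaging", "effect"),
            ("PolyPhen-2", "benign", "neutral"),
        ],
    )
    def test_default_thresholds(self, method, value, expected):
        assert classify_binary(self._scored(method, value),
                               METHOD_DEFAULTS[method]) == expected

    def test_sift_inversion(self):
        cfg = MethodConfig("SIFT-score", threshold=0.5, invert=True)
        assert normalize_for_correlation(self._scored("SIFT-score", 0.0), cfg) == 1.0
        assert normalize_for_correlation(self._scored("SIFT-score", 1.0), cfg) == 0.0

    def test_identity_transform(self):
        cfg = METHOD_DEFAULTS["SNAP2"]
        assert normalize_for_correlation(self._scored("SNAP2", 37.0), cfg) == 37.0


class TestErrorCorrection:
    def test_zero_rates_identity(self):
        res = error_correct_fractions(0.3, 0.7, 0.0, 0.0)
        assert res.neff_star == 0.3 and res.nneu_star == 0.7

    def test_worked_example(self):
        res = error_correct_fractions(0.5, 0.5, fpr=0.22, fnr=0.23)
        assert res.neff_star == pytest.approx(0.505)

    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_mass_conserved(self, neff, fpr, fnr):
        res = error_correct_fractions(neff, 1.0 - neff, fpr, fnr)
        assert abs(res.neff_star + res.nneu_star - 1.0) < 1e-12

    def test_inconsistent_fractions_rejected(self):
        with pytest.raises(StatisticsError):
            error_correct_fractions(0.5, 0.6)


class TestGroupedSummary:
    def test_identical_groups_d_zero(self, rng):
        scores = rng.uniform(-50, 50, size=100)
        summaries, pairwise = grouped_distribution_summary(
            {"a": scores, "b": scores.copy()}, n_boot=0
        )
        assert pairwise[("a", "b")].D == 0.0
        assert summaries["a"].mean == summaries["b"].mean

    def test_mean_ordering_preserved(self, rng):
        groups = {
            "low": rng.normal(10, 20, size=5000).clip(-100, 100),
            "high": rng.normal(30, 20, size=5000).clip(-100, 100),
        }
        summaries, _ = grouped_distribution_summary(groups, n_boot=0)
        assert summaries["low"].mean < summaries["high"].mean

    def test_single_group_has_no_pairs(self, rng):
        _, pairwise = grouped_distribution_summary({"only": rng.normal(size=10)},
                                                   n_boot=0)
        assert pairwise == {}

    def test_empty_group_named(self):
        with pytest.raises(EmptyInputError, match="bad"):
            grouped_distribution_summary({"bad": []})
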