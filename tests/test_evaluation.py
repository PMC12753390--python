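import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eeg2bold.evaluation import (ExperimentConfig, ResampledBaselineConfig,
                                 benjamini_hochberg, constant_baselines,
                                 make_cv_plan, mcnemar_exact_or_chi2,
                                 mcnemar_vs_resampled_baseline,
                                 run_experiment, wilcoxon_one_sided,
                                 wilcoxon_vs_resampled_baseline)
from eeg2bold.models import ModelSpec


class TestCVPlan:
    def test_classical_rotation(self):
        plan = make_cv_plan(("A", "B", "C"))
        triples = [(it.train_condition, it.test_condition, it.third_condition)
                   for it in plan.iterations]
        assert triples == [("A", "B", "C"), ("B", "C", "A"), ("C", "A", "B")]
        assert all(it.third_role == "left_out" for it in plan.iterations)

    def test_each_condition_trains_and_tests_exactly_once(self):
        plan = make_cv_plan(("A", "B", "C"))
        trains = [it.train_condition for it in plan.iterations]
        tests = [it.test_condition for it in plan.iterations]
        assert sorted(trains) == sorted(tests) == ["A", "B", "C"]

    def test_neural_flag_marks_validation(self):
        plan = make_cv_plan(("A", "B", "C"), needs_validation=True)
        assert all(it.third_role == "validation" for it in plan.iterations)

    def test_wrong_condition_count_errors(self):
        with pytest.raises(ValueError):
            make_cv_plan(("A", "B"))


class TestConstantBaselines:
    def test_classification_accuracy_is_increase_fraction(self):
        labels = np.array(["increase"] * 12 + ["decrease"] * 8)
        baseline = constant_baselines("classification")
        acc = np.mean(baseline.predict(labels) == labels)
        assert acc == pytest.approx(0.6)

    def test_balanced_labels_give_half(self):
        labels = np.array(["increase", "decrease"] * 10)
        baseline = constant_baselines("classification")
        assert np.mean(baseline.predict(labels) == labels) == pytest.approx(0.5)

    def test_zero_regression_mae_converges_to_mean_absolute_deviation(self):
        rng = np.random.default_rng(0)
        target = rng.normal(size=1_000_000)
        baseline = constant_baselines("regression")
        mae = np.mean(np.abs(baseline.predict(target) - target))
        assert mae == pytest.approx(np.sqrt(2 / np.pi), rel=0.01)


def brute_force_one_sided_p(d):
    """Exhaustive sign-assignment enumeration for the signed-rank null."""
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    n = len(d)
    for signs in itertools.product([False, True], repeat=n):
        if ranks[list(signs)].sum() >= w_obs - 1e-12:
            count += 1
    return count / 2 ** n


class TestWilcoxon:
    def test_six_distinct_positive_differences(self):
        result = wilcoxon_one_sided(np.arange(1.0, 7.0), np.zeros(6), "greater")
        assert result.p_value == pytest.approx(1 / 64)
        assert result.rbc == 1.0
        assert result.cles == 1.0

    def test_matches_exhaustive_enumeration_small_n(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 100:
            n = rng.integers(5, 13)
            d = rng.integers(-5, 6, size=n).astype(float)
            if (d != 0).sum() < 5:
                continue
            mine = wilcoxon_one_sided(d, np.zeros_like(d), "greater").p_value
            assert mine == pytest.approx(brute_force_one_sided_p(d), abs=1e-12)
            checked += 1

    def test_matches_scipy_exact_and_approx(self):
        rng = np.random.default_rng(1)
        d_small = rng.normal(0.3, 1.0, size=20)  # tie-free, exact branch
        assert wilcoxon_one_sided(d_small, np.zeros(20)).p_value == \
            pytest.approx(stats.wilcoxon(d_small, alternative="greater",
                                         method="exact").pvalue)
        d_large = rng.normal(0.1, 1.0, size=60)  # approx branch
        assert wilcoxon_one_sided(d_large, np.zeros(60)).p_value == \
            pytest.approx(stats.wilcoxon(d_large, alternative="greater",
                                         correction=True,
                                         method="approx").pvalue)

    def test_direction_less_flips_the_test(self):
        d = np.arange(1.0, 9.0)
        high = wilcoxon_one_sided(d, np.zeros(8), "greater").p_value
        low = wilcoxon_one_sided(d, np.zeros(8), "less").p_value
        assert high < 0.05 < low

    def test_zero_differences_discarded(self):
        metrics = np.array([1.0, 2, 3, 4, 5, 6, 0, 0])
        baselines = np.zeros(8)
        baselines[6:] = 0.0
        result = wilcoxon_one_sided(metrics[:6], baselines[:6], "greater")
        with_zeros = wilcoxon_one_sided(
            np.concatenate([metrics[:6], [0, 0]]), np.zeros(8), "greater")
        assert with_zeros.p_value == pytest.approx(result.p_value)
        assert with_zeros.n_informative == 6
        assert with_zeros.cles == pytest.approx((6 + 0.5 * 2) / 8)

    def test_all_zero_differences_undefined(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_one_sided(np.zeros(10), np.zeros(10), "greater")

    def test_rbc_sign_reflects_dominant_direction(self):
        d = np.array([-5.0, -4, -3, -2, -1, 0.5])
        assert wilcoxon_one_sided(d, np.zeros(6), "greater").rbc < 0


class TestMcNemar:
    def test_worked_discordant_example(self):
        assert mcnemar_exact_or_chi2(8, 2) == pytest.approx(0.109375)

    def test_exact_branch_matches_doubled_binomial_everywhere(self):
        for n_disc in range(1, 26):
            for b in range(n_disc + 1):
                c = n_disc - b
                expected = min(1.0, 2.0 * stats.binom.cdf(min(b, c), n_disc, 0.5))
                assert mcnemar_exact_or_chi2(b, c) == pytest.approx(expected)

    def test_exact_branch_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar
        rng = np.random.default_rng(2)
        for _ in range(30):
            b, c = rng.integers(0, 13, size=2)
            if b + c == 0:
                continue
            ref = sm_mcnemar([[0, b], [c, 0]], exact=True).pvalue
            assert mcnemar_exact_or_chi2(int(b), int(c)) == pytest.approx(ref)

    def test_no_discordance_is_p_one(self):
        assert mcnemar_exact_or_chi2(0, 0) == 1.0

    def test_chi2_branch_for_large_discordance(self):
        p = mcnemar_exact_or_chi2(40, 10)
        stat = (abs(40 - 10) - 1) ** 2 / 50
        assert p == pytest.approx(stats.chi2.sf(stat, 1))


class TestResampledBaseline:
    def test_oracle_model_on_balanced_truths_is_significant(self):
        rng = np.random.default_rng(3)
        truths = rng.choice(["increase", "decrease"], size=200)
        cfg = ResampledBaselineConfig(n_iterations_mcnemar=500, seed=3)
        summary = mcnemar_vs_resampled_baseline(truths, truths, cfg)
        assert summary.median_p < 0.05

    def test_null_model_rarely_significant(self):
        rng = np.random.default_rng(4)
        truths = rng.choice(["increase", "decrease"], size=200)
        model = rng.choice(truths, size=200)  # fresh draw from the same null
        cfg = ResampledBaselineConfig(n_iterations_mcnemar=2000, seed=4)
        summary = mcnemar_vs_resampled_baseline(model, truths, cfg)
        assert summary.proportion_significant <= 0.10

    def test_histogram_covers_unit_interval_in_20_bins(self):
        rng = np.random.default_rng(5)
        truths = rng.choice(["increase", "decrease"], size=50)
        cfg = ResampledBaselineConfig(n_iterations_mcnemar=200, seed=5)
        summary = mcnemar_vs_resampled_baseline(truths, truths, cfg)
        assert len(summary.histogram) == 20
        assert summary.histogram.sum() == 200

    def test_wilcoxon_path_oracle_beats_baseline(self):
        rng = np.random.default_rng(6)
        pair_ids = np.repeat(np.arange(10), 30)
        truths = rng.choice(["increase", "decrease"], size=300)
        cfg = ResampledBaselineConfig(n_iterations_wilcoxon=200, seed=6)
        summary = wilcoxon_vs_resampled_baseline(truths, truths, pair_ids, cfg)
        assert summary.median_p < 0.05

    def test_empty_predictions_error(self):
        with pytest.raises(ValueError, match="empty"):
            mcnemar_vs_resampled_baseline(np.array([]), np.array([]),
                                          ResampledBaselineConfig())


class TestBenjaminiHochberg:
    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=30)
        q = benjamini_hochberg(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


@pytest.fixture(scope="module")
def small_result():
    from eeg2bold.synthetic import SyntheticConfig
    cfg = SyntheticConfig(n_subjects=2, n_channels=4, n_regions=3,
                          n_scans=80, coupling_gain=2.0, noise_sd=0.8,
                          seed=13)
    specs = [ModelSpec("logistic", "classification", seed=0),
             ModelSpec("linear", "regression", seed=0)]
    return run_experiment(ExperimentConfig(cfg, specs))


class TestRunExperiment:
    def test_pair_count_conservation(self, small_result):
        table = small_result.pair_table
        for model in table["model"].unique():
            n = len(table[table["model"] == model])
            excluded = sum(1 for e in small_result.exclusions
                           if e["model"] == model)
            assert n + excluded == 2 * 3 * 3  # subjects × regions × iterations

    def test_report_contains_effect_sizes_and_pearson(self, small_result):
        cls = small_result.report.per_model["logistic_cla"]
        reg = small_result.report.per_model["linear_reg"]
        assert -1 <= cls.rbc <= 1
        assert 0 <= cls.cles <= 1
        assert reg.pearson_r is not None

    def test_per_roi_table_has_one_row_per_model_region(self, small_result):
        per_roi = small_result.report.per_roi
        assert len(per_roi) == 2 * 3  # models × regions
        assert {"mean_metric", "p_value", "q_value_bh"} <= set(per_roi.columns)

    def test_pairwise_table_is_same_task_only(self, small_result):
        pairwise = small_result.report.pairwise_p
        assert np.isnan(pairwise.loc["logistic_cla", "linear_reg"])

    def test_deterministic_given_seed(self):
        from eeg2bold.synthetic import SyntheticConfig
        cfg = SyntheticConfig(n_subjects=1, n_channels=3, n_regions=2,
                              n_scans=60, seed=14)
        spec = [ModelSpec("dtree", "classification", {"max_depth": 3}, seed=1)]
        a = run_experiment(ExperimentConfig(cfg, spec))
        b = run_experiment(ExperimentConfig(cfg, spec))
        pd.testing.assert_frame_equal(a.pair_table, b.pair_table)
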