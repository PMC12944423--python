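"""Statistics layer: ANOVA, BH-FDR, effect sizes, metrics, experiment loop."""

import numpy as np
import pytest

from miaug import CascadeSpec
from miaug.evaluation import (
    accuracy_from_confusion,
    bh_fdr,
    cohens_d,
    compare_to_baseline,
    confusion_matrix,
    one_way_anova,
    run_experiment,
    summarize,
    summary_table,
    tidy_results,
)
from miaug.transforms import AugmenterSpec


def brute_force_bh(p):
    """BH step-up by definition — the independent oracle."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adjusted[i] = running_min
    return np.minimum(adjusted, 1.0)


class TestAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        f, p = one_way_anova([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert f == 0.0 and p == 1.0

    def test_separated_groups_give_tiny_p(self):
        rng = np.random.default_rng(0)
        a = 0.0 + 1e-9 * rng.normal(size=4)
        b = 1.0 + 1e-9 * rng.normal(size=4)
        _, p = one_way_anova([a, b])
        assert p < 1e-6

    def test_f_equals_t_squared_for_two_groups(self):
        """Two-group ANOVA must reduce to the squared equal-variance t-test."""
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.normal(size=rng.integers(3, 12))
            b = rng.normal(loc=rng.normal(), size=rng.integers(3, 12))
            f, p_f = one_way_anova([a, b])
            t, p_t = ttest_ind(a, b, equal_var=True)
            assert f == pytest.approx(t**2, rel=1e-9)
            assert p_f == pytest.approx(p_t, rel=1e-9)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0]])
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [2.0, 3.0]])


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_equal_ps_unchanged(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2, 0.2]), 0.2)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 21))
            assert np.allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=15)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)


class TestCohensD:
    def test_identical_samples_give_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_unit_separation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=20_000)
        b = a - 1.0
        assert cohens_d(a, b) == pytest.approx(1.0, abs=0.02)

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=10), rng.normal(size=12)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))


class TestSummarize:
    def test_median_interpolation(self):
        assert summarize([1, 2, 3, 4])["median"] == 2.5

    def test_constant_samples_iqr_zero(self):
        assert summarize([5, 5, 5])["iqr"] == 0.0

    def test_quantile_convention(self):
        s = summarize([0, 25, 50, 75, 100])
        assert s["median"] == 50.0
        assert s["iqr"] == 50.0


class TestConfusion:
    def test_all_correct_is_diagonal(self):
        cm = confusion_matrix(["LEFT", "RIGHT", "REST"], ["LEFT", "RIGHT", "REST"])
        assert np.array_equal(cm, np.eye(3, dtype=int))

    def test_total_count_and_orientation(self):
        cm = confusion_matrix(["LEFT", "LEFT", "REST"], ["RIGHT", "LEFT", "LEFT"])
        assert cm.sum() == 3
        assert cm[0, 1] == 1  # true LEFT predicted RIGHT: row = true
        assert cm[2, 0] == 1

    def test_single_predicted_class_fills_one_column(self):
        cm = confusion_matrix(["LEFT", "RIGHT", "REST"], ["LEFT"] * 3)
        assert cm[:, 0].sum() == 3 and cm[:, 1:].sum() == 0

    def test_accuracy_equals_trace_over_total(self):
        true = ["LEFT", "RIGHT", "REST", "LEFT"]
        pred = ["LEFT", "REST", "REST", "LEFT"]
        cm = confusion_matrix(true, pred)
        assert accuracy_from_confusion(cm) == pytest.approx(np.mean(np.array(true) == np.array(pred)))


class TestRunExperiment:
    @staticmethod
    def perfect_factory(train_set, seed):
        return lambda epochs: epochs.labels.copy()

    @staticmethod
    def majority_factory(train_set, seed):
        return lambda epochs: np.array(["LEFT"] * epochs.n_epochs, dtype=object)

    def test_repeat_count(self, small_dataset):
        rs = run_experiment(small_dataset, "POOLED_RANDOM", None, n_repeats=3,
                            classifier_factory=self.perfect_factory)
        assert len(rs.accuracies) == 3

    def test_perfect_stub_scores_100(self, small_dataset):
        rs = run_experiment(small_dataset, "POOLED_RANDOM", None, n_repeats=2,
                            classifier_factory=self.perfect_factory)
        assert rs.accuracies == [100.0, 100.0]

    def test_majority_stub_on_stratified_split_scores_chance(self, small_dataset):
        # intra-patient split keeps the test side class-balanced exactly
        rs = run_experiment(small_dataset, "INTRA_PATIENT_THEN_POOL", None, n_repeats=2,
                            classifier_factory=self.majority_factory)
        for acc in rs.accuracies:
            assert acc == pytest.approx(100.0 / 3.0, abs=1e-9)

    def test_augmented_run_with_stub(self, small_dataset):
        spec = CascadeSpec([AugmenterSpec("gaussian_noise")], ratio=0.5, seed=0)
        rs = run_experiment(small_dataset, "POOLED_RANDOM", spec, n_repeats=2,
                            classifier_factory=self.perfect_factory)
        assert rs.augmentation == "gaussian_noise"
        assert rs.n_failed == 0

    def test_confusion_row_sums_match_test_counts(self, small_dataset):
        rs = run_experiment(small_dataset, "INTRA_PATIENT_THEN_POOL", None, n_repeats=1,
                            classifier_factory=self.majority_factory)
        cm = rs.confusions[0]
        assert cm.sum() == 6  # 1 test epoch per subject and class, stratified
        assert np.array_equal(cm.sum(axis=1), [2, 2, 2])


def test_compare_to_baseline_family_adjustment():
    rng = np.random.default_rng(0)
    groups = {
        "none": rng.normal(70, 1, 30).tolist(),
        "a": rng.normal(70, 1, 30).tolist(),
        "b": rng.normal(75, 1, 30).tolist(),
    }
    comps = compare_to_baseline(groups, "none", family="demo")
    by_name = {c.name: c for c in comps}
    assert by_name["b"].p_adjusted < 0.01
    assert abs(by_name["b"].cohens_d) > 2
    for c in comps:
        assert c.p_adjusted >= c.p_raw - 1e-15


def test_tidy_and_summary_tables(small_dataset):
    rs = run_experiment(small_dataset, "POOLED_RANDOM", None, n_repeats=2,
                        classifier_factory=TestRunExperiment.perfect_factory)
    results = {("POOLED_RANDOM", "none"): rs}
    tidy = tidy_results(results)
    assert list(tidy.columns) == ["strategy", "augmentation", "repeat", "seed", "accuracy_pct"]
    assert len(tidy) == 2
    summary = summary_table(results)
    assert list(summary.columns) == ["Strategy", "Augmentation", "Mean Acc. [%]", "Median (IQR)"]
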