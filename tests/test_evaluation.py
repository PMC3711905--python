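import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import parkmvpa as pk
import parkmvpa.evaluation as ev
from parkmvpa.evaluation import ConfusionMatrix
from parkmvpa.features import FeatureMatrix
from parkmvpa.probit import ClassifierConfig

from _oracles import metrics_by_hand

# Confusion matrix of the three-class disease contrast reconstructed from the
# reported error pattern: 1 IPD case predicted PSP, 3 PSP cases predicted
# IPD, MSA perfect.
CLASSIFIER_I_CM = np.array([[14, 3, 0], [1, 13, 0], [0, 0, 19]])
CLASSIFIER_I_CLASSES = ("PSP", "IPD", "MSA")


def _label_matrix(n_noise=30, n_per_class=10, signal=5.0, seed=0, shuffle_signal=False):
    """Noise features plus one label-coded column (the leakage probe)."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    labels = ["A"] * n_per_class + ["B"] * n_per_class
    sig = np.where(np.array(labels) == "A", signal, -signal)
    if shuffle_signal:
        sig = sig[rng.permutation(n)]
    values = np.column_stack([sig, rng.standard_normal((n, n_noise))])
    fm = FeatureMatrix(
        values=values,
        subject_ids=tuple(f"s{i}" for i in range(n)),
        channel_index=np.zeros(n_noise + 1, dtype=int),
        voxel_index=np.arange(n_noise + 1),
        mask_name="toy",
    )
    return fm, labels


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        cm = pk.confusion_matrix(["a", "a", "b"], ["a", "a", "b"], ("a", "b"))
        assert np.array_equal(cm.counts, [[2, 0], [0, 1]])

    def test_reported_error_pattern(self):
        true, pred = [], []
        for cls, row in zip(CLASSIFIER_I_CLASSES, CLASSIFIER_I_CM):
            for other, count in zip(CLASSIFIER_I_CLASSES, row):
                true += [cls] * count
                pred += [other] * count
        cm = pk.confusion_matrix(true, pred, CLASSIFIER_I_CLASSES)
        assert np.array_equal(cm.counts, CLASSIFIER_I_CM)
        assert cm.n_total == 50

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            pk.confusion_matrix([], [], ("a",))

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError, match="outside"):
            pk.confusion_matrix(["a"], ["z"], ("a", "b"))


class TestComputeMetrics:
    def test_reported_three_class_metrics(self):
        cm = ConfusionMatrix(CLASSIFIER_I_CM, CLASSIFIER_I_CLASSES)
        met = pk.compute_metrics(cm)
        assert round(met.balanced_accuracy, 3) == 0.917
        assert round(met.overall_predictive_value, 3) == 0.915

    def test_identity_matrix_all_ones(self):
        met = pk.compute_metrics(ConfusionMatrix(np.diag([5, 7, 3]), ("a", "b", "c")))
        assert np.all(met.sensitivity == 1) and np.all(met.predictive_value == 1)
        assert met.balanced_accuracy == met.overall_predictive_value == 1.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_hand_computation(self, seed):
        rng = np.random.default_rng(seed)
        C = rng.integers(0, 9, size=(4, 4))
        C[0, 0] += 1  # guarantee a nonzero matrix
        met = pk.compute_metrics(ConfusionMatrix(C, ("a", "b", "c", "d")))
        sens, pv, ba, opv = metrics_by_hand(C)
        assert np.allclose(met.sensitivity, sens)
        assert np.allclose(met.predictive_value, pv)
        assert np.isclose(met.balanced_accuracy, ba)
        assert np.isclose(met.overall_predictive_value, opv)

    def test_never_predicted_class_gets_zero_pv(self):
        C = np.array([[3, 0], [2, 0]])  # column b is empty
        met = pk.compute_metrics(ConfusionMatrix(C, ("a", "b")))
        assert met.predictive_value[1] == 0.0

    def test_all_zero_matrix_raises(self):
        with pytest.raises(ValueError):
            pk.compute_metrics(ConfusionMatrix(np.zeros((2, 2), int), ("a", "b")))

    def test_balanced_accuracy_invariant_to_class_duplication(self):
        # duplicating every member of one class leaves each sensitivity, and
        # hence the balanced accuracy, exactly unchanged
        C = np.array([[8, 2, 1], [1, 9, 2], [0, 3, 7]])
        dup = C.copy()
        dup[1] *= 2
        a = pk.compute_metrics(ConfusionMatrix(C, ("x", "y", "z")))
        b = pk.compute_metrics(ConfusionMatrix(dup, ("x", "y", "z")))
        assert np.array_equal(a.sensitivity, b.sensitivity)
        assert a.balanced_accuracy == b.balanced_accuracy


class TestChanceLevels:
    @pytest.mark.parametrize("m,expected", [(3, 1 / 3), (4, 0.25), (5, 0.2)])
    def test_aggregate_chance_is_one_over_m(self, m, expected):
        acc, _ = pk.chance_levels(["a", "b"] * m, m)
        assert acc == pytest.approx(expected)

    def test_per_class_chance_is_training_proportion(self):
        labels = ["PSP"] * 17 + ["IPD"] * 14 + ["MSA"] * 19
        _, per = pk.chance_levels(labels, 3)
        assert per == {"PSP": 17 / 50, "IPD": 14 / 50, "MSA": 19 / 50}


class TestPearsonChiSquare:
    def test_reported_sex_table(self):
        # M:F per group: HC 10:9, PSP 7:10, IPD 7:7, MSA 10:9
        table = [[10, 9], [7, 10], [7, 7], [10, 9]]
        stat, dof, p = pk.pearson_chi_square(table)
        assert round(stat, 2) == 0.62
        assert dof == 3
        assert round(p, 2) == 0.89

    def test_independent_table_statistic_zero(self):
        table = np.outer([1, 2, 3], [4, 5])
        stat, _, _ = pk.pearson_chi_square(table)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_2x2(self):
        stat, dof, _ = pk.pearson_chi_square([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert dof == 1

    def test_zero_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            pk.pearson_chi_square([[0, 0], [1, 2]])


class TestBalancedAccuracyInterval:
    def test_single_correct_subject_wide_interval(self):
        cm = ConfusionMatrix(np.array([[1]]), ("only",))
        lo, hi = pk.balanced_accuracy_interval(cm, seed=0)
        assert hi > 0.97 and lo < 0.4  # Beta(2, 1) posterior

    def test_perfect_three_class_lower_bound(self):
        cm = ConfusionMatrix(np.diag([20, 20, 20]), ("a", "b", "c"))
        lo, _ = pk.balanced_accuracy_interval(cm, seed=1)
        assert lo > 0.85

    @pytest.mark.parametrize("seed", range(5))
    def test_interval_contains_point_estimate(self, seed):
        rng = np.random.default_rng(seed)
        C = rng.integers(1, 15, size=(3, 3))
        cm = ConfusionMatrix(C, ("a", "b", "c"))
        ba = pk.compute_metrics(cm).balanced_accuracy
        lo, hi = pk.balanced_accuracy_interval(cm, seed=seed)
        assert lo <= ba <= hi


class TestLOOCrossValidate:
    def test_fold_count_and_determinism(self):
        fm, labels = _label_matrix(n_per_class=4, seed=2)
        cfg = ClassifierConfig(n_classes=2, n_samples=60, n_burnin=30, seed=5)
        a = pk.loo_cross_validate(fm, labels, cfg)
        b = pk.loo_cross_validate(fm, labels, cfg)
        assert a.n_predictions == fm.n_subjects  # one prediction per subject
        assert np.array_equal(a.probabilities, b.probabilities)
        assert np.array_equal(a.confusion.counts.sum(axis=1), [4, 4])

    def test_singleton_class_rejected_before_compute(self):
        fm, labels = _label_matrix(n_per_class=3, seed=0)
        labels = ["A"] * 5 + ["B"]
        cfg = ClassifierConfig(n_classes=2, n_samples=10, n_burnin=5, seed=0)
        with pytest.raises(ValueError, match="at least 2"):
            pk.loo_cross_validate(fm, labels, cfg)

    def test_label_column_leaks_to_perfect_accuracy(self):
        fm, labels = _label_matrix(n_per_class=8, signal=5.0, seed=3)
        cfg = ClassifierConfig(n_classes=2, n_samples=100, n_burnin=50, seed=1)
        res = pk.loo_cross_validate(fm, labels, cfg)
        assert res.metrics.balanced_accuracy >= 0.95

    def test_shuffled_label_column_restores_chance(self):
        fm, labels = _label_matrix(n_per_class=8, signal=5.0, seed=3,
                                   shuffle_signal=True)
        cfg = ClassifierConfig(n_classes=2, n_samples=100, n_burnin=50, seed=1)
        res = pk.loo_cross_validate(fm, labels, cfg)
        assert 0.2 <= res.metrics.balanced_accuracy <= 0.8


class TestPermutationTest:
    def test_p_value_formula(self, monkeypatch):
        # Stub the CV harness: the original (sorted) arrangement scores 1.0,
        # every shuffled arrangement 0.5 -> p = 1/(N+1).
        class Stub:
            def __init__(self, score):
                self.metrics = type("M", (), {"balanced_accuracy": score})()

        def fake_loo(features, labels, cfg, class_names=None, **kw):
            ordered = list(labels) == sorted(labels)
            return Stub(1.0 if ordered else 0.5)

        monkeypatch.setattr(ev, "loo_cross_validate", fake_loo)
        fm, labels = _label_matrix(n_per_class=6)
        res = ev.permutation_test(fm, sorted(labels), lambda r: r.metrics.balanced_accuracy,
                                  19, seed=0)
        assert res.p_value == pytest.approx(1 / 20)

    def test_observed_below_all_gives_p_one(self, monkeypatch):
        class Stub:
            def __init__(self, score):
                self.metrics = type("M", (), {"balanced_accuracy": score})()

        calls = {"n": 0}

        def fake_loo(features, labels, cfg, class_names=None, **kw):
            calls["n"] += 1
            return Stub(0.0 if calls["n"] == 1 else 1.0)

        monkeypatch.setattr(ev, "loo_cross_validate", fake_loo)
        fm, labels = _label_matrix(n_per_class=6)
        res = ev.permutation_test(fm, labels, lambda r: r.metrics.balanced_accuracy,
                                  9, seed=0)
        assert res.p_value == 1.0

    def test_same_seed_same_permutations(self):
        fm, labels = _label_matrix(n_per_class=3, n_noise=5, seed=4)
        cfg = ClassifierConfig(n_classes=2, n_samples=20, n_burnin=10, seed=2)
        a = ev.permutation_test(fm, labels, lambda r: r.metrics.balanced_accuracy,
                                5, seed=9, classifier_config=cfg)
        b = ev.permutation_test(fm, labels, lambda r: r.metrics.balanced_accuracy,
                                5, seed=9, classifier_config=cfg)
        assert np.array_equal(a.permuted, b.permuted)
        assert a.p_value == b.p_value


class TestSignificanceMarkers:
    @pytest.mark.parametrize("p,mark", [(0.005, "*"), (0.03, "#"), (0.07, "+"),
                                        (0.5, "")])
    def test_markers(self, p, mark):
        assert ev.significance_marker(p) == mark


class TestApplyContrast:
    LABELS = ["HC"] * 3 + ["PSP"] * 2 + ["IPD"] * 2 + ["MSA-P"] * 2 + ["MSA-C"] * 2

    def test_contrast_one_drops_hc_and_pools_msa(self):
        keep, mapped, classes = pk.apply_contrast(self.LABELS, "I")
        assert classes == ("PSP", "IPD", "MSA")
        assert len(keep) == 8 and "HC" not in mapped
        assert list(mapped).count("MSA") == 4

    def test_contrast_four_keeps_everything(self):
        keep, mapped, classes = pk.apply_contrast(self.LABELS, "IV")
        assert len(keep) == len(self.LABELS)
        assert set(mapped) == {"HC", "PSP", "IPD", "MSA-P", "MSA-C"}

    def test_unknown_contrast_raises(self):
        with pytest.raises(ValueError, match="contrast"):
            pk.apply_contrast(self.LABELS, "V")
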