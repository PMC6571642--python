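"""One-vs-rest metric formulas, brute-force oracles and cross-validation."""

import math

import numpy as np
import pytest
from scipy import stats

import nystagrid as ng
from nystagrid.evaluation import (
    CLINICAL_VALIDATION_TABLE,
    _binary_roc,
    binomial_vs_nir,
    class_metrics,
    confusion,
    cross_validate,
    f1,
    micro_macro,
    nir,
    roc_auc,
)


def brute_ovr(truth, pred, cls):
    """Oracle: explicit loops over samples for one-vs-rest counts."""
    tp = fp = fn = tn = 0
    for t, p in zip(truth, pred):
        if t == cls and p == cls:
            tp += 1
        elif t != cls and p == cls:
            fp += 1
        elif t == cls and p != cls:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def concordance(y, s):
    """Oracle: pairwise concordance with ties counted one half."""
    pos = [si for si, yi in zip(s, y) if yi]
    neg = [si for si, yi in zip(s, y) if not yi]
    num = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return num / (len(pos) * len(neg))


class TestConfusion:
    def test_diagonal_when_perfect(self):
        cm = confusion(["a", "b", "c"], ["a", "b", "c"])
        assert (cm.counts == np.eye(3)).all()

    def test_direct_tally(self):
        cm = confusion(["A", "A", "B"], ["A", "B", "B"])
        i = {l: k for k, l in enumerate(cm.labels)}
        assert cm.counts[i["A"], i["A"]] == 1
        assert cm.counts[i["A"], i["B"]] == 1
        assert cm.counts[i["B"], i["B"]] == 1

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError):
            confusion(["a"], ["z"], labels=["a", "b"])

    def test_total_preserved(self):
        rng = np.random.default_rng(0)
        t, p = rng.integers(0, 5, 200), rng.integers(0, 5, 200)
        assert confusion(t.tolist(), p.tolist(), labels=range(5)).total == 200


class TestClassMetrics:
    def test_perfect_diagonal(self):
        cm = confusion([0, 1, 2], [0, 1, 2], labels=range(3))
        m = class_metrics(cm, 1)
        assert m["precision"] == m["sensitivity"] == m["specificity"] == m["accuracy"] == 1.0

    def test_hand_computed_counts(self):
        # TP=3, FP=1, FN=2, TN=4 via an explicit 2-class tally
        truth = ["x"] * 5 + ["y"] * 5
        pred = ["x", "x", "x", "y", "y", "x", "y", "y", "y", "y"]
        cm = confusion(truth, pred)
        m = class_metrics(cm, "x")
        assert m["precision"] == pytest.approx(0.75)
        assert m["sensitivity"] == pytest.approx(0.6)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["accuracy"] == pytest.approx(0.7)

    def test_formulas_match_brute_force_on_random_cases(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            n = int(rng.integers(5, 60))
            truth = rng.integers(0, k, n).tolist()
            pred = rng.integers(0, k, n).tolist()
            cm = confusion(truth, pred, labels=range(k))
            for cls in range(k):
                tp, fp, fn, tn = brute_ovr(truth, pred, cls)
                m = class_metrics(cm, cls)
                assert m["precision"] == (tp / (tp + fp) if tp + fp else 0.0)
                assert m["sensitivity"] == (tp / (tp + fn) if tp + fn else 0.0)
                assert m["specificity"] == (tn / (tn + fp) if tn + fp else 0.0)
                assert m["fpr"] == pytest.approx(1 - m["specificity"])

    def test_fpr_specificity_complement(self):
        cm = confusion([0, 0, 1, 1, 1], [0, 1, 1, 0, 1], labels=range(2))
        for cls in range(2):
            m = class_metrics(cm, cls)
            assert m["fpr"] + m["specificity"] == pytest.approx(1.0)


class TestF1:
    @pytest.mark.parametrize(
        "p,s,expected", [(0.837, 0.916, 0.875), (0.775, 0.614, 0.685), (0.707, 0.663, 0.684)]
    )
    def test_clinical_table_rows(self, p, s, expected):
        assert round(f1(p, s), 3) == expected

    def test_identity_when_equal(self):
        assert f1(0.42, 0.42) == pytest.approx(0.42)

    def test_zero_inputs(self):
        assert f1(0.0, 0.0) == 0.0


class TestMicroMacro:
    def test_perfect_balanced(self):
        cm = confusion([0, 1, 2] * 4, [0, 1, 2] * 4, labels=range(3))
        mm = micro_macro(cm)
        assert mm["accuracy"] == mm["micro_f1"] == mm["macro_f1"] == 1.0

    def test_micro_identity_on_random_matrices(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            t = rng.integers(0, 4, 80).tolist()
            p = rng.integers(0, 4, 80).tolist()
            mm = micro_macro(confusion(t, p, labels=range(4)))
            assert mm["micro_precision"] == pytest.approx(mm["accuracy"])
            assert mm["micro_sensitivity"] == pytest.approx(mm["accuracy"])

    def test_macro_f1_of_clinical_table(self):
        assert round(CLINICAL_VALIDATION_TABLE["f1"].mean(), 3) == 0.794


class TestNIR:
    def test_balanced_eight_classes(self):
        assert nir(list(range(8)) * 10) == 0.125

    def test_majority_share(self):
        assert nir(["A", "A", "B"]) == pytest.approx(2 / 3)

    def test_single_class(self):
        assert nir(["A"] * 5) == 1.0


class TestBinomialVsNIR:
    def test_all_correct_at_half(self):
        assert binomial_vs_nir(10, 10, 0.5) == pytest.approx(0.5**10)

    def test_zero_correct_is_one(self):
        assert binomial_vs_nir(0, 25, 0.3) == pytest.approx(1.0)

    def test_matches_direct_summation(self):
        for correct, total, p in [(7, 12, 0.25), (3, 9, 0.5), (14, 20, 0.168)]:
            direct = sum(
                math.comb(total, k) * p**k * (1 - p) ** (total - k)
                for k in range(correct, total + 1)
            )
            assert binomial_vs_nir(correct, total, p) == pytest.approx(direct, rel=1e-12)

    def test_monotone_in_correct(self):
        ps = [binomial_vs_nir(c, 15, 0.2) for c in range(16)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestROC:
    def test_perfect_separation(self):
        y = np.array([True, True, False, False])
        *_, a = _binary_roc(y, np.array([0.9, 0.8, 0.2, 0.1]))
        assert a == 1.0

    def test_constant_scores_chance(self):
        y = np.array([True, False, True, False])
        *_, a = _binary_roc(y, np.full(4, 0.5))
        assert a == pytest.approx(0.5)

    def test_small_example_pairwise(self):
        y = np.array([True, True, True, False])
        *_, a = _binary_roc(y, np.array([0.9, 0.8, 0.2, 0.3]))
        assert a == pytest.approx(2 / 3)

    def test_equals_concordance_on_random_sets(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(6, 40))
            y = rng.integers(0, 2, n).astype(bool)
            if y.all() or not y.any():
                continue
            s = np.round(rng.random(n), 1)  # coarse scores force ties
            *_, a = _binary_roc(y, s)
            assert a == pytest.approx(concordance(y, s), rel=1e-12)

    def test_modes(self):
        rng = np.random.default_rng(4)
        truth = rng.integers(0, 3, 40)
        scores = rng.random((40, 3))
        _, macro = roc_auc(scores, truth, range(3), "macro")
        _, per = roc_auc(scores, truth, range(3), "per_class")
        _, micro = roc_auc(scores, truth, range(3), "micro")
        assert macro == pytest.approx(np.mean(list(per.values())))
        assert 0 <= micro <= 1

    def test_single_class_truth_flagged(self):
        _, areas = roc_auc(np.random.default_rng(5).random((5, 2)), [0] * 5, range(2), "per_class")
        assert math.isnan(areas[1])


class TestCrossValidate:
    @staticmethod
    def _rule_pipeline(xg, yl, tg):
        idx = {c: i for i, c in enumerate(ng.CLASS_LABELS)}
        pred = [idx.get(ng.rule_classify(ng.GridImage(g)), 0) for g in tg]
        return np.array(pred), None

    def test_ten_folds_reported_with_ci(self, synthetic_datasets):
        train_ds, _ = synthetic_datasets
        sub = slice(0, 400)
        rep = cross_validate(
            train_ds.grids[sub], train_ds.labels[sub], ng.CLASS_LABELS,
            self._rule_pipeline, k=10, seed=0,
        )
        assert len(rep.folds) == 10
        assert rep.mean("accuracy") > 0.9  # clean templates are easy
        assert rep.ci95("accuracy") >= 0.0
        # subset of a shuffled balanced set: majority share near 1/8
        assert rep.mean("nir") == pytest.approx(0.125, abs=0.03)

    def test_duplicated_data_zero_ci(self):
        grids = np.repeat(np.stack([t.mean_grid().values for t in ng.default_templates()]), 4, 0)
        labels = np.repeat(np.arange(8), 4)
        rep = cross_validate(grids, labels, ng.CLASS_LABELS, self._rule_pipeline, k=4, seed=1)
        assert rep.ci95("accuracy") == pytest.approx(0.0, abs=1e-12)

    def test_fold_assignment_pure_function_of_seed(self, synthetic_datasets):
        train_ds, _ = synthetic_datasets
        sub = slice(0, 160)
        a = cross_validate(train_ds.grids[sub], train_ds.labels[sub], ng.CLASS_LABELS,
                           self._rule_pipeline, k=4, seed=3)
        b = cross_validate(train_ds.grids[sub], train_ds.labels[sub], ng.CLASS_LABELS,
                           self._rule_pipeline, k=4, seed=3)
        assert a.summary.equals(b.summary)

    def test_insufficient_samples_rejected(self):
        grids = np.zeros((8, 3, 10), np.uint8) + 128
        with pytest.raises(ValueError):
            cross_validate(grids, np.arange(8), ng.CLASS_LABELS, self._rule_pipeline, k=4)


class TestClinicalTableArithmetic:
    def test_macro_row_reproduced(self):
        T = CLINICAL_VALIDATION_TABLE
        assert round(T["precision"].mean(), 3) == 0.798
        assert round(T["sensitivity"].mean(), 3) == 0.808
        assert round(T["specificity"].mean(), 3) == 0.971
        assert round(T["f1"].mean(), 3) == 0.794

    def test_sample_sizes_sum(self):
        assert int(CLINICAL_VALIDATION_TABLE["n"].sum()) == 1005

    def test_f1_column_consistent_with_precision_sensitivity(self):
        T = CLINICAL_VALIDATION_TABLE
        recomputed = [f1(p, s) for p, s in zip(T["precision"], T["sensitivity"])]
        assert np.abs(np.array(recomputed) - T["f1"].to_numpy()).max() <= 0.001
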