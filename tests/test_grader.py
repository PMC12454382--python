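import numpy as np
import pytest

from locsgrade.grader import (AnnConfig, AnnModel, GradeLabel, evaluate,
                              predict_grade, split_dataset, train_ann)
from locsgrade.imgcore import DataError


class TestGradeLabel:
    @pytest.mark.parametrize("ctype,lo,hi", [("NO", 0, 6), ("NC", 0, 6),
                                             ("C", 0, 5), ("P", 0, 5)])
    def test_ranges(self, ctype, lo, hi):
        GradeLabel(ctype, lo)
        GradeLabel(ctype, hi)
        with pytest.raises(ValueError):
            GradeLabel(ctype, hi + 1)
        with pytest.raises(ValueError):
            GradeLabel(ctype, -1)

    def test_unknown_type(self):
        with pytest.raises(ValueError):
            GradeLabel("X", 0)


class TestSplitDataset:
    def test_700_300(self):
        train, test = split_dataset(list(range(1000)), seed=0)
        assert (len(train), len(test)) == (700, 300)
        assert set(train) | set(test) == set(range(1000))
        assert not set(train) & set(test)

    def test_small_n(self):
        train, test = split_dataset(list(range(10)), seed=1)
        assert (len(train), len(test)) == (7, 3)
        assert sorted(train + test) == list(range(10))

    def test_stratified_proportions(self):
        items = [("A", i) for i in range(50)] + [("B", i) for i in range(50)]
        train, test = split_dataset(items, seed=2, stratify_key=lambda x: x[0])
        for cls in ("A", "B"):
            n_tr = sum(1 for it in train if it[0] == cls)
            n_te = sum(1 for it in test if it[0] == cls)
            assert abs(n_tr - 35) <= 1 and abs(n_te - 15) <= 1

    def test_singleton_class_goes_to_train(self):
        items = [("A", i) for i in range(9)] + [("B", 0)]
        with pytest.warns(UserWarning, match="singleton"):
            train, test = split_dataset(items, seed=0,
                                        stratify_key=lambda x: x[0])
        assert ("B", 0) in train

    def test_deterministic(self):
        a = split_dataset(list(range(100)), seed=9)
        b = split_dataset(list(range(100)), seed=9)
        assert a == b


def _monotone_dataset(n_per_grade=30, ctype="NO", seed=0):
    """1-D feature strictly separable by grade."""
    rng = np.random.default_rng(seed)
    X, labels = [], []
    lo, hi = (0, 6) if ctype in ("NO", "NC") else (0, 5)
    for g in range(lo, hi + 1):
        X.append(g / hi + rng.normal(0, 0.01, (n_per_grade, 1)))
        labels += [GradeLabel(ctype, g)] * n_per_grade
    return np.vstack(X), labels


class TestTrainAnn:
    def test_constant_labels_predict_constant(self):
        rng = np.random.default_rng(0)
        X = rng.random((40, 3))
        labels = [GradeLabel("C", 2)] * 40
        model = train_ann(X, labels, AnnConfig(epochs=3000))
        for x in X[:10]:
            assert predict_grade(model, x)[0].grade == 2

    def test_monotone_feature_high_training_accuracy(self):
        X, labels = _monotone_dataset()
        model = train_ann(X, labels)
        acc = np.mean([predict_grade(model, x)[0].grade == lab.grade
                       for x, lab in zip(X, labels)])
        assert acc >= 0.95

    def test_same_seed_identical_weights(self):
        X, labels = _monotone_dataset(n_per_grade=5)
        cfg = AnnConfig(epochs=200, seed=7)
        m1, m2 = train_ann(X, labels, cfg), train_ann(X, labels, cfg)
        assert (m1.W1 == m2.W1).all() and (m1.W2 == m2.W2).all()
        assert (m1.b1 == m2.b1).all() and (m1.b2 == m2.b2).all()

    def test_non_finite_feature_names_row(self):
        X = np.ones((5, 2))
        X[3, 1] = np.nan
        with pytest.raises(DataError, match="row 3"):
            train_ann(X, [GradeLabel("P", 1)] * 5)

    def test_mixed_types_rejected(self):
        X = np.ones((2, 1))
        with pytest.raises(ValueError, match="mix"):
            train_ann(X, [GradeLabel("NO", 1), GradeLabel("NC", 1)])

    def test_json_round_trip(self):
        X, labels = _monotone_dataset(n_per_grade=4)
        model = train_ann(X, labels, AnnConfig(epochs=100))
        back = AnnModel.from_json(model.to_json())
        x = np.array([0.37])
        assert back.raw_output(x) == pytest.approx(model.raw_output(x))


class TestPredictGrade:
    def _dummy(self, raw, lo=0, hi=6):
        """Model whose raw output is forced via the output bias."""
        logit = np.log(raw / (1 - raw))
        return AnnModel("NO" if hi == 6 else "C", 1, 1,
                        W1=np.zeros((1, 1)), b1=np.zeros(1),
                        W2=np.zeros((1, 1)), b2=np.array([logit]),
                        feat_mean=np.zeros(1), feat_scale=np.ones(1),
                        min_grade=lo, max_grade=hi, seed=0, epochs=0,
                        learning_rate=0.0, final_loss=0.0)

    @pytest.mark.parametrize("raw,expected", [
        (0.5, 3),          # midpoint of 0..6
        (0.58, 3),         # 0.58*6 = 3.48 rounds down
        (0.59, 4),         # 3.54 rounds up
    ])
    def test_rescale_round(self, raw, expected):
        label, r = predict_grade(self._dummy(raw), np.array([0.0]))
        assert label.grade == expected
        assert r == pytest.approx(raw, abs=1e-9)

    def test_extremes_clip(self):
        assert predict_grade(self._dummy(1e-9), np.array([0.0]))[0].grade == 0
        assert predict_grade(self._dummy(1 - 1e-9),
                             np.array([0.0]))[0].grade == 6

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            predict_grade(self._dummy(0.5), np.array([0.0, 1.0]))


class TestEvaluate:
    def test_perfect_predictions(self):
        rng = np.random.default_rng(1)
        grades = rng.integers(0, 6, 60)
        truth = [GradeLabel("C", int(g)) for g in grades]
        raws = grades / 5.0
        rep = evaluate(truth, truth, raws)
        assert rep.accuracy == 1.0
        present = set(int(g) for g in grades)
        assert len(present) > 1
        for g in present:
            assert rep.f1[g] == 1.0
            assert rep.auc[g] == 1.0
        assert rep.macro_auc == 1.0

    def test_hand_computed_binary_confusion(self):
        # TP=8, FP=1, FN=2 for grade 1 against grade 0
        truth = [GradeLabel("P", 1)] * 10 + [GradeLabel("P", 0)] * 10
        pred = ([GradeLabel("P", 1)] * 8 + [GradeLabel("P", 0)] * 2
                + [GradeLabel("P", 1)] * 1 + [GradeLabel("P", 0)] * 9)
        rep = evaluate(truth, pred)
        assert rep.precision[1] == pytest.approx(8 / 9)
        assert rep.recall[1] == pytest.approx(0.8)
        f1 = 2 * (8 / 9) * 0.8 / (8 / 9 + 0.8)
        assert rep.f1[1] == pytest.approx(f1)
        assert rep.accuracy == pytest.approx(17 / 20)
        assert rep.confusion.sum() == 20
        # row sums = true class counts
        assert rep.confusion.sum(axis=1)[0] == 10
        assert rep.confusion.sum(axis=1)[1] == 10

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(123)
        n = 2000
        grades = rng.integers(0, 7, n)
        truth = [GradeLabel("NO", int(g)) for g in grades]
        pred = [GradeLabel("NO", int(g)) for g in rng.integers(0, 7, n)]
        raws = rng.random(n)
        rep = evaluate(truth, pred, raws)
        for g, a in rep.auc.items():
            assert 0.45 <= a <= 0.55

    def test_auc_invariant_under_monotone_transform_extreme_classes(self):
        # for the lowest and highest grade the one-vs-rest score is a
        # monotone function of the raw output, so AUC must not change
        rng = np.random.default_rng(5)
        n = 300
        grades = rng.integers(0, 6, n)
        truth = [GradeLabel("C", int(g)) for g in grades]
        pred = truth
        raws = rng.random(n)
        rep1 = evaluate(truth, pred, raws)
        rep2 = evaluate(truth, pred, np.tanh(3 * raws))  # strictly monotone
        # transform preserves order of |raw - 0| and |raw - 1| scores only
        # approximately for interior classes; extremes are exact
        assert rep2.auc[0] == pytest.approx(rep1.auc[0])

    def test_accuracy_equals_weighted_recall(self):
        rng = np.random.default_rng(8)
        truth = [GradeLabel("P", int(g)) for g in rng.integers(0, 6, 200)]
        pred = [GradeLabel("P", int(g)) for g in rng.integers(0, 6, 200)]
        rep = evaluate(truth, pred)
        weights = rep.confusion.sum(axis=1) / rep.n
        weighted_recall = sum(w * rep.recall[g]
                              for w, g in zip(weights, rep.grades))
        assert rep.accuracy == pytest.approx(weighted_recall)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate([GradeLabel("C", 1)], [])

    def test_text_table_mentions_all_grades(self):
        truth = [GradeLabel("C", g % 6) for g in range(30)]
        rep = evaluate(truth, truth, np.linspace(0, 1, 30))
        table = rep.text_table()
        for g in range(6):
            assert f"\n{g:>6} " in table or table.startswith(f"{g:>6} ")
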