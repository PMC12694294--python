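import numpy as np
import pandas as pd
import pytest

from fallfusion.errors import DataError, UsageError
from fallfusion.evaluate import (
    ConfusionMatrix,
    aggregate,
    anova_tukey,
    cross_dataset_eval,
    cross_validate,
    micro_scores,
    prf1,
    roc_auc,
)
from fallfusion.models import ModelSpec


def auc_pair_counting(scores, labels):
    """Concordant-pair fraction with 1/2 credit for ties (binary AUC oracle)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def table_from(X, labels):
    df = pd.DataFrame(X, columns=[f"avm_f{i}" for i in range(X.shape[1])])
    df.insert(0, "label", labels)
    df.insert(0, "recording_id", [f"r{i}" for i in range(len(df))])
    return df


class TestPRF1:
    def test_perfect_predictions(self):
        cm = ConfusionMatrix.from_labels(["a", "b", "a"], ["a", "b", "a"])
        for v in prf1(cm).values():
            assert v["precision"] == v["recall"] == v["f1"] == 1.0

    def test_hand_computed_cell(self):
        # class "a": TP=1, FP=1, FN=0 -> P=0.5, R=1, F1=2/3
        cm = ConfusionMatrix.from_labels(["a", "b"], ["a", "a"])
        m = prf1(cm)["a"]
        assert m["precision"] == pytest.approx(0.5)
        assert m["recall"] == pytest.approx(1.0)
        assert m["f1"] == pytest.approx(2 / 3)

    def test_absent_class_degenerate_convention(self):
        cm = ConfusionMatrix.from_labels(["a", "a"], ["a", "a"], classes=["a", "ghost"])
        m = prf1(cm)["ghost"]
        assert m["precision"] == m["recall"] == m["f1"] == 0.0
        assert m["degenerate"]

    def test_three_class_hand_fixture(self):
        cm = ConfusionMatrix(classes=["a", "b", "c"],
                             table=np.array([[5, 1, 0], [2, 3, 1], [0, 0, 4]]))
        m = prf1(cm)
        assert m["a"]["precision"] == pytest.approx(5 / 7)
        assert m["a"]["recall"] == pytest.approx(5 / 6)
        assert m["b"]["precision"] == pytest.approx(3 / 4)
        assert m["c"]["recall"] == pytest.approx(1.0)


class TestAggregate:
    def test_equal_supports_macro_equals_weighted(self):
        per = {"a": {"f1": 0.8, "precision": 1, "recall": 1, "support": 10},
               "b": {"f1": 0.4, "precision": 1, "recall": 1, "support": 10}}
        agg = aggregate(per)
        assert agg["f1"]["macro"] == pytest.approx(0.6)
        assert agg["f1"]["weighted"] == pytest.approx(agg["f1"]["macro"])

    def test_imbalanced_hand_computation(self):
        per = {"a": {"f1": 1.0, "precision": 1, "recall": 1, "support": 99},
               "b": {"f1": 0.0, "precision": 0, "recall": 0, "support": 1}}
        agg = aggregate(per)
        assert agg["f1"]["macro"] == pytest.approx(0.5)
        assert agg["f1"]["weighted"] == pytest.approx(0.99)

    def test_single_class(self):
        per = {"a": {"f1": 0.7, "precision": 0.7, "recall": 0.7, "support": 5}}
        agg = aggregate(per)
        assert agg["f1"]["macro"] == agg["f1"]["weighted"] == pytest.approx(0.7)


class TestMicroIdentity:
    @pytest.mark.parametrize("seed", range(5))
    def test_micro_precision_equals_recall_equals_accuracy(self, seed):
        rng = np.random.default_rng(seed)
        y_true = rng.choice(list("abc"), 60)
        y_pred = rng.choice(list("abc"), 60)
        cm = ConfusionMatrix.from_labels(y_true, y_pred, classes=list("abc"))
        mic = micro_scores(cm)
        acc = float(np.mean(y_true == y_pred))
        assert mic["precision"] == mic["recall"] == mic["accuracy"] == pytest.approx(acc)


class TestCrossValidate:
    def test_separable_data_perfect_cv(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 1, (40, 3)), rng.normal(12, 1, (40, 3))])
        table = table_from(X, ["sitting"] * 40 + ["falling"] * 40)
        cv = cross_validate(ModelSpec("LR"), table, table["label"].to_numpy(), k=5, seed=0)
        assert cv.mean("accuracy") == 1.0

    def test_permuted_labels_score_at_chance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(250, 4))
        labels = np.repeat(["a", "b", "c", "d", "e"], 50)
        table = table_from(X, rng.permutation(labels))
        cv = cross_validate(ModelSpec("LR"), table, table["label"].to_numpy(), k=5, seed=1)
        assert cv.mean("accuracy") == pytest.approx(0.2, abs=0.08)

    def test_every_row_tested_exactly_once(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        table = table_from(X, ["sitting"] * 20 + ["falling"] * 20)
        cv = cross_validate(ModelSpec("LR"), table, table["label"].to_numpy(), k=5, seed=0)
        assert len(cv.oof_pred) == 40
        assert set(cv.oof_pred) <= {"sitting", "falling"}
        assert not np.any(pd.isna(cv.oof_pred))

    def test_small_class_advises_reducing_k(self):
        X = np.zeros((12, 2))
        table = table_from(X, ["sitting"] * 9 + ["falling"] * 3)
        with pytest.raises(DataError, match="reduce k"):
            cross_validate(ModelSpec("LR"), table, table["label"].to_numpy(), k=5)


class TestRocAuc:
    def test_perfect_ranking(self):
        labels = np.array(["a"] * 5 + ["b"] * 5)
        proba = np.column_stack([np.r_[np.ones(5), np.zeros(5)],
                                 np.r_[np.zeros(5), np.ones(5)]])
        rep = roc_auc(proba, labels, ["a", "b"])
        assert rep.per_class_auc == {"a": 1.0, "b": 1.0}
        assert rep.micro_auc == 1.0 and rep.macro_auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(7)
        labels = rng.choice(["a", "b"], 400)
        p = rng.uniform(size=400)
        rep = roc_auc(np.column_stack([p, 1 - p]), labels, ["a", "b"])
        assert rep.macro_auc == pytest.approx(0.5, abs=0.08)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        labels = rng.choice(["neg", "pos"], n, p=[0.6, 0.4])
        scores = np.round(rng.uniform(size=n), 1)  # coarse grid forces ties
        if len(set(labels)) < 2:
            pytest.skip("degenerate draw")
        proba = np.column_stack([1 - scores, scores])
        rep = roc_auc(proba, labels, ["neg", "pos"])
        oracle = auc_pair_counting(scores, (labels == "pos").astype(int))
        assert rep.per_class_auc["pos"] == pytest.approx(oracle, abs=1e-12)

    def test_absent_class_excluded_with_flag(self):
        labels = np.array(["a", "a", "b", "b"])
        proba = np.full((4, 3), 1 / 3)
        rep = roc_auc(proba, labels, ["a", "b", "ghost"])
        assert rep.excluded == ["ghost"]
        assert "ghost" not in rep.per_class_auc


class TestAnovaTukey:
    def test_identical_scores_flag_nothing(self):
        scores = {"RF": [0.9, 0.8, 0.85], "SVM": [0.9, 0.8, 0.85], "LR": [0.9, 0.8, 0.85]}
        rep = anova_tukey(scores)
        assert rep.significant_pairs == []

    def test_constructed_separation_detected(self):
        rng = np.random.default_rng(0)
        scores = {"good": 0.9 + rng.normal(0, 0.01, 5), "bad": 0.5 + rng.normal(0, 0.01, 5)}
        rep = anova_tukey(scores)
        assert rep.p_value < 0.001
        assert ("bad", "good") in rep.significant_pairs or ("good", "bad") in rep.significant_pairs

    def test_single_classifier_rejected(self):
        with pytest.raises(UsageError):
            anova_tukey({"RF": [0.9, 0.8]})

    def test_all_constant_groups_degenerate(self):
        rep = anova_tukey({"a": [0.8, 0.8], "b": [0.8, 0.8]})
        assert rep.degenerate and rep.significant_pairs == []


class TestCrossDataset:
    def test_train_on_self_is_degenerate_check(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(0, 1, (30, 3)), rng.normal(10, 1, (30, 3))])
        table = table_from(X, ["sitting"] * 30 + ["falling"] * 30)
        df = cross_dataset_eval([ModelSpec("LR", task="binary")], table, table)
        both = df[df["model"] == "LR"]
        assert both["macro_f1"].nunique() == 1  # A->B and B->A identical when A = B
        assert both["macro_f1"].iloc[0] == 1.0

    def test_feature_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 3))
        a = table_from(X, ["sitting"] * 10 + ["falling"] * 10)
        b = a.rename(columns={"avm_f0": "avm_other"})
        with pytest.raises(UsageError):
            cross_dataset_eval([ModelSpec("LR", task="binary")], a, b)
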