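"""Evaluation: confusion-based metrics, cross-validation, ROC, cross-dataset
generalization, and ANOVA + Tukey HSD model comparison.

Precision, recall and F1 follow the one-vs-rest definitions
P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R), with the 0/0 case
defined as 0 and flagged. Aggregation offers both the support-weighted
mean (overall performance) and the unweighted macro mean (each class
counts equally — the right lens for heavily imbalanced activity mixes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .config import RunConfig
from .errors import DataError, UsageError
from .models import (
    EnsembleSpec,
    ModelSpec,
    Prediction,
    majority_vote,
    make_task_labels,
    train_model,
)
from .select import feature_columns, fit_scaler


@dataclass
class ConfusionMatrix:
    """K x K confusion table with one-vs-rest views per class."""

    classes: list[str]
    table: np.ndarray  # rows = true, cols = predicted

    @classmethod
    def from_labels(cls, y_true, y_pred, classes: list[str] | None = None) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=object).astype(str)
        y_pred = np.asarray(y_pred, dtype=object).astype(str)
        if classes is None:
            classes = sorted(set(y_true) | set(y_pred))
        idx = {c: i for i, c in enumerate(classes)}
        table = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            table[idx[t], idx[p]] += 1
        return cls(classes=list(classes), table=table)

    def one_vs_rest(self, cls_name: str) -> dict[str, int]:
        i = self.classes.index(cls_name)
        tp = int(self.table[i, i])
        fp = int(self.table[:, i].sum() - tp)
        fn = int(self.table[i, :].sum() - tp)
        tn = int(self.table.sum() - tp - fp - fn)
        return {"TP": tp, "FP": fp, "FN": fn, "TN": tn}

    @property
    def n(self) -> int:
        return int(self.table.sum())


def prf1(cm: ConfusionMatrix) -> dict[str, dict[str, float]]:
    """Per-class precision/recall/F1 with supports; 0/0 -> 0 (flagged)."""
    if cm.n == 0:
        raise DataError("empty confusion matrix")
    out: dict[str, dict[str, float]] = {}
    for c in cm.classes:
        v = cm.one_vs_rest(c)
        tp, fp, fn = v["TP"], v["FP"], v["FN"]
        degenerate = False
        if tp + fp == 0:
            precision, degenerate = 0.0, True
        else:
            precision = tp / (tp + fp)
        if tp + fn == 0:
            recall, degenerate = 0.0, True
        else:
            recall = tp / (tp + fn)
        if precision + recall == 0:
            f1 = 0.0
            degenerate = degenerate or (tp + fp + fn > 0)
        else:
            f1 = 2 * precision * recall / (precision + recall)
        out[c] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": tp + fn,
            "degenerate": degenerate,
        }
    return out


def aggregate(per_class: dict[str, dict[str, float]],
              metrics: tuple[str, ...] = ("precision", "recall", "f1")) -> dict[str, dict[str, float]]:
    """Macro (unweighted) and weighted (support-weighted) class means."""
    supports = np.array([v["support"] for v in per_class.values()], dtype=float)
    if supports.sum() <= 0:
        raise DataError("total support must be positive")
    out = {}
    for m in metrics:
        vals = np.array([v[m] for v in per_class.values()], dtype=float)
        out[m] = {
            "macro": float(vals.mean()),
            "weighted": float(np.average(vals, weights=supports)),
        }
    return out


def micro_scores(cm: ConfusionMatrix) -> dict[str, float]:
    """Micro-averaged precision/recall (= accuracy for single-label tasks)."""
    tp = int(np.trace(cm.table))
    return {"precision": tp / cm.n, "recall": tp / cm.n, "accuracy": tp / cm.n}


# ---------------------------------------------------------------- CV ----


@dataclass
class CVResult:
    """Per-fold scores plus pooled out-of-fold predictions."""

    fold_scores: pd.DataFrame  # columns: fold, accuracy, macro_f1, weighted_f1
    oof_true: np.ndarray
    oof_pred: np.ndarray
    oof_proba: np.ndarray
    classes: list[str]

    def mean(self, metric: str) -> float:
        return float(self.fold_scores[metric].mean())

    def std(self, metric: str) -> float:
        return float(self.fold_scores[metric].std(ddof=1))


def _fit_predict(spec: ModelSpec | EnsembleSpec, X_tr, y_tr, X_te) -> Prediction:
    if isinstance(spec, EnsembleSpec):
        members = [train_model(m, X_tr, y_tr) for m in spec.member_specs()]
        return majority_vote([m.predict(X_te) for m in members])
    return train_model(spec, X_tr, y_tr).predict(X_te)


def cross_validate(spec: ModelSpec | EnsembleSpec, table: pd.DataFrame, labels: np.ndarray,
                   k: int = 5, seed: int = 0) -> CVResult:
    """Stratified k-fold CV with the scaler re-fit inside every fold.

    Fold assignment partitions the rows: every recording is tested
    exactly once, and the pooled out-of-fold predictions are returned
    alongside per-fold accuracy and F1 scores.
    """
    labels = np.asarray(labels, dtype=object).astype(str)
    counts = pd.Series(labels).value_counts()
    if (counts < k).any():
        small = counts[counts < k]
        raise DataError(
            f"class(es) {dict(small)} have fewer than k={k} members; reduce k"
        )
    feats = feature_columns(table)
    X = table[feats].to_numpy(dtype=float)
    classes = sorted(set(labels))
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    oof_pred = np.empty(len(labels), dtype=object)
    oof_proba = np.zeros((len(labels), len(classes)))
    for fold, (tr, te) in enumerate(skf.split(X, labels)):
        scaler = fit_scaler(table.iloc[tr])
        X_tr = scaler.transform(table.iloc[tr])[feats].to_numpy(dtype=float)
        X_te = scaler.transform(table.iloc[te])[feats].to_numpy(dtype=float)
        pred = _fit_predict(spec, X_tr, labels[tr], X_te)
        cm = ConfusionMatrix.from_labels(labels[te], pred.labels, classes)
        agg = aggregate(prf1(cm))
        rows.append({
            "fold": fold,
            "accuracy": micro_scores(cm)["accuracy"],
            "macro_f1": agg["f1"]["macro"],
            "weighted_f1": agg["f1"]["weighted"],
        })
        oof_pred[te] = pred.labels
        # member class sets can miss classes absent from a training fold
        for j, c in enumerate(pred.classes):
            oof_proba[te, classes.index(c)] = pred.proba[:, j]
    return CVResult(
        fold_scores=pd.DataFrame(rows),
        oof_true=labels,
        oof_pred=oof_pred.astype(str),
        oof_proba=oof_proba,
        classes=classes,
    )


# --------------------------------------------------------------- ROC ----


@dataclass
class RocReport:
    per_class_auc: dict[str, float]
    micro_auc: float
    macro_auc: float
    curves: dict[str, pd.DataFrame]  # class -> (fpr, tpr, threshold)
    excluded: list[str] = field(default_factory=list)


def roc_auc(proba: np.ndarray, labels: np.ndarray, classes: list[str]) -> RocReport:
    """One-vs-rest ROC per class plus micro- and macro-averaged AUC.

    Micro pools all (class, recording) decisions; macro is the
    unweighted mean over classes present in the labels. Classes absent
    from the test labels have undefined AUC and are excluded from the
    macro with a flag.
    """
    labels = np.asarray(labels, dtype=object).astype(str)
    proba = np.asarray(proba, float)
    if proba.shape != (len(labels), len(classes)) or len(classes) < 2:
        raise UsageError("probability matrix must be n x K with K >= 2")
    per_class: dict[str, float] = {}
    curves: dict[str, pd.DataFrame] = {}
    excluded: list[str] = []
    onehot = np.zeros_like(proba)
    for j, c in enumerate(classes):
        onehot[:, j] = (labels == c).astype(float)
        if onehot[:, j].sum() in (0, len(labels)):
            excluded.append(c)
            continue
        fpr, tpr, thr = roc_curve(onehot[:, j], proba[:, j])
        per_class[c] = float(auc(fpr, tpr))
        curves[c] = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    if not per_class:
        raise DataError("no class has both positive and negative test examples")
    fpr_mi, tpr_mi, _ = roc_curve(onehot.ravel(), proba.ravel())
    return RocReport(
        per_class_auc=per_class,
        micro_auc=float(auc(fpr_mi, tpr_mi)),
        macro_auc=float(np.mean(list(per_class.values()))),
        curves=curves,
        excluded=excluded,
    )


# ----------------------------------------------------- cross-dataset ----


def cross_dataset_eval(specs: list[ModelSpec | EnsembleSpec], table_a: pd.DataFrame,
                       table_b: pd.DataFrame, task: str = "binary") -> pd.DataFrame:
    """Train-on-A/test-on-B and the reverse, per classifier.

    The scaler is fit on the training dataset only. Returns one row per
    (spec, direction) with weighted F1, macro F1 and macro ROC-AUC, plus
    mean +/- sd rows across the two directions.
    """
    fa, fb = feature_columns(table_a), feature_columns(table_b)
    if fa != fb:
        raise UsageError("feature sets of the two tables differ")
    rows = []
    for spec in specs:
        name = spec.family if isinstance(spec, ModelSpec) else "MV"
        for direction, (tr_tab, te_tab) in {
            "A->B": (table_a, table_b),
            "B->A": (table_b, table_a),
        }.items():
            y_tr = make_task_labels(tr_tab["label"], task)
            y_te = make_task_labels(te_tab["label"], task)
            scaler = fit_scaler(tr_tab)
            X_tr = scaler.transform(tr_tab)[fa].to_numpy(dtype=float)
            X_te = scaler.transform(te_tab)[fa].to_numpy(dtype=float)
            pred = _fit_predict(spec, X_tr, y_tr, X_te)
            cm = ConfusionMatrix.from_labels(y_te, pred.labels, sorted(set(y_tr) | set(y_te)))
            agg = aggregate(prf1(cm))
            roc = roc_auc(pred.proba, y_te, pred.classes)
            rows.append({
                "model": name,
                "direction": direction,
                "weighted_f1": agg["f1"]["weighted"],
                "macro_f1": agg["f1"]["macro"],
                "roc_auc": roc.macro_auc,
            })
    df = pd.DataFrame(rows)
    summary = df.groupby("model", sort=False).agg(
        weighted_f1_mean=("weighted_f1", "mean"), weighted_f1_sd=("weighted_f1", "std"),
        macro_f1_mean=("macro_f1", "mean"), macro_f1_sd=("macro_f1", "std"),
        roc_auc_mean=("roc_auc", "mean"),
    ).reset_index()
    return df.merge(summary, on="model")


# ------------------------------------------------------ ANOVA + Tukey ----


@dataclass
class StatTestReport:
    f_statistic: float
    p_value: float
    alpha: float
    significant_pairs: list[tuple[str, str]]
    tukey_table: pd.DataFrame | None
    degenerate: bool = False


def anova_tukey(per_fold_scores: dict[str, np.ndarray | list], alpha: float = 0.05) -> StatTestReport:
    """One-way ANOVA over per-fold scores by classifier, Tukey HSD post hoc.

    Tukey pairwise comparisons run only when the ANOVA is significant at
    ``alpha``. If every group is constant the F statistic is undefined;
    the report is flagged degenerate with no significant pairs.
    """
    if len(per_fold_scores) < 2:
        raise UsageError("need at least 2 classifiers to compare")
    groups = {k: np.asarray(v, float) for k, v in per_fold_scores.items()}
    sizes = {len(v) for v in groups.values()}
    if len(sizes) != 1 or min(sizes) < 2:
        raise UsageError("all classifiers need the same number (>= 2) of fold scores")
    values = list(groups.values())
    if all(np.ptp(v) == 0.0 for v in values):
        # zero within-group variance everywhere: F is undefined (0/0) when the
        # means coincide, infinite when they differ — flag rather than test
        names = list(groups)
        pairs = [
            (a, b)
            for i, a in enumerate(names)
            for b in names[i + 1:]
            if groups[a][0] != groups[b][0]
        ]
        p = 1.0 if not pairs else 0.0
        return StatTestReport(float("nan"), p, alpha, pairs, None, degenerate=True)
    f_stat, p = sps.f_oneway(*values)
    if np.isnan(f_stat):
        return StatTestReport(float("nan"), 1.0, alpha, [], None, degenerate=True)
    pairs: list[tuple[str, str]] = []
    tukey_df = None
    if p <= alpha:
        data = np.concatenate(values)
        labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
        res = pairwise_tukeyhsd(data, labels, alpha=alpha)
        tukey_df = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        for row in tukey_df.itertuples(index=False):
            if bool(row.reject):
                pairs.append((str(row.group1), str(row.group2)))
    return StatTestReport(float(f_stat), float(p), alpha, pairs, tukey_df)


# ------------------------------------------------------------ holdout ----


def holdout_report(spec: ModelSpec | EnsembleSpec, table: pd.DataFrame, task: str,
                   cfg: RunConfig | None = None) -> dict:
    """Per-class P/R/F1, aggregates and ROC on a stratified holdout split."""
    cfg = cfg or RunConfig()
    y = make_task_labels(table["label"], task)
    idx = np.arange(len(table))
    tr, te = train_test_split(
        idx, test_size=cfg.holdout_fraction, stratify=y, random_state=cfg.seed
    )
    feats = feature_columns(table)
    scaler = fit_scaler(table.iloc[tr])
    X_tr = scaler.transform(table.iloc[tr])[feats].to_numpy(dtype=float)
    X_te = scaler.transform(table.iloc[te])[feats].to_numpy(dtype=float)
    pred = _fit_predict(spec, X_tr, y[tr], X_te)
    cm = ConfusionMatrix.from_labels(y[te], pred.labels, sorted(set(y)))
    per_class = prf1(cm)
    roc = roc_auc(pred.proba, y[te], pred.classes)
    return {
        "task": task,
        "per_class": per_class,
        "aggregate": aggregate(per_class),
        "accuracy": micro_scores(cm)["accuracy"],
        "roc_auc": {"per_class": roc.per_class_auc, "micro": roc.micro_auc,
                    "macro": roc.macro_auc, "excluded": roc.excluded},
        "confusion": {"classes": cm.classes, "table": cm.table.tolist()},
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
    }
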