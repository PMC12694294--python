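"""Benchmark orchestration: arms x tasks x classifier families.

Mirrors the comparison design of the study this pipeline supports: three
sensor arms (accelerometer-only, altimeter-only, fused), two tasks
(binary ADL-vs-FALL and five-class), five methods (RF/SVM/XGB/LR and the
majority voter), with 5-fold cross-validated scores and an ANOVA + Tukey
comparison of the families per arm and task.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RunConfig
from .evaluate import CVResult, anova_tukey, cross_validate, roc_auc
from .io import META_COLUMNS
from .models import FAMILIES, EnsembleSpec, ModelSpec, make_task_labels
from .select import canonical_preset

ARMS = ("fusion", "avm", "alt")
TASKS = ("binary", "multiclass")
METHODS = FAMILIES + ("MV",)


def arm_table(table: pd.DataFrame, arm: str) -> pd.DataFrame:
    """Subset a full feature table to one sensor arm's preset columns."""
    cols = [c for c in META_COLUMNS if c in table.columns]
    return table[cols + canonical_preset(arm)]


def method_spec(method: str, task: str, seed: int, cfg: RunConfig) -> ModelSpec | EnsembleSpec:
    if method == "MV":
        return EnsembleSpec(task=task, seed=seed, params=cfg.hyperparams)
    return ModelSpec(method, dict(cfg.hyperparams.get(method, {})), task=task, seed=seed)


def run_benchmark(table: pd.DataFrame, cfg: RunConfig | None = None,
                  arms: tuple[str, ...] = ARMS, tasks: tuple[str, ...] = TASKS,
                  methods: tuple[str, ...] = METHODS) -> dict:
    """Cross-validated scores for every (arm, task, method) cell.

    Returns a nested report with per-fold scores, mean +/- sd, pooled
    out-of-fold ROC-AUC, and per-(arm, task) ANOVA/Tukey across methods
    on fold macro-F1.
    """
    cfg = cfg or RunConfig()
    report: dict = {"seed": cfg.seed, "config_hash": cfg.config_hash(), "cells": {},
                    "anova": {}}
    for arm in arms:
        sub = arm_table(table, arm)
        for task in tasks:
            labels = make_task_labels(sub["label"], task)
            fold_scores: dict[str, np.ndarray] = {}
            for method in methods:
                spec = method_spec(method, task, cfg.seed, cfg)
                cv: CVResult = cross_validate(spec, sub, labels, k=cfg.cv_folds, seed=cfg.seed)
                roc = roc_auc(cv.oof_proba, cv.oof_true, cv.classes)
                report["cells"][f"{arm}/{task}/{method}"] = {
                    "cv_accuracy_mean": cv.mean("accuracy"),
                    "cv_accuracy_sd": cv.std("accuracy"),
                    "macro_f1_mean": cv.mean("macro_f1"),
                    "macro_f1_sd": cv.std("macro_f1"),
                    "weighted_f1_mean": cv.mean("weighted_f1"),
                    "weighted_f1_sd": cv.std("weighted_f1"),
                    "roc_auc_micro": roc.micro_auc,
                    "roc_auc_macro": roc.macro_auc,
                    "folds": cv.fold_scores.to_dict(orient="records"),
                }
                fold_scores[method] = cv.fold_scores["macro_f1"].to_numpy()
            if len(fold_scores) >= 2:
                st = anova_tukey(fold_scores, alpha=0.05)
                report["anova"][f"{arm}/{task}"] = {
                    "f_statistic": None if np.isnan(st.f_statistic) else st.f_statistic,
                    "p_value": st.p_value,
                    "significant_pairs": st.significant_pairs,
                    "degenerate": st.degenerate,
                }
    return report


def render_markdown(report: dict) -> str:
    """Render a benchmark report as a compact Markdown table."""
    lines = ["| arm | task | method | CV acc | weighted F1 | macro F1 | ROC-AUC (macro) |",
             "|---|---|---|---|---|---|---|"]
    for key, cell in report["cells"].items():
        arm, task, method = key.split("/")
        lines.append(
            f"| {arm} | {task} | {method} "
            f"| {cell['cv_accuracy_mean']:.3f} "
            f"| {cell['weighted_f1_mean']:.3f} ± {cell['weighted_f1_sd']:.3f} "
            f"| {cell['macro_f1_mean']:.3f} ± {cell['macro_f1_sd']:.3f} "
            f"| {cell['roc_auc_macro']:.3f} |"
        )
    if report.get("anova"):
        lines.append("")
        lines.append("| arm/task | ANOVA p (fold macro-F1) | significant pairs |")
        lines.append("|---|---|---|")
        for key, st in report["anova"].items():
            pairs = "; ".join("-".join(p) for p in st["significant_pairs"]) or "none"
            lines.append(f"| {key} | {st['p_value']:.4g} | {pairs} |")
    return "\n".join(lines) + "\n"
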