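"""Gene-panel benchmarking and cross-cancer specificity experiments.

Selected panels are evaluated with linear SVM, KNN and random-forest
classifiers over a ladder of panel sizes, reporting a stratified 75:25
hold-out result and a stratified five-fold cross-validation mean +- SD
of accuracy, F1 and AUROC. Specificity is probed by applying one cancer
type's panel to another type's cohort (``cross_apply``) and by pooling
panels (``union_panel``): on cohorts with type-specific signature genes,
own-panel AUROC exceeds both.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._seeds import derive_seed
from .exprprep import ExpressionMatrix

__all__ = [
    "PanelEvalConfig",
    "MetricSet",
    "PanelResult",
    "evaluate_panel",
    "overlap_table",
    "cross_apply",
    "union_panel",
]

DEFAULT_PANEL_SIZES = [30, 25, 20, 15, 10, 5, 3, 2, 1]
MODELS = ("svm", "knn", "rf")


@dataclass
class PanelEvalConfig:
    panel_sizes: list[int] = field(default_factory=lambda: list(DEFAULT_PANEL_SIZES))
    models: tuple[str, ...] = MODELS
    split_ratio: float = 0.75  # train fraction of the hold-out split
    cv_folds: int = 5
    knn_k: int = 5
    rf_trees: int = 500
    svm_c: float = 1.0
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.panel_sizes):
            raise ValueError("panel sizes must be positive")
        if list(self.panel_sizes) != sorted(self.panel_sizes, reverse=True):
            raise ValueError("panel sizes must be descending")
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must be in (0, 1)")
        unknown = set(self.models) - set(MODELS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")


@dataclass
class MetricSet:
    """Per-fold accuracy/F1/AUROC with their means and SDs."""

    per_fold: list[dict[str, float]]

    @property
    def accuracy(self) -> float:
        return float(np.mean([f["accuracy"] for f in self.per_fold]))

    @property
    def f1(self) -> float:
        return float(np.mean([f["f1"] for f in self.per_fold]))

    @property
    def auroc(self) -> float:
        return float(np.mean([f["auroc"] for f in self.per_fold]))

    def sd(self, metric: str) -> float:
        return float(np.std([f[metric] for f in self.per_fold], ddof=1)) if len(
            self.per_fold
        ) > 1 else 0.0

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auroc": self.auroc,
            "accuracy_sd": self.sd("accuracy"),
            "f1_sd": self.sd("f1"),
            "auroc_sd": self.sd("auroc"),
            "n_folds": len(self.per_fold),
        }


@dataclass
class PanelResult:
    holdout: dict[str, float]
    cv: MetricSet


def make_classifier(model: str, cfg: PanelEvalConfig, seed: int):
    """Instantiate one of the benchmark classifiers."""
    if model == "svm":
        clf = SVC(kernel="linear", C=cfg.svm_c, random_state=seed)
    elif model == "knn":
        clf = KNeighborsClassifier(n_neighbors=cfg.knn_k)
    elif model == "rf":
        clf = RandomForestClassifier(n_estimators=cfg.rf_trees, random_state=seed, n_jobs=1)
    else:
        raise ValueError(f"unknown model {model!r}")
    if cfg.standardize and model in ("svm", "knn"):
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    return clf


def decision_scores(clf, x: np.ndarray) -> np.ndarray:
    """Continuous scores for AUROC: margins for SVM, P(class 1) otherwise."""
    if hasattr(clf, "decision_function"):
        return np.asarray(clf.decision_function(x))
    return np.asarray(clf.predict_proba(x)[:, 1])


def _fit_score(clf, x_tr, y_tr, x_te, y_te) -> dict[str, float]:
    clf.fit(x_tr, y_tr)
    pred = clf.predict(x_te)
    scores = decision_scores(clf, x_te)
    return {
        "accuracy": float(accuracy_score(y_te, pred)),
        "f1": float(f1_score(y_te, pred, zero_division=0)),
        "auroc": float(roc_auc_score(y_te, scores)),
    }


def evaluate_panel(
    m: ExpressionMatrix,
    panel: Sequence[str],
    cfg: PanelEvalConfig | None = None,
) -> dict[tuple[str, int], PanelResult]:
    """Benchmark the top-s genes of a panel for each s in ``panel_sizes``.

    Returns {(model, panel_size): PanelResult}. The hold-out split is
    stratified 75:25 (``split_ratio``); cross-validation is stratified
    ``cv_folds``-fold over the full cohort. Both are deterministic under
    ``cfg.seed`` and shared across models so comparisons are paired.
    """
    cfg = cfg or PanelEvalConfig()
    panel = list(panel)
    missing = [g for g in panel if g not in set(m.gene_ids)]
    if missing:
        raise KeyError(f"panel genes absent from matrix: {missing}")
    y = np.asarray(m.labels)
    if np.unique(y).size < 2:
        raise ValueError("both classes required")

    results: dict[tuple[str, int], PanelResult] = {}
    for s in cfg.panel_sizes:
        if s > len(panel):
            warnings.warn(f"panel size {s} exceeds panel length {len(panel)}; skipped",
                          stacklevel=2)
            continue
        sub = m.subset_genes(panel[:s])
        x = sub.values
        ho_seed = derive_seed(cfg.seed, "holdout", s)
        x_tr, x_te, y_tr, y_te = train_test_split(
            x, y, train_size=cfg.split_ratio, stratify=y, random_state=ho_seed % (2**31)
        )
        skf = StratifiedKFold(
            n_splits=cfg.cv_folds, shuffle=True,
            random_state=derive_seed(cfg.seed, "cv", s) % (2**31),
        )
        fold_indices = list(skf.split(x, y))
        for model in cfg.models:
            mseed = derive_seed(cfg.seed, "model", model, s) % (2**31)
            holdout = _fit_score(
                make_classifier(model, cfg, mseed), x_tr, y_tr, x_te, y_te
            )
            folds = []
            for tr, te in fold_indices:
                folds.append(
                    _fit_score(
                        make_classifier(model, cfg, mseed), x[tr], y[tr], x[te], y[te]
                    )
                )
            results[(model, s)] = PanelResult(holdout=holdout, cv=MetricSet(folds))
    return results


def overlap_table(panels: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """All pairwise-and-higher intersections between named gene panels.

    One row per combination of >= 2 groups, with the overlap count and
    the sorted overlapping gene IDs.
    """
    if len(panels) < 2:
        raise ValueError("at least two panels required")
    names = list(panels)
    rows = []
    for r in range(2, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inter = set(panels[combo[0]])
            for name in combo[1:]:
                inter &= set(panels[name])
            rows.append(
                {
                    "groups": " | ".join(combo),
                    "n_groups": r,
                    "overlap_count": len(inter),
                    "overlap_ids": ",".join(sorted(inter)),
                }
            )
    return pd.DataFrame(rows)


def cross_apply(
    source_panel: Sequence[str],
    target: ExpressionMatrix,
    cfg: PanelEvalConfig | None = None,
) -> dict[tuple[str, int], PanelResult]:
    """Evaluate a panel selected on one cohort against another cohort.

    Genes absent from the target matrix are dropped (panel order kept);
    an empty intersection is an error. Quantifies how much a signature
    transfers across cancer types.
    """
    cfg = cfg or PanelEvalConfig()
    present = set(target.gene_ids)
    usable = [g for g in source_panel if g in present]
    if not usable:
        raise ValueError("source panel has no genes in common with the target matrix")
    return evaluate_panel(target, usable, cfg)


def union_panel(panels: Sequence[Sequence[str]]) -> list[str]:
    """Order-stable union of gene lists (first occurrence wins)."""
    if len(panels) < 2:
        raise ValueError("at least two panels required")
    seen: set[str] = set()
    out: list[str] = []
    for panel in panels:
        for g in panel:
            if g not in seen:
                seen.add(g)
                out.append(g)
    return out
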