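"""Late fusion of genomic, image and clinical blocks with Monte-Carlo
cross-validated classifiers.

Clinical cleaning follows the cohort-study convention: missing age is
imputed with the rounded mean age of the patient's cancer type; invalid
or missing T stage, N stage and positive-node counts become 0; min-max
normalization is applied to age and node count (stages pass through as
ordinals). Blocks are concatenated column-wise per patient (late
fusion) and evaluated with linear SVM and a single-hidden-layer MLP
over independent stratified 80:20 resplits (Monte-Carlo CV). The
modality report compares the six block combinations of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._seeds import derive_seed
from .panel_eval import MetricSet, decision_scores

__all__ = [
    "MCCVConfig",
    "FusionDataset",
    "clean_clinical",
    "fuse",
    "evaluate_mccv",
    "modality_report",
    "MODALITY_COMBINATIONS",
]

CLASSIFIERS = ("svm", "mlp")
CLINICAL_COLUMNS = ["age", "t_stage", "n_stage", "nodes_positive"]

MODALITY_COMBINATIONS: list[tuple[str, ...]] = [
    ("clinical",),
    ("image",),
    ("genomic",),
    ("genomic", "image"),
    ("clinical", "genomic"),
    ("genomic", "image", "clinical"),
]


@dataclass
class MCCVConfig:
    n_splits: int = 5
    test_fraction: float = 0.20
    classifiers: tuple[str, ...] = CLASSIFIERS
    mlp_hidden: int = 32
    svm_c: float = 1.0
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        unknown = set(self.classifiers) - set(CLASSIFIERS)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")


@dataclass
class FusionDataset:
    """Row-aligned feature blocks plus labels; row i is the same patient
    in every block."""

    blocks: dict[str, pd.DataFrame]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        n = self.labels.shape[0]
        for name, block in self.blocks.items():
            if len(block) != n:
                raise ValueError(
                    f"block {name!r} has {len(block)} rows, expected {n}"
                )
        indexes = [tuple(b.index) for b in self.blocks.values()]
        if indexes and any(ix != indexes[0] for ix in indexes[1:]):
            raise ValueError("blocks are not aligned on the same patient index")


def clean_clinical(
    records: pd.DataFrame,
    group_mean_ages: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Impute and normalize the four clinical variables.

    Missing age -> rounded mean age of that cancer type (from the
    non-missing members, unless ``group_mean_ages`` overrides); missing
    or invalid stages and node counts -> 0; min-max scaling on age and
    node count over the whole cohort. Stages stay ordinal. Note the
    deliberate ambiguity inherited from the cleaning rule: an imputed
    N stage of 0 is indistinguishable from genuine N0.
    """
    df = records.copy()
    for col in ("patient_id", "cancer_type"):
        if col not in df.columns:
            raise ValueError(f"clinical table lacks column {col!r}")
    age = pd.to_numeric(df["age"], errors="coerce")
    for ct, sub in df.groupby("cancer_type"):
        mask = (df["cancer_type"] == ct) & age.isna()
        if not mask.any():
            continue
        if group_mean_ages is not None and ct in group_mean_ages:
            fill = round(float(group_mean_ages[ct]))
        else:
            known = age[df["cancer_type"] == ct].dropna()
            if known.empty:
                raise ValueError(f"cancer type {ct!r} has no non-missing ages")
            fill = round(float(known.mean()))
        age.loc[mask] = fill
    df["age"] = age.astype(float)

    for col in ("t_stage", "n_stage", "nodes_positive"):
        vals = pd.to_numeric(df[col], errors="coerce")
        df[col] = vals.fillna(0).astype(float)

    for col in ("age", "nodes_positive"):
        lo, hi = df[col].min(), df[col].max()
        df[col] = (df[col] - lo) / (hi - lo) if hi > lo else 0.0
    return df


def fuse(
    blocks: Mapping[str, pd.DataFrame | np.ndarray],
    block_names: Sequence[str],
) -> pd.DataFrame:
    """Column-wise concatenation of the requested blocks, in order.

    Column names carry provenance as ``<block>:<original column>``.
    """
    names = list(block_names)
    if len(set(names)) != len(names):
        raise ValueError("duplicate block names requested")
    missing = [n for n in names if n not in blocks]
    if missing:
        raise ValueError(f"blocks not available: {missing}")
    frames = []
    n_rows = None
    bad = []
    for name in names:
        block = blocks[name]
        df = block if isinstance(block, pd.DataFrame) else pd.DataFrame(np.asarray(block))
        if n_rows is None:
            n_rows = len(df)
        elif len(df) != n_rows:
            bad.append((name, len(df)))
        frames.append(df.rename(columns={c: f"{name}:{c}" for c in df.columns}))
    if bad:
        raise ValueError(
            f"row-count mismatch: expected {n_rows}, got {bad}"
        )
    fused = pd.concat([f.reset_index(drop=True) for f in frames], axis=1)
    fused.index = frames[0].index
    return fused


def _make_fusion_classifier(name: str, cfg: MCCVConfig, seed: int):
    if name == "svm":
        clf = SVC(kernel="linear", C=cfg.svm_c, random_state=seed)
    elif name == "mlp":
        clf = MLPClassifier(
            hidden_layer_sizes=(cfg.mlp_hidden,),
            max_iter=800,
            random_state=seed,
        )
    else:
        raise ValueError(f"unknown classifier {name!r}")
    if cfg.standardize:
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    return clf


def _mc_splits(y: np.ndarray, cfg: MCCVConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Independent stratified 80:20 resplits, shared across classifiers.

    A split whose test set is single-class is redrawn (max 10 retries).
    """
    idx = np.arange(y.shape[0])
    splits = []
    for s in range(cfg.n_splits):
        for retry in range(10):
            seed = derive_seed(cfg.seed, "mccv", s, retry) % (2**31)
            tr, te = train_test_split(
                idx, test_size=cfg.test_fraction, stratify=y, random_state=seed
            )
            if np.unique(y[te]).size == 2:
                splits.append((tr, te))
                break
        else:
            raise RuntimeError("could not draw a two-class test split in 10 tries")
    return splits


def evaluate_mccv(
    fused: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    cfg: MCCVConfig | None = None,
) -> dict[str, MetricSet]:
    """Monte-Carlo CV: per classifier, metrics over ``n_splits``
    independent stratified train/test resplits (splits shared across
    classifiers so comparisons are paired)."""
    cfg = cfg or MCCVConfig()
    x = fused.to_numpy(dtype=float) if isinstance(fused, pd.DataFrame) else np.asarray(fused, dtype=float)
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("both classes required")
    splits = _mc_splits(y, cfg)
    out: dict[str, MetricSet] = {}
    for name in cfg.classifiers:
        folds = []
        for s, (tr, te) in enumerate(splits):
            seed = derive_seed(cfg.seed, "clf", name, s) % (2**31)
            clf = _make_fusion_classifier(name, cfg, seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # MLP convergence chatter
                clf.fit(x[tr], y[tr])
            pred = clf.predict(x[te])
            scores = decision_scores(clf, x[te])
            folds.append(
                {
                    "accuracy": float(accuracy_score(y[te], pred)),
                    "f1": float(f1_score(y[te], pred, zero_division=0)),
                    "auroc": float(roc_auc_score(y[te], scores)),
                }
            )
        out[name] = MetricSet(folds)
    return out


def modality_report(
    dataset: FusionDataset,
    cfg: MCCVConfig | None = None,
    combinations: Sequence[Sequence[str]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Benchmark the six standard block combinations.

    Returns {classifier: DataFrame} where each frame has one row per
    combination and mean/SD columns for accuracy, F1 and AUROC.
    """
    cfg = cfg or MCCVConfig()
    combos = [tuple(c) for c in (combinations or MODALITY_COMBINATIONS)]
    rows: dict[str, list[dict]] = {name: [] for name in cfg.classifiers}
    for combo in combos:
        fused = fuse(dataset.blocks, combo)
        metrics = evaluate_mccv(fused, dataset.labels, cfg)
        label = " + ".join(c.capitalize() for c in combo)
        for name, ms in metrics.items():
            rows[name].append(
                {
                    "data_types": label,
                    "mean_accuracy": ms.accuracy,
                    "accuracy_sd": ms.sd("accuracy"),
                    "mean_f1": ms.f1,
                    "f1_sd": ms.sd("f1"),
                    "mean_auroc": ms.auroc,
                    "auroc_sd": ms.sd("auroc"),
                }
            )
    return {
        name: pd.DataFrame(r).set_index("data_types") for name, r in rows.items()
    }
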