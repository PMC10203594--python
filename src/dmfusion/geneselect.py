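"""Frequency-ranked iterative random-forest gene selection.

The selection algorithm refits a random-forest DM classifier N times
(default 1000), records the K (default 100) most important genes of each
fit, and ranks genes by how often they appear in those top-K lists. The
frequency tally, not any single forest's importance, is the selection
signal: genes that matter show up iteration after iteration, while
noise genes drift in and out. The top ``n_select`` (default 50) by
frequency form the gene panel.

A univariate Welch t-statistic ranker is included as a desk-scale
baseline for comparing against the multivariate selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from ._seeds import derive_seed, spawn_rng
from .exprprep import ExpressionMatrix

__all__ = [
    "SelectionConfig",
    "RankEntry",
    "GeneRanking",
    "select_genes",
    "rank_genes_by_tstat",
]


@dataclass
class SelectionConfig:
    """Parameters of the iterative selection.

    ``n_iterations`` and ``top_k`` default to the N=1000 / K=100 study
    protocol; ``trees_per_forest`` defaults to 500 which stabilizes
    impurity importances at desk scale. ``subsample_fraction`` (optional)
    refits each iteration on a stratified subsample instead of the full
    data; by default the forest's internal bootstrap is the only
    resampling between iterations.
    """

    n_iterations: int = 1000
    top_k: int = 100
    n_select: int = 50
    trees_per_forest: int = 500
    importance_measure: Literal["impurity_decrease", "permutation"] = (
        "impurity_decrease"
    )
    subsample_fraction: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")
        if self.subsample_fraction is not None and not (
            0.0 < self.subsample_fraction <= 1.0
        ):
            raise ValueError("subsample_fraction must be in (0, 1]")


@dataclass
class RankEntry:
    gene_id: str
    frequency: int
    mean_importance: float


@dataclass
class GeneRanking:
    """Ranked genes plus the per-iteration audit trail.

    ``entries`` are sorted by frequency descending, then mean importance
    descending, then gene ID ascending. ``iteration_log`` holds the K
    gene IDs selected at each of the N iterations, in importance order,
    so the tally can be recounted independently.
    """

    entries: list[RankEntry]
    iteration_log: list[list[str]]
    n_select: int = 50

    @property
    def panel(self) -> list[str]:
        """Top ``n_select`` gene IDs by the final ranking."""
        return [e.gene_id for e in self.entries[: self.n_select]]

    def top(self, n: int) -> list[str]:
        return [e.gene_id for e in self.entries[:n]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.entries) + 1),
                "gene_id": [e.gene_id for e in self.entries],
                "frequency": [e.frequency for e in self.entries],
                "mean_importance": [e.mean_importance for e in self.entries],
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _iteration_importance(
    x: np.ndarray,
    y: np.ndarray,
    cfg: SelectionConfig,
    sub_seed: int,
) -> np.ndarray:
    rng = np.random.default_rng(sub_seed)
    if cfg.subsample_fraction is not None and cfg.subsample_fraction < 1.0:
        n = x.shape[0]
        idx_parts = []
        for cls in np.unique(y):
            rows = np.flatnonzero(y == cls)
            take = max(2, int(round(cfg.subsample_fraction * rows.size)))
            idx_parts.append(rng.choice(rows, size=min(take, rows.size), replace=False))
        idx = np.sort(np.concatenate(idx_parts))
        x, y = x[idx], y[idx]
    forest = RandomForestClassifier(
        n_estimators=cfg.trees_per_forest,
        random_state=int(sub_seed % (2**31 - 1)),
        n_jobs=1,
    )
    forest.fit(x, y)
    if cfg.importance_measure == "permutation":
        result = permutation_importance(
            forest, x, y, n_repeats=5, random_state=int(sub_seed % (2**31 - 1))
        )
        return np.asarray(result.importances_mean)
    return np.asarray(forest.feature_importances_)


def select_genes(m: ExpressionMatrix, cfg: SelectionConfig) -> GeneRanking:
    """Run the N-iteration frequency-ranked selection on a cohort.

    Each iteration fits a fresh forest (distinct derived sub-seed) to
    classify DM vs non-DM and records its top-K genes by importance
    (ties broken by gene ID ascending). Deterministic under ``cfg.seed``.
    """
    classes = np.unique(m.labels)
    if classes.size < 2:
        raise ValueError("both DM and non-DM samples are required for selection")
    n_genes = m.n_genes
    k = cfg.top_k
    if k > n_genes:
        warnings.warn(
            f"top_k={k} exceeds {n_genes} genes; clamping to {n_genes}",
            stacklevel=2,
        )
        k = n_genes

    gene_ids = np.asarray(m.gene_ids, dtype=object)
    id_rank = np.argsort(np.argsort(gene_ids))
    counts = np.zeros(n_genes, dtype=int)
    imp_sum = np.zeros(n_genes, dtype=float)
    iteration_log: list[list[str]] = []
    x = np.asarray(m.values, dtype=float)
    y = np.asarray(m.labels)

    for i in range(cfg.n_iterations):
        sub_seed = derive_seed(cfg.seed, "select-iter", i)
        imp = _iteration_importance(x, y, cfg, sub_seed)
        imp_sum += imp
        order = np.lexsort((id_rank, -imp))  # importance desc, gene ID asc
        top = order[:k]
        counts[top] += 1
        iteration_log.append([str(gene_ids[g]) for g in top])

    mean_imp = imp_sum / cfg.n_iterations
    final = np.lexsort((id_rank, -mean_imp, -counts))
    entries = [
        RankEntry(
            gene_id=str(gene_ids[g]),
            frequency=int(counts[g]),
            mean_importance=float(mean_imp[g]),
        )
        for g in final
    ]
    return GeneRanking(entries=entries, iteration_log=iteration_log, n_select=cfg.n_select)


def rank_genes_by_tstat(
    m: ExpressionMatrix, return_stats: bool = False
) -> list[str] | tuple[list[str], pd.Series]:
    """Rank genes by |Welch t| between DM and non-DM samples.

    A univariate baseline for the multivariate frequency selection.
    Genes with zero variance in both groups get t = 0.
    """
    y = np.asarray(m.labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes required")
    a = m.values[y == classes.max()]
    b = m.values[y == classes.min()]
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant genes trigger a scipy precision warning; their t is set to 0
        warnings.simplefilter("ignore", RuntimeWarning)
        t, _ = stats.ttest_ind(a, b, axis=0, equal_var=False)
    t = np.nan_to_num(np.asarray(t), nan=0.0)
    gene_ids = np.asarray(m.gene_ids, dtype=object)
    id_rank = np.argsort(np.argsort(gene_ids))
    order = np.lexsort((id_rank, -np.abs(t)))
    ranked = [str(gene_ids[i]) for i in order]
    if return_stats:
        return ranked, pd.Series(t, index=m.gene_ids, name="t")
    return ranked
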