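"""Expression-matrix preprocessing for distant-metastasis cohorts.

The pipeline mirrors common practice for TPM tables pooled from
per-sample records: merge on the gene universe, replace NaN with zero,
log10(x+1) transform, drop genes that are zero in more than 80% of
samples, and keep the top-variance genes.

The canonical in-memory container is :class:`ExpressionMatrix`:
a samples x genes float matrix plus sample/gene identifiers, binary
distant-metastasis (DM) labels and a per-sample cancer-type tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "merge_and_clean",
    "log_transform",
    "prevalence_filter",
    "top_variance_filter",
    "preprocess",
    "read_expression_tsv",
    "write_expression_tsv",
]


@dataclass
class ExpressionMatrix:
    """samples x genes expression values with DM labels and cancer-type tags.

    ``values`` are on the TPM scale before transformation and on the
    log10(x+1) scale afterwards (``transformed`` flag). Labels are 0/1
    with 1 = distant metastasis.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    labels: np.ndarray
    cancer_type: np.ndarray
    transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        self.cancer_type = np.asarray(self.cancer_type, dtype=object)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.gene_ids)} genes)"
            )
        if self.labels.shape[0] != len(self.sample_ids):
            raise ValueError("labels length does not match sample count")
        if self.cancer_type.shape[0] != len(self.sample_ids):
            raise ValueError("cancer_type length does not match sample count")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not present in matrix") from None

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Column subset in the order given; unknown genes raise KeyError."""
        idx = [self.gene_index(g) for g in genes]
        return replace(
            self,
            values=self.values[:, idx].copy(),
            gene_ids=[self.gene_ids[i] for i in idx],
        )

    def subset_samples(self, mask: np.ndarray) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return replace(
            self,
            values=self.values[idx].copy(),
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx].copy(),
            cancer_type=self.cancer_type[idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """genes x samples DataFrame (the on-disk orientation)."""
        return pd.DataFrame(
            self.values.T, index=self.gene_ids, columns=self.sample_ids
        )


def merge_and_clean(
    per_sample_tables: Mapping[str, pd.Series] | Sequence[tuple[str, pd.Series]],
    labels: Mapping[str, int] | Sequence[int],
    cancer_types: Mapping[str, str] | Sequence[str] | str,
) -> ExpressionMatrix:
    """Merge per-sample (gene -> value) tables into one cohort matrix.

    Gene universes are outer-joined (absent entries filled with 0) and
    every NaN is replaced by zero. Row order follows the input sample
    order; genes are sorted by identifier for determinism.
    """
    if isinstance(per_sample_tables, Mapping):
        items = list(per_sample_tables.items())
    else:
        items = list(per_sample_tables)
    if not items:
        raise ValueError("no per-sample tables supplied")
    sample_ids = [str(s) for s, _ in items]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicate sample IDs: {dupes}")

    merged = pd.concat(
        [t.astype(float) for _, t in items], axis=1, keys=sample_ids, join="outer"
    )
    merged = merged.sort_index()
    merged = merged.fillna(0.0)

    if isinstance(labels, Mapping):
        lab = np.array([labels[s] for s in sample_ids])
    else:
        lab = np.asarray(list(labels))
    if isinstance(cancer_types, str):
        ct = np.array([cancer_types] * len(sample_ids), dtype=object)
    elif isinstance(cancer_types, Mapping):
        ct = np.array([cancer_types[s] for s in sample_ids], dtype=object)
    else:
        ct = np.asarray(list(cancer_types), dtype=object)

    return ExpressionMatrix(
        values=merged.to_numpy().T,
        sample_ids=sample_ids,
        gene_ids=[str(g) for g in merged.index],
        labels=lab,
        cancer_type=ct,
        transformed=False,
    )


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """log10(x + 1) on every value; keeps zeros at zero."""
    if m.transformed:
        raise ValueError("matrix is already log-transformed")
    if np.isnan(m.values).any():
        raise ValueError("matrix contains NaN; run merge_and_clean first")
    if (m.values < 0).any():
        raise ValueError("negative expression values cannot be log-transformed")
    return replace(m, values=np.log10(m.values + 1.0), transformed=True)


def prevalence_filter(m: ExpressionMatrix, threshold: float = 0.80) -> ExpressionMatrix:
    """Drop genes whose zero fraction is strictly greater than ``threshold``.

    A gene that is zero in exactly ``threshold`` of the samples is kept
    (strict inequality). Works identically before or after the log10(x+1)
    transform since that transform maps 0 to 0.
    """
    zero_frac = (m.values == 0).mean(axis=0)
    keep = np.flatnonzero(zero_frac <= threshold)
    return replace(
        m,
        values=m.values[:, keep].copy(),
        gene_ids=[m.gene_ids[i] for i in keep],
    )


def top_variance_filter(m: ExpressionMatrix, k: int = 10000) -> ExpressionMatrix:
    """Keep the min(k, n_genes) genes with the largest per-gene variance.

    Variance is the population variance (ddof=0) across all samples; ties
    are broken by gene ID ascending. The survivors keep their original
    column order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    var = m.values.var(axis=0, ddof=0)
    id_rank = np.argsort(np.argsort(np.asarray(m.gene_ids, dtype=object)))
    # primary key: variance descending; secondary: gene ID ascending
    order = np.lexsort((id_rank, -var))
    chosen = np.sort(order[: min(k, m.n_genes)])
    return replace(
        m,
        values=m.values[:, chosen].copy(),
        gene_ids=[m.gene_ids[i] for i in chosen],
    )


def preprocess(
    m: ExpressionMatrix,
    prevalence_threshold: float = 0.80,
    top_k_variance: int = 10000,
) -> tuple[ExpressionMatrix, dict]:
    """Full chain: NaN->0, log10(x+1), prevalence filter, variance filter.

    Returns the processed matrix and a provenance dict with per-filter
    dropped-gene counts.
    """
    values = np.nan_to_num(m.values, nan=0.0)
    cleaned = replace(m, values=values)
    logged = log_transform(cleaned) if not cleaned.transformed else cleaned
    after_prev = prevalence_filter(logged, prevalence_threshold)
    after_var = top_variance_filter(after_prev, top_k_variance)
    provenance = {
        "n_genes_in": m.n_genes,
        "dropped_prevalence": logged.n_genes - after_prev.n_genes,
        "dropped_variance": after_prev.n_genes - after_var.n_genes,
        "n_genes_out": after_var.n_genes,
        "prevalence_threshold": prevalence_threshold,
        "top_k_variance": top_k_variance,
    }
    return after_var, provenance


def write_expression_tsv(m: ExpressionMatrix, path: str | Path) -> None:
    """Write genes x samples TSV (first column = gene ID)."""
    df = m.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_expression_tsv(
    path: str | Path,
    labels: Mapping[str, int] | None = None,
    cancer_types: Mapping[str, str] | None = None,
    transformed: bool = False,
) -> ExpressionMatrix:
    """Read a genes x samples TSV written by :func:`write_expression_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    sample_ids = [str(c) for c in df.columns]
    lab = np.array([labels[s] for s in sample_ids]) if labels else np.zeros(len(sample_ids), dtype=int)
    ct = (
        np.array([cancer_types[s] for s in sample_ids], dtype=object)
        if cancer_types
        else np.array(["NA"] * len(sample_ids), dtype=object)
    )
    return ExpressionMatrix(
        values=df.to_numpy().T,
        sample_ids=sample_ids,
        gene_ids=[str(g) for g in df.index],
        labels=lab,
        cancer_type=ct,
        transformed=transformed,
    )
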