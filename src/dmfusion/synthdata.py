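"""Synthetic multimodal cohort generator with known ground truth.

Emulates the structure of a TCGA-style distant-metastasis (DM) study at
desk scale: per-cancer-type groups with equal numbers of DM and non-DM
samples, TPM-like gene expression with zero inflation and sporadic NaN,
clinical variables (age, T/N stage, positive-node count) with realistic
missingness, and per-patient sets of 512x512 RGB histology-like patches.

Ground truth is planted explicitly: each cancer type gets a disjoint set
of signature genes whose log10 mean is shifted by ``effect_size`` in DM
samples of that type only; DM patients' patches are rendered at a higher
nucleus density; DM patients carry more positive lymph nodes. Every
downstream stage (selection, panel benchmarking, the patch funnel,
fusion) can therefore be validated against a known answer.

Expression model: per-gene log10-mean ~ Uniform(-1, 3) and log10-SD ~
Uniform(0.2, 0.6), i.e. a log-normal on the TPM scale spanning several
orders of magnitude. Zero inflation replaces a drawn value by 0 with
probability ``zero_inflation``; NaN injection follows (a distinct event
from a true zero). All randomness derives from a single seed: the same
config reproduces the cohort bit for bit, pixels included.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import ellipse

from ._seeds import derive_seed, spawn_rng
from .exprprep import ExpressionMatrix
from .wsiprep import Patch

__all__ = [
    "ImageConfig",
    "SyntheticConfig",
    "SyntheticCohort",
    "generate_cohort",
    "render_patch",
    "write_cohort",
]

_TISSUE_RGB = np.array([231, 170, 200], dtype=float)  # eosin-pink field
_NUCLEUS_RGB = np.array([72, 48, 120], dtype=float)  # hematoxylin-dark blob
_GLASS_RGB = np.array([250, 250, 250], dtype=float)


@dataclass
class ImageConfig:
    """Patch-set parameters for the image block.

    ``density_dispersion`` is the SD of a per-patient lognormal
    multiplier on the class nucleus density: tumors of the same DM
    status differ in cellularity, so the image block is an informative
    but imperfect predictor rather than a deterministic label readout.
    Patch counts are then Poisson around the patient's density.
    """

    patches_per_patient: int = 8
    nucleus_density_dm: int = 45  # mean nuclei per patch, DM patients
    nucleus_density_nondm: int = 30
    nucleus_radius_px: int = 8
    glass_fraction: float = 0.2  # probability a patch is mostly blank glass
    density_dispersion: float = 0.35

    def __post_init__(self) -> None:
        if self.patches_per_patient < 0:
            raise ValueError("patches_per_patient must be >= 0")
        if min(self.nucleus_density_dm, self.nucleus_density_nondm) < 0:
            raise ValueError("nucleus densities must be >= 0")
        if not 0.0 <= self.glass_fraction <= 1.0:
            raise ValueError("glass_fraction must be in [0, 1]")
        if self.density_dispersion < 0:
            raise ValueError("density_dispersion must be >= 0")


@dataclass
class SyntheticConfig:
    """Everything that defines a synthetic cohort.

    ``groups`` is a list of (cancer_type_label, n_dm, n_nondm);
    ``planted`` maps cancer type -> gene indices whose log10 mean is
    shifted by ``effect_size`` in that type's DM samples. When
    ``specificity_mode`` is on, planted sets must be pairwise disjoint
    (the cross-cancer specificity experiments rely on this).
    """

    groups: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("A", 24, 24)]
    )
    n_genes: int = 200
    planted: Mapping[str, Sequence[int]] = field(default_factory=dict)
    effect_size: float = 1.0  # log10-scale mean shift
    zero_inflation: float = 0.10
    nan_rate: float = 0.01
    image: ImageConfig = field(default_factory=ImageConfig)
    clinical_effect: float = 1.0  # added mean positive-node count for DM
    node_na_rate: float | Mapping[str, float] = 0.20
    age_na_rate: float = 0.05
    stage_invalid_rate: float = 0.05
    specificity_mode: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        for label, n_dm, n_nondm in self.groups:
            if n_dm < 1 or n_nondm < 1:
                raise ValueError(f"group {label!r}: counts must be >= 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for prob in (self.zero_inflation, self.nan_rate, self.age_na_rate,
                     self.stage_invalid_rate):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for ct, idx in self.planted.items():
            if any(i < 0 or i >= self.n_genes for i in idx):
                raise ValueError(f"planted indices for {ct!r} exceed n_genes")
        if self.specificity_mode:
            seen: set[int] = set()
            for ct, idx in self.planted.items():
                overlap = seen.intersection(idx)
                if overlap:
                    raise ValueError(
                        f"planted sets overlap at gene indices {sorted(overlap)}; "
                        "disjoint sets required under specificity_mode"
                    )
                seen.update(idx)

    def node_na_rate_for(self, cancer_type: str) -> float:
        if isinstance(self.node_na_rate, Mapping):
            return float(self.node_na_rate.get(cancer_type, 0.0))
        return float(self.node_na_rate)


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: pd.DataFrame
    patches: dict[str, list[Patch]]
    truth: dict[str, list[str]]  # cancer type -> planted gene IDs

    def __post_init__(self) -> None:
        ids = set(self.expression.sample_ids)
        if set(self.clinical["patient_id"]) != ids:
            raise ValueError("clinical patient IDs do not match expression samples")
        if self.patches:
            if set(self.patches) != ids:
                raise ValueError("patch patient IDs do not match expression samples")
            for pid, plist in self.patches.items():
                if not plist:
                    raise ValueError(f"patient {pid} has no patches")


# ---------------------------------------------------------------------------
# patch rendering


def render_patch(
    density: int,
    radius_px: int = 8,
    glass: bool = False,
    seed: int = 0,
    size: int = 512,
) -> Patch:
    """Render one histology-like tile.

    Tissue patches are a noisy pink field with ``density`` dark
    elliptical nuclei placed by rejection sampling (minimum center
    distance 2 * radius, so blobs never merge and the count is an
    unambiguous ground truth). Glass patches are near-white noise. The
    actually rendered nucleus count is stored in ``meta['n_nuclei']``.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    rng = np.random.default_rng(seed)
    if glass:
        pixels = _GLASS_RGB + rng.normal(0.0, 2.0, size=(size, size, 3))
        patch = Patch(
            pixels=np.clip(np.rint(pixels), 0, 255).astype(np.uint8),
            meta={"n_nuclei": 0, "glass": True},
        )
        return patch

    pixels = _TISSUE_RGB + rng.normal(0.0, 5.0, size=(size, size, 3))
    centers: list[tuple[float, float]] = []
    min_dist2 = (2.0 * radius_px) ** 2
    attempts = 0
    max_attempts = max(200, 100 * density)
    margin = 2 * radius_px
    while len(centers) < density and attempts < max_attempts:
        attempts += 1
        r = rng.uniform(margin, size - margin)
        c = rng.uniform(margin, size - margin)
        if all((r - rr) ** 2 + (c - cc) ** 2 >= min_dist2 for rr, cc in centers):
            centers.append((r, c))
    for r, c in centers:
        r_rad = radius_px * rng.uniform(0.7, 1.1)
        c_rad = radius_px * rng.uniform(0.7, 1.1)
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(r, c, r_rad, c_rad, shape=(size, size), rotation=rot)
        jitter = rng.normal(0.0, 4.0, size=3)
        pixels[rr, cc] = _NUCLEUS_RGB + jitter
    return Patch(
        pixels=np.clip(np.rint(pixels), 0, 255).astype(np.uint8),
        meta={"n_nuclei": len(centers), "glass": False},
    )


# ---------------------------------------------------------------------------
# cohort generation


def _stage_from_nodes(nodes: int) -> int:
    """TNM-like N stage from the positive-node count."""
    if nodes <= 0:
        return 0
    if nodes <= 2:
        return 1
    if nodes <= 6:
        return 2
    return 3


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate expression, clinical and image blocks for one cohort.

    See the module docstring for the statistical model. Patients are
    named ``<type>-DM-<i>`` / ``<type>-N-<i>``; genes ``G0000``...
    """
    seed = config.seed
    n_genes = config.n_genes
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]

    rng_genes = spawn_rng(seed, "gene-params")
    mu = rng_genes.uniform(-1.0, 3.0, size=n_genes)
    sd = rng_genes.uniform(0.2, 0.6, size=n_genes)

    sample_ids: list[str] = []
    labels: list[int] = []
    cancer_type: list[str] = []
    for ct, n_dm, n_nondm in config.groups:
        sample_ids += [f"{ct}-DM-{i:03d}" for i in range(n_dm)]
        labels += [1] * n_dm
        sample_ids += [f"{ct}-N-{i:03d}" for i in range(n_nondm)]
        labels += [0] * n_nondm
        cancer_type += [ct] * (n_dm + n_nondm)
    n_samples = len(sample_ids)
    labels_arr = np.array(labels)
    ct_arr = np.array(cancer_type, dtype=object)

    # log10 expression: per-gene baseline + planted shift in DM samples
    rng_expr = spawn_rng(seed, "expression")
    log_values = rng_expr.normal(
        loc=mu[None, :], scale=sd[None, :], size=(n_samples, n_genes)
    )
    for ct, idx in config.planted.items():
        rows = np.flatnonzero((ct_arr == ct) & (labels_arr == 1))
        if rows.size:
            log_values[np.ix_(rows, list(idx))] += config.effect_size
    values = np.power(10.0, log_values)
    zero_mask = rng_expr.random((n_samples, n_genes)) < config.zero_inflation
    values[zero_mask] = 0.0
    nan_mask = rng_expr.random((n_samples, n_genes)) < config.nan_rate
    values[nan_mask] = np.nan

    expression = ExpressionMatrix(
        values=values,
        sample_ids=sample_ids,
        gene_ids=gene_ids,
        labels=labels_arr,
        cancer_type=ct_arr,
        transformed=False,
    )

    # clinical block
    rng_clin = spawn_rng(seed, "clinical")
    ages = np.clip(np.rint(rng_clin.normal(63.0, 9.0, size=n_samples)), 40, 90)
    t_stage = rng_clin.choice([1, 2, 3, 4], size=n_samples, p=[0.05, 0.25, 0.5, 0.2])
    node_lambda = 1.5 + config.clinical_effect * labels_arr
    nodes = rng_clin.poisson(node_lambda).astype(float)
    n_stage = np.array([_stage_from_nodes(int(n)) for n in nodes])
    age_na = rng_clin.random(n_samples) < config.age_na_rate
    stage_invalid = rng_clin.random(n_samples) < config.stage_invalid_rate
    node_rates = np.array([config.node_na_rate_for(ct) for ct in cancer_type])
    node_na = rng_clin.random(n_samples) < node_rates
    ages = ages.astype(object)
    ages[age_na] = np.nan
    t_stage = t_stage.astype(object)
    t_stage[stage_invalid] = np.nan
    nodes = nodes.astype(object)
    nodes[node_na] = np.nan
    clinical = pd.DataFrame(
        {
            "patient_id": sample_ids,
            "cancer_type": cancer_type,
            "age": ages,
            "t_stage": t_stage,
            "n_stage": n_stage,
            "nodes_positive": nodes,
            "dm": labels_arr,
        }
    )

    # image block
    patches: dict[str, list[Patch]] = {}
    img = config.image
    if img.patches_per_patient > 0:
        rng_img = spawn_rng(seed, "image-flags")
        for pid, lab in zip(sample_ids, labels):
            base = img.nucleus_density_dm if lab else img.nucleus_density_nondm
            patient_density = base * rng_img.lognormal(0.0, img.density_dispersion)
            plist = []
            for k in range(img.patches_per_patient):
                glass = bool(rng_img.random() < img.glass_fraction)
                density = int(rng_img.poisson(patient_density))
                patch = render_patch(
                    density=density,
                    radius_px=img.nucleus_radius_px,
                    glass=glass,
                    seed=derive_seed(seed, "patch", pid, k),
                )
                patch.parent_id = pid
                plist.append(patch)
            patches[pid] = plist

    truth = {ct: [gene_ids[i] for i in idx] for ct, idx in config.planted.items()}
    return SyntheticCohort(
        expression=expression, clinical=clinical, patches=patches, truth=truth
    )


# ---------------------------------------------------------------------------
# on-disk layout


def write_cohort(
    cohort: SyntheticCohort,
    out_dir: str | Path,
    write_patches: bool = True,
) -> dict:
    """Write expression/clinical TSVs, truth JSON and patch PNGs.

    Expression is written genes x samples (first column gene ID);
    patches as ``patches/<patient>_<index>.png``. Returns a manifest of
    paths and counts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr_path = out / "expression.tsv"
    df = cohort.expression.to_frame()
    df.index.name = "gene_id"
    df.to_csv(expr_path, sep="\t")
    clin_path = out / "clinical.tsv"
    cohort.clinical.to_csv(clin_path, sep="\t", index=False)
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(cohort.truth, indent=2))
    n_png = 0
    if write_patches and cohort.patches:
        patch_dir = out / "patches"
        patch_dir.mkdir(exist_ok=True)
        for pid, plist in cohort.patches.items():
            for k, patch in enumerate(plist):
                Image.fromarray(patch.pixels).save(patch_dir / f"{pid}_{k}.png")
                n_png += 1
    return {
        "expression": str(expr_path),
        "clinical": str(clin_path),
        "truth": str(truth_path),
        "n_samples": cohort.expression.n_samples,
        "n_genes": cohort.expression.n_genes,
        "n_patches_written": n_png,
    }
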