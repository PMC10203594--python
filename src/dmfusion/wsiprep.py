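"""Histology patch funnel: extraction, tissue filtering, cellularity
ranking and Macenko stain normalization.

Whole-slide images are analyzed as fixed-size RGB patches. The funnel
reduces a slide to its most tumor-representative tiles in three stages:

1. up to ``max_random_patches`` random non-overlapping 512x512 patches,
2. patches with a tissue fraction >= ``tissue_threshold`` (capped at
   ``max_after_tissue`` by uniform subsampling),
3. the ``n_top_cellularity`` patches with the highest cellularity score.

Stain appearance is standardized by Macenko normalization: per-patch
hematoxylin/eosin optical-density vectors are estimated from the plane
of the top two singular vectors of the OD cloud, robust extreme angles
are taken at the alpha / (100 - alpha) percentiles, and the image is
reconstructed with a reference stain matrix after concentration scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skimage import measure
from skimage.color import rgb2hed

from ._seeds import spawn_rng

__all__ = [
    "Patch",
    "PatchScore",
    "StainParams",
    "FunnelConfig",
    "InsufficientTissueError",
    "extract_patches",
    "tissue_fraction",
    "cellularity_score",
    "default_cellularity_scorer",
    "run_funnel",
    "fit_stains",
    "macenko_normalize",
    "forward_synthesize",
]

PATCH_SIZE = 512


@dataclass
class Patch:
    """One RGB tile with provenance back to its parent image.

    ``origin`` is the 0-based (row, col) of the top-left corner; the
    extent is half-open: rows [r, r + h), cols [c, c + w).
    """

    pixels: np.ndarray
    origin: tuple[int, int] = (0, 0)
    parent_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("patch pixels must be HxWx3")
        if self.pixels.dtype != np.uint8:
            raise ValueError("patch pixels must be 8-bit (uint8)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    def extent(self) -> tuple[int, int, int, int]:
        """(row0, col0, row1, col1), half-open."""
        r, c = self.origin
        h, w = self.shape
        return r, c, r + h, c + w


@dataclass
class PatchScore:
    tissue_fraction: float
    cellularity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.tissue_fraction <= 1.0:
            raise ValueError("tissue_fraction must be in [0, 1]")
        if self.cellularity < 0:
            raise ValueError("cellularity must be >= 0")


@dataclass
class StainParams:
    """Macenko stain model: H&E optical-density unit vectors plus the
    99th-percentile concentration of each stain."""

    stain_matrix: np.ndarray  # 3x2, columns = hematoxylin, eosin
    max_concentrations: np.ndarray  # length 2
    od_floor: float = 0.15
    angle_percentile: float = 1.0

    def __post_init__(self) -> None:
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=float)
        if self.stain_matrix.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2")
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain columns must have unit norm")
        if (self.stain_matrix < -1e-9).any():
            raise ValueError("stain columns must be nonnegative")
        if (self.max_concentrations <= 0).any():
            raise ValueError("max_concentrations must be positive")


@dataclass
class FunnelConfig:
    max_random_patches: int = 500
    max_after_tissue: int = 200
    n_top_cellularity: int = 60
    tissue_threshold: float = 0.80
    patch_size: int = PATCH_SIZE
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_top_cellularity <= self.max_after_tissue <= self.max_random_patches):
            raise ValueError(
                "funnel caps must satisfy 0 < n_top <= max_after_tissue <= max_random_patches"
            )
        if not 0.0 <= self.tissue_threshold <= 1.0:
            raise ValueError("tissue_threshold must be in [0, 1]")


class InsufficientTissueError(ValueError):
    """Raised when a patch has too few optical-density pixels to fit stains."""


# ---------------------------------------------------------------------------
# patch extraction


def _intersects(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> bool:
    return a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]


def extract_patches(
    image: np.ndarray, cfg: FunnelConfig, parent_id: str = ""
) -> list[Patch]:
    """Random non-overlapping patches from one RGB image.

    Top-left corners are rejection-sampled on integer coordinates; a
    proposal overlapping an accepted patch is discarded. Sampling stops
    after ``max_random_patches`` acceptances or 10x that many failed
    proposals. Deterministic under ``cfg.seed``.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be HxWx3 RGB")
    h, w = image.shape[:2]
    ps = cfg.patch_size
    if h < ps or w < ps:
        warnings.warn(
            f"image {h}x{w} smaller than patch size {ps}; no patches extracted",
            stacklevel=2,
        )
        return []
    rng = spawn_rng(cfg.seed, "extract", parent_id)
    accepted: list[Patch] = []
    extents: list[tuple[int, int, int, int]] = []
    failures = 0
    max_failures = 10 * cfg.max_random_patches
    while len(accepted) < cfg.max_random_patches and failures < max_failures:
        r = int(rng.integers(0, h - ps + 1))
        c = int(rng.integers(0, w - ps + 1))
        ext = (r, c, r + ps, c + ps)
        if any(_intersects(ext, e) for e in extents):
            failures += 1
            continue
        extents.append(ext)
        accepted.append(
            Patch(
                pixels=np.ascontiguousarray(image[r : r + ps, c : c + ps]),
                origin=(r, c),
                parent_id=parent_id,
            )
        )
    return accepted


# ---------------------------------------------------------------------------
# scoring


def tissue_fraction(p: Patch) -> float:
    """Fraction of pixels classified as tissue rather than background glass.

    A pixel is background when it is bright and unsaturated: minimum
    channel >= 200 and (max - min) channel spread <= 30. H&E tissue is
    pink/purple (low green relative to red) and fails both conditions.
    """
    px = p.pixels.astype(np.int16)
    mn = px.min(axis=2)
    spread = px.max(axis=2) - mn
    background = (mn >= 200) & (spread <= 30)
    return float(1.0 - background.mean())


def default_cellularity_scorer(
    p: Patch, hematoxylin_threshold: float = 0.05, min_area_px: int = 20
) -> float:
    """Nuclei count by stain deconvolution.

    The patch is separated into H&E channels (color deconvolution), the
    hematoxylin channel is thresholded, and connected components above
    ``min_area_px`` are counted. On rendered fixtures with well-separated
    nuclei the score equals the true nucleus count.
    """
    hed = rgb2hed(p.pixels)
    mask = hed[:, :, 0] > hematoxylin_threshold
    labels = measure.label(mask, connectivity=2)
    count = 0
    for region in measure.regionprops(labels):
        if region.area >= min_area_px:
            count += 1
    return float(count)


def cellularity_score(
    p: Patch, scorer: Callable[[Patch], float] | None = None
) -> float:
    """Score a patch's nuclear content with ``scorer`` (default: stain
    deconvolution + component count). Scorer failures are re-raised with
    the patch's provenance attached."""
    scorer = scorer or default_cellularity_scorer
    try:
        return float(scorer(p))
    except InsufficientTissueError:
        raise
    except Exception as exc:  # attach provenance, keep original as cause
        raise RuntimeError(
            f"cellularity scorer failed on patch parent={p.parent_id!r} "
            f"origin={p.origin}"
        ) from exc


def run_funnel(
    patches: Sequence[Patch],
    cfg: FunnelConfig,
    scorer: Callable[[Patch], float] | None = None,
) -> list[Patch]:
    """Apply the tissue filter then the cellularity ranking.

    Stage 1 keeps patches with tissue fraction >= ``tissue_threshold``;
    if more than ``max_after_tissue`` survive, a uniform random subsample
    (under ``cfg.seed``) is taken. Stage 2 keeps the top
    ``n_top_cellularity`` by score, ties broken by origin row-major order.
    """
    patches = list(patches)[: cfg.max_random_patches]
    tissue = [p for p in patches if tissue_fraction(p) >= cfg.tissue_threshold]
    if not tissue:
        warnings.warn("no patches passed the tissue filter", stacklevel=2)
        return []
    if len(tissue) > cfg.max_after_tissue:
        rng = spawn_rng(cfg.seed, "tissue-cap")
        idx = rng.choice(len(tissue), size=cfg.max_after_tissue, replace=False)
        tissue = [tissue[i] for i in sorted(idx)]
    scored = [(cellularity_score(p, scorer), p) for p in tissue]
    order = sorted(
        range(len(scored)),
        key=lambda i: (-scored[i][0], scored[i][1].origin[0], scored[i][1].origin[1]),
    )
    keep = order[: cfg.n_top_cellularity]
    return [scored[i][1] for i in keep]


# ---------------------------------------------------------------------------
# Macenko stain normalization


def _od(pixels: np.ndarray) -> np.ndarray:
    """Optical density: OD = -log10((I + 1) / 256), flattened to Nx3."""
    i = pixels.reshape(-1, 3).astype(float)
    return -np.log10((i + 1.0) / 256.0)


def _nnls_2col(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Nonnegative least squares for a 3x2 system, vectorized over pixels.

    Exact active-set solution for two unknowns: solve unconstrained; for
    rows with a negative coefficient, fix it at 0 and solve the 1-D
    problem on the other column (clamped at 0).
    """
    # unconstrained: x = (A^T A)^-1 A^T b  for every pixel row of b (Nx3)
    ata = a.T @ a
    atb = b @ a  # N x 2
    x = np.linalg.solve(ata, atb.T).T  # N x 2
    neg0 = x[:, 0] < 0
    neg1 = x[:, 1] < 0
    # fix x0 = 0, solve for x1
    if neg0.any():
        x[neg0, 0] = 0.0
        x[neg0, 1] = np.maximum(0.0, b[neg0] @ a[:, 1] / (a[:, 1] @ a[:, 1]))
    if neg1.any():
        sel = neg1 & ~neg0
        x[sel, 1] = 0.0
        x[sel, 0] = np.maximum(0.0, b[sel] @ a[:, 0] / (a[:, 0] @ a[:, 0]))
    return x


def fit_stains(p: Patch, alpha: float = 1.0, beta: float = 0.15) -> StainParams:
    """Estimate hematoxylin/eosin OD vectors by the Macenko procedure.

    Pixels with all OD channels <= ``beta`` are discarded as glass. The
    remaining OD cloud is projected onto the plane of its top two
    singular vectors; the robust extreme directions at the ``alpha`` and
    ``100 - alpha`` angle percentiles become the stain vectors. Columns
    are ordered so hematoxylin is the one with the larger red-channel OD,
    then clipped to nonnegative and normalized to unit length.
    """
    od = _od(p.pixels)
    tissue = od[(od > beta).any(axis=1)]
    if tissue.shape[0] < 100:
        raise InsufficientTissueError(
            f"only {tissue.shape[0]} pixels above OD floor {beta}; need >= 100"
        )
    # plane of the top-2 right singular vectors of the centered-free OD cloud
    _, _, vt = np.linalg.svd(tissue, full_matrices=False)
    basis = vt[:2].T  # 3 x 2
    # orient basis so projections are predominantly positive
    for j in range(2):
        if (tissue @ basis[:, j]).sum() < 0:
            basis[:, j] = -basis[:, j]
    proj = tissue @ basis
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(angles, [alpha, 100.0 - alpha])
    v_lo = basis @ np.array([np.cos(lo), np.sin(lo)])
    v_hi = basis @ np.array([np.cos(hi), np.sin(hi)])
    # hematoxylin absorbs red more strongly -> larger red-channel OD
    if v_lo[0] >= v_hi[0]:
        stains = np.column_stack([v_lo, v_hi])
    else:
        stains = np.column_stack([v_hi, v_lo])
    stains = np.clip(stains, 0.0, None)
    norms = np.linalg.norm(stains, axis=0)
    if (norms <= 0).any():
        raise InsufficientTissueError("degenerate stain direction (zero norm)")
    stains = stains / norms
    conc = _nnls_2col(stains, tissue)
    max_c = np.percentile(conc, 99.0, axis=0)
    max_c = np.maximum(max_c, 1e-6)
    return StainParams(
        stain_matrix=stains,
        max_concentrations=max_c,
        od_floor=beta,
        angle_percentile=alpha,
    )


def macenko_normalize(p: Patch, ref: StainParams) -> Patch:
    """Re-render a patch in the reference stain space.

    Source stains are fitted, per-pixel concentrations solved by
    nonnegative least squares, scaled so the source's 99th-percentile
    concentration matches the reference's, and the image is rebuilt with
    the reference stain matrix.
    """
    src = fit_stains(p, alpha=ref.angle_percentile, beta=ref.od_floor)
    od = _od(p.pixels)
    conc = _nnls_2col(src.stain_matrix, od)  # N x 2
    scale = ref.max_concentrations / src.max_concentrations
    conc = conc * scale[None, :]
    od_new = conc @ ref.stain_matrix.T  # N x 3
    intensity = 256.0 * np.power(10.0, -od_new) - 1.0
    pixels = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)
    return Patch(
        pixels=pixels.reshape(p.pixels.shape),
        origin=p.origin,
        parent_id=p.parent_id,
        meta={**p.meta, "macenko_normalized": True},
    )


def forward_synthesize(
    params: StainParams,
    concentrations: np.ndarray,
    shape: tuple[int, int],
) -> Patch:
    """Render a patch from a stain matrix and per-pixel concentrations.

    The inverse of the OD model: I = 256 * 10^(-M c) - 1. Used as the
    round-trip oracle for the Macenko fit.
    """
    conc = np.asarray(concentrations, dtype=float)
    if conc.shape != (shape[0] * shape[1], 2):
        raise ValueError("concentrations must be (H*W) x 2")
    od = conc @ params.stain_matrix.T
    intensity = 256.0 * np.power(10.0, -od) - 1.0
    pixels = np.clip(np.rint(intensity), 0, 255).astype(np.uint8)
    return Patch(pixels=pixels.reshape(shape[0], shape[1], 3), meta={"synthetic": True})
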