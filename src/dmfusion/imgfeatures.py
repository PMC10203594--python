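"""Patient-level image features: pluggable per-patch extraction and
mean aggregation.

The study-level contract is a 32-dimensional feature vector per patch,
averaged over a patient's surviving patches into one
:class:`PatientFeatureVector` (weakly supervised: only patient-level
labels exist, so patch features are mean-pooled). Any callable honoring
the :class:`FeatureExtractor` interface can supply the per-patch
vectors; the default :class:`Handcrafted32` uses channel histograms,
intensity moments, a nuclear-stain fraction and an edge-density summary
— no pretrained weights, but enough signal to separate cellularity
classes in the synthetic cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
from skimage.color import rgb2gray, rgb2hed
from skimage.filters import sobel

from .wsiprep import Patch

__all__ = [
    "FeatureExtractor",
    "Handcrafted32",
    "ConstantExtractor",
    "PatientFeatureVector",
    "extract_features",
    "aggregate_patient",
    "write_patient_features",
]


@runtime_checkable
class FeatureExtractor(Protocol):
    """Maps a patch to a fixed-length finite real vector.

    Implementations must be deterministic for a fixed patch and return
    exactly ``dim`` values.
    """

    name: str
    dim: int

    def __call__(self, patch: Patch) -> np.ndarray: ...


class Handcrafted32:
    """Default 32-dim handcrafted extractor.

    Layout: 8-bin normalized intensity histogram per RGB channel (24),
    per-channel mean and SD scaled to [0, 1] (6), fraction of pixels
    above a hematoxylin optical-density threshold (1), mean Sobel edge
    magnitude (1).
    """

    name = "handcrafted32"
    dim = 32

    def __init__(self, hematoxylin_threshold: float = 0.05) -> None:
        self.hematoxylin_threshold = hematoxylin_threshold

    def __call__(self, patch: Patch) -> np.ndarray:
        px = patch.pixels
        feats: list[float] = []
        for c in range(3):
            hist, _ = np.histogram(px[:, :, c], bins=8, range=(0, 256))
            feats.extend(hist / hist.sum())
        for c in range(3):
            channel = px[:, :, c].astype(float)
            feats.append(channel.mean() / 255.0)
            feats.append(channel.std() / 255.0)
        hed = rgb2hed(px)
        feats.append(float((hed[:, :, 0] > self.hematoxylin_threshold).mean()))
        feats.append(float(sobel(rgb2gray(px)).mean()))
        return np.asarray(feats, dtype=float)


class ConstantExtractor:
    """Emits the same vector for every patch (testing stub)."""

    def __init__(self, vector: Sequence[float], name: str = "constant") -> None:
        self.vector = np.asarray(vector, dtype=float)
        self.dim = self.vector.size
        self.name = name

    def __call__(self, patch: Patch) -> np.ndarray:
        return self.vector.copy()


@dataclass
class PatientFeatureVector:
    patient_id: str
    values: np.ndarray
    n_patches: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_patches < 1:
            raise ValueError("n_patches must be >= 1")
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must be finite")


def extract_features(
    patches: Sequence[Patch], extractor: FeatureExtractor
) -> list[np.ndarray]:
    """One feature vector per patch; enforces the extractor's dim contract."""
    if not patches:
        raise ValueError("no patches supplied")
    out = []
    for p in patches:
        v = np.asarray(extractor(p), dtype=float)
        if v.shape != (extractor.dim,):
            raise ValueError(
                f"extractor {extractor.name!r} returned shape {v.shape}, "
                f"expected ({extractor.dim},)"
            )
        if not np.isfinite(v).all():
            raise ValueError(f"extractor {extractor.name!r} returned non-finite values")
        out.append(v)
    return out


def aggregate_patient(
    vectors: Sequence[np.ndarray], patient_id: str
) -> PatientFeatureVector:
    """Element-wise mean over a patient's patch vectors."""
    if not len(vectors):
        raise ValueError("cannot aggregate an empty vector list")
    arrs = [np.asarray(v, dtype=float) for v in vectors]
    dims = {a.shape for a in arrs}
    if len(dims) != 1:
        raise ValueError(f"vectors have unequal shapes: {sorted(dims)}")
    return PatientFeatureVector(
        patient_id=patient_id,
        values=np.mean(arrs, axis=0),
        n_patches=len(arrs),
    )


def write_patient_features(
    features: Sequence[PatientFeatureVector], path: str | Path
) -> None:
    """TSV: patient_id, f1..f<dim>, n_patches."""
    if not features:
        raise ValueError("no features to write")
    dim = features[0].values.size
    rows = []
    for f in features:
        row = {"patient_id": f.patient_id}
        row.update({f"f{i + 1}": f.values[i] for i in range(dim)})
        row["n_patches"] = f.n_patches
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
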