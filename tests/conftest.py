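"""Shared fixtures: small synthetic cohorts generated at session scope.

All fixtures are seeded; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dmfusion.exprprep import preprocess
from dmfusion.geneselect import SelectionConfig, select_genes
from dmfusion.imgfeatures import Handcrafted32, aggregate_patient, extract_features
from dmfusion.synthdata import ImageConfig, SyntheticConfig, generate_cohort

PLANTED_A = [3, 50, 90, 140, 190]


@pytest.fixture(scope="session")
def cohort_small():
    """48 samples x 200 genes, one cancer type, 5 planted genes at
    effect size 1.0, no image block."""
    cfg = SyntheticConfig(
        groups=[("A", 24, 24)],
        n_genes=200,
        planted={"A": PLANTED_A},
        effect_size=1.0,
        image=ImageConfig(patches_per_patient=0),
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def processed_small(cohort_small):
    m, _ = preprocess(cohort_small.expression)
    return m


@pytest.fixture(scope="session")
def ranking_small(processed_small):
    """Frequency ranking at the N=50 / K=10 desk-scale protocol."""
    cfg = SelectionConfig(
        n_iterations=50, top_k=10, n_select=10, trees_per_forest=100, seed=5
    )
    return select_genes(processed_small, cfg)


@pytest.fixture(scope="session")
def image_cohort():
    """24 patients with 4 patches each; moderate image signal."""
    cfg = SyntheticConfig(
        groups=[("A", 12, 12)],
        n_genes=100,
        planted={"A": list(range(5))},
        effect_size=1.0,
        image=ImageConfig(patches_per_patient=4),
        seed=9,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def patient_features(image_cohort):
    """Mean-aggregated 32-dim patient vectors from the image cohort."""
    extractor = Handcrafted32()
    rows = {
        pid: aggregate_patient(extract_features(plist, extractor), pid).values
        for pid, plist in image_cohort.patches.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"f{i + 1}" for i in range(extractor.dim)]
    return df.loc[image_cohort.expression.sample_ids]
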