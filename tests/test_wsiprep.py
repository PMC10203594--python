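"""Patch funnel, tissue/cellularity scoring, Macenko normalization."""

import numpy as np
import pytest

from dmfusion.synthdata import _GLASS_RGB, _TISSUE_RGB, render_patch
from dmfusion.wsiprep import (
    FunnelConfig,
    InsufficientTissueError,
    Patch,
    StainParams,
    cellularity_score,
    extract_patches,
    fit_stains,
    forward_synthesize,
    macenko_normalize,
    run_funnel,
    tissue_fraction,
)


def _uniform_patch(rgb, size=512):
    return Patch(pixels=np.full((size, size, 3), rgb, dtype=np.uint8))


class TestExtractPatches:
    def test_exact_fit_image_gives_single_origin_patch(self):
        img = np.zeros((512, 512, 3), dtype=np.uint8)
        patches = extract_patches(img, FunnelConfig(seed=1))
        assert len(patches) == 1
        assert patches[0].origin == (0, 0)

    def test_small_image_yields_empty_list_with_warning(self):
        img = np.zeros((100, 100, 3), dtype=np.uint8)
        with pytest.warns(UserWarning, match="smaller"):
            assert extract_patches(img, FunnelConfig(seed=1)) == []

    def test_patches_pairwise_disjoint_by_rectangle_check(self):
        img = np.zeros((1024, 1024, 3), dtype=np.uint8)
        patches = extract_patches(img, FunnelConfig(seed=2))
        assert 1 <= len(patches) <= 4
        exts = [p.extent() for p in patches]
        for i in range(len(exts)):
            for j in range(i + 1, len(exts)):
                a, b = exts[i], exts[j]
                overlap = a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]
                assert not overlap

    def test_deterministic_origins_under_seed(self):
        img = np.zeros((1500, 1500, 3), dtype=np.uint8)
        o1 = [p.origin for p in extract_patches(img, FunnelConfig(seed=3))]
        o2 = [p.origin for p in extract_patches(img, FunnelConfig(seed=3))]
        assert o1 == o2


class TestTissueFraction:
    def test_uniform_white_is_pure_glass(self):
        assert tissue_fraction(_uniform_patch(255)) == 0.0

    def test_half_painted_patch(self):
        px = np.full((512, 512, 3), _GLASS_RGB, dtype=np.uint8)
        px[:256, :, :] = _TISSUE_RGB.astype(np.uint8)  # paint exactly half
        assert tissue_fraction(Patch(pixels=px)) == pytest.approx(0.5, abs=0.02)

    def test_fully_painted_tissue(self):
        p = render_patch(density=20, seed=1)
        assert tissue_fraction(p) >= 0.98


class TestCellularity:
    def test_blank_glass_scores_zero(self):
        p = render_patch(density=0, glass=True, seed=1)
        assert cellularity_score(p) == 0.0

    def test_well_separated_nuclei_counted(self):
        p = render_patch(density=50, seed=2)
        assert cellularity_score(p) == pytest.approx(50, abs=5)

    def test_monotone_in_density_over_paired_seeds(self):
        wins = 0
        for seed in range(20):
            hi = cellularity_score(render_patch(density=80, seed=1000 + seed))
            lo = cellularity_score(render_patch(density=10, seed=2000 + seed))
            wins += hi > lo
        assert wins == 20

    def test_scorer_failure_carries_provenance(self):
        p = render_patch(density=5, seed=3)
        p.parent_id = "slide-7"

        def broken(_):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="slide-7"):
            cellularity_score(p, broken)


class TestFunnel:
    def test_glass_eliminated_tissue_retained(self):
        tissue = [render_patch(density=5, seed=100 + i) for i in range(10)]
        glass = [render_patch(density=0, glass=True, seed=200 + i) for i in range(20)]
        for i, p in enumerate(tissue + glass):
            p.origin = (i, 0)
        cfg = FunnelConfig(max_random_patches=50, max_after_tissue=30,
                           n_top_cellularity=30, seed=1)
        out = run_funnel(tissue + glass, cfg)
        assert len(out) == 10
        assert all(tissue_fraction(p) >= 0.8 for p in out)

    def test_caps_applied_in_order(self):
        patches = [render_patch(density=3, seed=300 + i) for i in range(30)]
        for i, p in enumerate(patches):
            p.origin = (i, 0)
        cfg = FunnelConfig(max_random_patches=50, max_after_tissue=20,
                           n_top_cellularity=10, seed=2)
        out = run_funnel(patches, cfg)
        assert len(out) == 10

    def test_below_caps_everything_survives(self):
        patches = [render_patch(density=4, seed=400 + i) for i in range(5)]
        for i, p in enumerate(patches):
            p.origin = (i, 0)
        out = run_funnel(patches, FunnelConfig(seed=3))
        assert len(out) == 5

    def test_all_glass_returns_empty_with_warning(self):
        glass = [render_patch(density=0, glass=True, seed=i) for i in range(3)]
        with pytest.warns(UserWarning, match="tissue"):
            assert run_funnel(glass, FunnelConfig(seed=4)) == []

    def test_deterministic_origin_list(self):
        patches = [render_patch(density=3, seed=500 + i) for i in range(25)]
        for i, p in enumerate(patches):
            p.origin = (i, 0)
        cfg = FunnelConfig(max_random_patches=30, max_after_tissue=15,
                           n_top_cellularity=8, seed=5)
        o1 = [p.origin for p in run_funnel(patches, cfg)]
        o2 = [p.origin for p in run_funnel(patches, cfg)]
        assert o1 == o2


def _reference_fixture(seed=0, size=128):
    """Patch forward-synthesized from known stain parameters.

    Thirds of the pixels are hematoxylin-dominant, eosin-dominant and
    mixed, so the robust angle percentiles can recover the true stain
    directions.
    """
    rng = np.random.default_rng(seed)
    m = np.array([[0.65, 0.07], [0.70, 0.99], [0.29, 0.11]])
    m = m / np.linalg.norm(m, axis=0)
    n = size * size
    k = n // 3
    ch = np.concatenate(
        [rng.uniform(0.4, 1.5, k), rng.uniform(0.0, 0.05, k), rng.uniform(0.2, 1.0, n - 2 * k)]
    )
    ce = np.concatenate(
        [rng.uniform(0.0, 0.05, k), rng.uniform(0.4, 1.2, k), rng.uniform(0.2, 0.8, n - 2 * k)]
    )
    conc = np.column_stack([ch, ce])
    ref = StainParams(
        stain_matrix=m, max_concentrations=np.percentile(conc, 99, axis=0)
    )
    return ref, forward_synthesize(ref, conc, (size, size))


class TestMacenko:
    def test_round_trip_reconstruction_error_small(self):
        ref, patch = _reference_fixture()
        normalized = macenko_normalize(patch, ref)
        mae = np.abs(
            normalized.pixels.astype(float) - patch.pixels.astype(float)
        ).mean()
        assert mae <= 2.0

    def test_fitted_stain_columns_unit_norm_and_nonnegative(self):
        _, patch = _reference_fixture(seed=1)
        params = fit_stains(patch)
        norms = np.linalg.norm(params.stain_matrix, axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)
        assert (params.stain_matrix >= 0).all()

    def test_fit_recovers_true_stain_vectors(self):
        ref, patch = _reference_fixture(seed=2)
        fitted = fit_stains(patch)
        np.testing.assert_allclose(
            fitted.stain_matrix, ref.stain_matrix, atol=0.02
        )

    def test_hematoxylin_column_has_larger_red_od(self):
        _, patch = _reference_fixture(seed=3)
        m = fit_stains(patch).stain_matrix
        assert m[0, 0] > m[0, 1]

    def test_uniform_white_raises_insufficient_tissue(self):
        with pytest.raises(InsufficientTissueError):
            fit_stains(_uniform_patch(255, size=128))

    def test_normalization_idempotent_within_tolerance(self):
        ref, patch = _reference_fixture(seed=4)
        once = macenko_normalize(patch, ref)
        twice = macenko_normalize(once, ref)
        mae = np.abs(twice.pixels.astype(float) - once.pixels.astype(float)).mean()
        assert mae <= 2.0

    def test_rendered_tissue_patch_fits_without_error(self):
        p = render_patch(density=40, seed=6)
        params = fit_stains(p)
        assert params.max_concentrations.shape == (2,)
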