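"""Clinical cleaning, block fusion and Monte-Carlo cross-validation."""

import numpy as np
import pandas as pd
import pytest

from dmfusion.fusion_eval import (
    CLINICAL_COLUMNS,
    FusionDataset,
    MCCVConfig,
    clean_clinical,
    evaluate_mccv,
    fuse,
    modality_report,
)


def _records(ages, t_stages=None, n_stages=None, nodes=None, cancer_type="A"):
    n = len(ages)
    return pd.DataFrame(
        {
            "patient_id": [f"p{i}" for i in range(n)],
            "cancer_type": [cancer_type] * n,
            "age": ages,
            "t_stage": t_stages if t_stages is not None else [2] * n,
            "n_stage": n_stages if n_stages is not None else [1] * n,
            "nodes_positive": nodes if nodes is not None else [1] * n,
        }
    )


class TestCleanClinical:
    def test_missing_age_imputed_with_rounded_group_mean(self):
        df = clean_clinical(_records([60.0, 70.0, np.nan, 40.0]))
        # mean of 60, 70, 40 = 56.67 -> 57; then min-max over [60,70,57,40]
        raw = np.array([60.0, 70.0, 57.0, 40.0])
        expected = (raw - raw.min()) / (raw.max() - raw.min())
        np.testing.assert_allclose(df["age"].to_numpy(), expected)

    def test_invalid_stage_and_nodes_become_zero(self):
        df = clean_clinical(
            _records(
                [60.0, 61.0],
                t_stages=["TX", 3],
                n_stages=[np.nan, 2],
                nodes=[np.nan, 4],
            )
        )
        assert df.loc[0, "t_stage"] == 0.0
        assert df.loc[0, "n_stage"] == 0.0
        assert df.loc[0, "nodes_positive"] == 0.0  # before scaling, min -> 0

    def test_min_max_normalization_of_age(self):
        df = clean_clinical(_records([50.0, 60.0, 70.0]))
        np.testing.assert_allclose(df["age"].to_numpy(), [0.0, 0.5, 1.0])

    def test_group_specific_imputation(self):
        recs = pd.concat(
            [
                _records([60.0, np.nan], cancer_type="A"),
                _records([80.0, 80.0], cancer_type="B"),
            ]
        ).reset_index(drop=True)
        recs["patient_id"] = [f"q{i}" for i in range(4)]
        df = clean_clinical(recs)
        # A's missing age -> 60 (A's mean), not the pooled mean
        ages_raw = np.array([60.0, 60.0, 80.0, 80.0])
        expected = (ages_raw - 60.0) / 20.0
        np.testing.assert_allclose(df["age"].to_numpy(), expected)

    def test_all_ages_missing_in_a_type_rejected(self):
        with pytest.raises(ValueError, match="non-missing"):
            clean_clinical(_records([np.nan, np.nan]))

    def test_explicit_group_means_override(self):
        df = clean_clinical(
            _records([np.nan, 50.0]), group_mean_ages={"A": 70.2}
        )
        # imputed 70 vs observed 50 -> normalized [1, 0]
        np.testing.assert_allclose(df["age"].to_numpy(), [1.0, 0.0])


class TestFuse:
    def _blocks(self, n=10, genomic_cols=50, image_cols=32, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"p{i}" for i in range(n)]
        return {
            "genomic": pd.DataFrame(
                rng.normal(size=(n, genomic_cols)), index=idx,
                columns=[f"G{j}" for j in range(genomic_cols)],
            ),
            "image": pd.DataFrame(
                rng.normal(size=(n, image_cols)), index=idx,
                columns=[f"f{j}" for j in range(image_cols)],
            ),
        }

    def test_panel_plus_image_width(self):
        fused = fuse(self._blocks(genomic_cols=50), ["genomic", "image"])
        assert fused.shape[1] == 82

    def test_three_panel_union_plus_image_width(self):
        fused = fuse(self._blocks(genomic_cols=150), ["genomic", "image"])
        assert fused.shape[1] == 182

    def test_single_block_identity(self):
        blocks = self._blocks()
        fused = fuse(blocks, ["genomic"])
        np.testing.assert_array_equal(fused.to_numpy(), blocks["genomic"].to_numpy())

    def test_column_provenance_recorded(self):
        fused = fuse(self._blocks(), ["genomic", "image"])
        assert fused.columns[0] == "genomic:G0"
        assert fused.columns[-1] == "image:f31"

    def test_row_count_mismatch_names_block(self):
        blocks = self._blocks()
        blocks["image"] = blocks["image"].iloc[:5]
        with pytest.raises(ValueError, match="image"):
            fuse(blocks, ["genomic", "image"])

    def test_duplicate_block_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            fuse(self._blocks(), ["genomic", "genomic"])

    def test_deleting_block_and_refusing_reproduces_remainder(self):
        blocks = self._blocks()
        full = fuse(blocks, ["genomic", "image"])
        genomic_only = fuse(blocks, ["genomic"])
        np.testing.assert_array_equal(
            full.loc[:, full.columns.str.startswith("genomic:")].to_numpy(),
            genomic_only.to_numpy(),
        )


class TestMCCV:
    def _xy(self, n=40, informative=True, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([0, 1] * (n // 2))
        x = rng.normal(size=(n, 6))
        if informative:
            x[y == 1, 0] += 2.5
        return x, y

    def test_identical_seed_identical_metrics(self):
        x, y = self._xy()
        cfg = MCCVConfig(n_splits=3, classifiers=("svm",), seed=7)
        m1 = evaluate_mccv(x, y, cfg)["svm"].as_dict()
        m2 = evaluate_mccv(x, y, cfg)["svm"].as_dict()
        assert m1 == m2

    def test_informative_data_beats_chance(self):
        x, y = self._xy(informative=True)
        out = evaluate_mccv(x, y, MCCVConfig(classifiers=("svm",), seed=1))
        assert out["svm"].auroc > 0.8

    def test_reports_one_fold_per_split_for_each_classifier(self):
        x, y = self._xy()
        out = evaluate_mccv(x, y, MCCVConfig(n_splits=4, seed=2))
        assert set(out) == {"svm", "mlp"}
        assert all(len(ms.per_fold) == 4 for ms in out.values())

    def test_split_stratification_within_one_sample(self):
        from dmfusion.fusion_eval import _mc_splits

        y = np.array([0] * 25 + [1] * 15)
        cfg = MCCVConfig(n_splits=5, test_fraction=0.2, seed=3)
        global_frac = y.mean()
        for tr, te in _mc_splits(y, cfg):
            for subset in (tr, te):
                observed = y[subset].sum()
                expected = global_frac * subset.size
                assert abs(observed - expected) <= 1

    def test_single_class_labels_rejected(self):
        x, _ = self._xy()
        with pytest.raises(ValueError):
            evaluate_mccv(x, np.zeros(40, dtype=int), MCCVConfig(seed=4))


class TestModalityReport:
    def test_six_combination_table_shape(self, image_cohort, patient_features):
        clinical = clean_clinical(image_cohort.clinical)
        clinical = clinical.set_index("patient_id").loc[
            image_cohort.expression.sample_ids
        ]
        rng = np.random.default_rng(0)
        genomic = pd.DataFrame(
            rng.normal(size=(24, 5)), index=image_cohort.expression.sample_ids
        )
        dataset = FusionDataset(
            blocks={
                "genomic": genomic,
                "image": patient_features,
                "clinical": clinical[CLINICAL_COLUMNS],
            },
            labels=image_cohort.expression.labels,
        )
        report = modality_report(
            dataset, MCCVConfig(n_splits=2, classifiers=("svm",), seed=5)
        )
        table = report["svm"]
        assert len(table) == 6
        assert list(table.columns) == [
            "mean_accuracy", "accuracy_sd", "mean_f1", "f1_sd",
            "mean_auroc", "auroc_sd",
        ]
        assert "Genomic + Image + Clinical" in table.index
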