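"""End-to-end orchestration: synthetic cohort -> expression
preprocessing -> gene selection -> panel benchmarking -> patch funnel ->
image features -> clinical cleaning -> late-fusion evaluation.

One master seed derives every stage seed by name, so a rerun with the
same config is bit-identical on all deterministic outputs. The run
emits a JSON manifest recording inputs, outputs, seeds and per-stage
counts; the manifest (minus its timestamp) is itself a determinism
check.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .exprprep import preprocess
from .fusion_eval import (
    CLINICAL_COLUMNS,
    FusionDataset,
    MCCVConfig,
    clean_clinical,
    modality_report,
)
from .geneselect import SelectionConfig, select_genes
from .imgfeatures import Handcrafted32, aggregate_patient, extract_features
from .panel_eval import PanelEvalConfig, cross_apply, evaluate_panel, overlap_table, union_panel
from .synthdata import SyntheticConfig, generate_cohort, write_cohort
from .wsiprep import FunnelConfig, run_funnel

__all__ = ["RunConfig", "run_pipeline", "load_run_config"]

ALL_STAGES = ("synth", "expr", "select", "panel", "images", "fusion")


@dataclass
class RunConfig:
    out_dir: str = "dmfusion-run"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    synth: SyntheticConfig = field(default_factory=SyntheticConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    panel: PanelEvalConfig = field(default_factory=PanelEvalConfig)
    funnel: FunnelConfig = field(default_factory=FunnelConfig)
    mccv: MCCVConfig = field(default_factory=MCCVConfig)
    write_patch_pngs: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file; nested keys map onto the
    stage config dataclasses."""
    import yaml

    from .synthdata import ImageConfig

    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    for key in ("out_dir", "seed", "write_patch_pngs"):
        if key in raw:
            kwargs[key] = raw[key]
    if "stages" in raw:
        kwargs["stages"] = tuple(raw["stages"])
    if "synth" in raw:
        synth = dict(raw["synth"])
        if "groups" in synth:
            synth["groups"] = [tuple(g) for g in synth["groups"]]
        if "image" in synth:
            synth["image"] = ImageConfig(**synth["image"])
        kwargs["synth"] = SyntheticConfig(**synth)
    for key, cls in (
        ("selection", SelectionConfig),
        ("panel", PanelEvalConfig),
        ("funnel", FunnelConfig),
        ("mccv", MCCVConfig),
    ):
        if key in raw:
            kwargs[key] = cls(**raw[key])
    return RunConfig(**kwargs)


def _metricset_dict(results) -> dict:
    return {f"{model}|{size}": r.cv.as_dict() for (model, size), r in results.items()}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages in dependency order; returns (and
    writes) the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "stages": list(cfg.stages),
        "outputs": {},
        "counts": {},
    }

    stages = set(cfg.stages)
    cohort = None
    if "synth" in stages:
        import dataclasses

        synth_cfg = dataclasses.replace(
            cfg.synth, seed=derive_seed(cfg.seed, "synth")
        )
        cohort = generate_cohort(synth_cfg)
        info = write_cohort(cohort, out / "cohort", write_patches=cfg.write_patch_pngs)
        # store paths relative to the run dir so manifests are location-free
        for key in ("expression", "clinical", "truth"):
            info[key] = str(Path(info[key]).relative_to(out))
        manifest["outputs"]["cohort"] = info
        manifest["counts"]["n_samples"] = info["n_samples"]
        manifest["counts"]["n_genes"] = info["n_genes"]

    needs_expr = stages & {"expr", "select", "panel", "fusion"}
    if needs_expr and cohort is None:
        raise RuntimeError("stage 'expr' and later require the 'synth' stage output")

    processed = None
    if needs_expr:
        processed, provenance = preprocess(cohort.expression)
        manifest["counts"]["expr_provenance"] = provenance

    panels: dict[str, list[str]] = {}
    if stages & {"select", "panel", "fusion"}:
        types = list(dict.fromkeys(cohort.expression.cancer_type))
        import dataclasses

        for ct in types:
            sub = processed.subset_samples(processed.cancer_type == ct)
            sel_cfg = dataclasses.replace(
                cfg.selection, seed=derive_seed(cfg.seed, "select", ct)
            )
            ranking = select_genes(sub, sel_cfg)
            panels[ct] = ranking.panel
            ranking.write_tsv(out / f"ranking_{ct}.tsv")
        if len(types) > 1:
            sel_cfg = dataclasses.replace(
                cfg.selection, seed=derive_seed(cfg.seed, "select", "ALL")
            )
            ranking_all = select_genes(processed, sel_cfg)
            panels["ALL"] = ranking_all.panel
            ranking_all.write_tsv(out / "ranking_ALL.tsv")
        manifest["outputs"]["panels"] = {
            ct: panel for ct, panel in panels.items()
        }
        manifest["counts"]["panel_sizes"] = {ct: len(p) for ct, p in panels.items()}

    if "panel" in stages:
        import dataclasses

        panel_metrics: dict = {}
        types = [ct for ct in panels if ct != "ALL"]
        for ct in types:
            sub = processed.subset_samples(processed.cancer_type == ct)
            p_cfg = dataclasses.replace(
                cfg.panel, seed=derive_seed(cfg.seed, "panel", ct)
            )
            own = evaluate_panel(sub, panels[ct], p_cfg)
            panel_metrics[ct] = {"own": _metricset_dict(own)}
            if "ALL" in panels:
                crossed = cross_apply(panels["ALL"], sub, p_cfg)
                panel_metrics[ct]["cross_ALL"] = _metricset_dict(crossed)
        if len(types) > 1:
            union = union_panel([panels[ct] for ct in types])
            manifest["counts"]["union_panel_size"] = len(union)
            manifest["outputs"]["overlap_table"] = overlap_table(
                {ct: panels[ct] for ct in panels}
            ).to_dict(orient="records")
        (out / "panel_metrics.json").write_text(json.dumps(panel_metrics, indent=2))
        manifest["outputs"]["panel_metrics"] = panel_metrics

    patient_features = None
    if "images" in stages:
        if not cohort.patches:
            raise RuntimeError("stage 'images' requires patches (patches_per_patient > 0)")
        import dataclasses

        extractor = Handcrafted32()
        rows = {}
        counts = []
        for pid, plist in cohort.patches.items():
            f_cfg = dataclasses.replace(
                cfg.funnel, seed=derive_seed(cfg.seed, "funnel", pid)
            )
            surviving = run_funnel(plist, f_cfg)
            if not surviving:
                surviving = plist  # flagged: nothing passed, fall back to all
            counts.append(len(surviving))
            vectors = extract_features(surviving, extractor)
            rows[pid] = aggregate_patient(vectors, pid).values
        patient_features = pd.DataFrame.from_dict(rows, orient="index")
        patient_features.columns = [f"f{i + 1}" for i in range(extractor.dim)]
        patient_features = patient_features.loc[cohort.expression.sample_ids]
        patient_features.to_csv(out / "patient_features.tsv", sep="\t")
        manifest["counts"]["patches_surviving_mean"] = float(np.mean(counts))
        manifest["outputs"]["patient_features"] = "patient_features.tsv"

    if "fusion" in stages:
        if patient_features is None:
            raise RuntimeError("stage 'fusion' requires the 'images' stage output")
        import dataclasses

        clinical = clean_clinical(cohort.clinical)
        clinical = clinical.set_index("patient_id").loc[cohort.expression.sample_ids]
        genomic_genes = union_panel(list(panels.values())) if len(panels) > 1 else list(panels.values())[0]
        genomic_genes = [g for g in genomic_genes if g in set(processed.gene_ids)]
        genomic = pd.DataFrame(
            processed.subset_genes(genomic_genes).values,
            index=processed.sample_ids,
            columns=genomic_genes,
        )
        dataset = FusionDataset(
            blocks={
                "genomic": genomic,
                "image": patient_features,
                "clinical": clinical[CLINICAL_COLUMNS],
            },
            labels=cohort.expression.labels,
        )
        m_cfg = dataclasses.replace(cfg.mccv, seed=derive_seed(cfg.seed, "fusion"))
        report = modality_report(dataset, m_cfg)
        tables = {name: df.reset_index().to_dict(orient="records") for name, df in report.items()}
        (out / "modality_report.json").write_text(json.dumps(tables, indent=2))
        for name, df in report.items():
            df.to_csv(out / f"modality_report_{name}.tsv", sep="\t")
        manifest["outputs"]["modality_report"] = tables
        manifest["counts"]["modality_rows"] = {
            name: len(df) for name, df in report.items()
        }

    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
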