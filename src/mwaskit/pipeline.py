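"""End-to-end orchestration: QC -> classify -> adjust -> PLS-DA select ->
associate -> enrich, on in-memory objects.  The CLI wraps this module with
file I/O; tests drive it directly."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import adjust, association, pathway, plsda, qc
from .core_io import FeatureTable, Mode, PathwayDB, SampleRecord
from .exposure import ExposureCall, ExposureRule, classify_from_table
from .synthetic import SimResult

__all__ = ["PipelineParams", "ModeResult", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineParams:
    qc_thresholds: qc.QcThresholds = field(default_factory=qc.QcThresholds)
    exposure_rule: ExposureRule = field(default_factory=ExposureRule)
    n_components: int = 2
    vip_cutoff: float = 2.0
    enrich: pathway.EnrichConfig = field(default_factory=pathway.EnrichConfig)
    associate_all_features: bool = False  # selected-only (default) or every feature
    run_enrichment: bool = True
    run_association: bool = True


@dataclass
class ModeResult:
    mode: Mode
    qc_report: pd.DataFrame
    retained_ids: list[str]
    processed: pd.DataFrame  # imputed, auto-scaled features x samples
    scale_sd: pd.Series  # auto-scaling sd per feature (log2-scale backmap)
    adjusted: pd.DataFrame  # residualized matrix
    excluded: list[str]  # biomarker features passed through unadjusted
    model: plsda.PlsdaModel | None
    selection: pd.DataFrame  # per feature: vip, selected, fold_change
    associations: pd.DataFrame | None
    enrichment: list[pathway.EnrichmentResult]


@dataclass
class PipelineResult:
    calls: list[ExposureCall]
    modes: dict[Mode, ModeResult]
    manifest: dict


def _run_mode(
    table: FeatureTable,
    samples: list[SampleRecord],
    smoker: np.ndarray,
    biomarker_ids: set[str],
    pathway_db: PathwayDB | None,
    params: PipelineParams,
) -> ModeResult:
    filtered, report = qc.apply_qc(table, params.qc_thresholds)
    summarized = qc.summarize_replicates(filtered)
    transform = qc.log2_batch_center_autoscale(summarized, filtered.sample_batches)
    complete = qc.knn_impute(transform.values, k=params.qc_thresholds.knn_k)

    design = adjust.build_design(samples)
    adjusted, excluded = adjust.residualize(
        complete, design, exclude=biomarker_ids & set(complete.index)
    )

    discoverable = [f for f in adjusted.index if f not in biomarker_ids]
    X = adjusted.loc[discoverable].to_numpy().T
    model = plsda.fit_plsda(
        X, smoker.astype(float), n_components=params.n_components, feature_ids=discoverable
    )
    vip = pd.Series(model.vip_, index=discoverable)
    # backmap residuals to the log2 scale before computing fold changes
    log2_adjusted = adjusted.loc[discoverable].mul(
        transform.sd.reindex(discoverable), axis=0
    )
    fc = plsda.fold_change(log2_adjusted, smoker)
    meta = report.loc[discoverable, ["mz", "rt"]]
    selection = pd.DataFrame(
        {
            "mz": meta["mz"],
            "rt": meta["rt"],
            "vip": vip,
            "selected": vip >= params.vip_cutoff,
            "fold_change": fc,
        },
        index=pd.Index(discoverable, name="feature_id"),
    )
    selected_ids = list(selection.index[selection["selected"]])

    associations = None
    if params.run_association:
        assoc_ids = discoverable if params.associate_all_features else selected_ids
        if assoc_ids:
            associations = association.associate(
                smoker.astype(float),
                adjusted.loc[assoc_ids],
                meta=selection.loc[assoc_ids, ["mz", "rt", "vip", "fold_change"]],
            )
            associations["mode"] = table.mode.value

    enrichment: list[pathway.EnrichmentResult] = []
    if params.run_enrichment and pathway_db is not None and selected_ids:
        mz_of = dict(zip(report.index, report["mz"]))
        enrichment = pathway.enrich(
            selected_ids,
            [mz_of[f] for f in discoverable],
            discoverable,
            pathway_db,
            table.mode,
            params.enrich,
        )

    return ModeResult(
        mode=table.mode,
        qc_report=report,
        retained_ids=filtered.feature_ids,
        processed=complete,
        scale_sd=transform.sd,
        adjusted=adjusted,
        excluded=excluded,
        model=model,
        selection=selection,
        associations=associations,
        enrichment=enrichment,
    )


def run_pipeline(sim: SimResult, params: PipelineParams = PipelineParams()) -> PipelineResult:
    """Run every stage on a simulated (or equivalently loaded) study."""
    calls = classify_from_table(sim.hilic, sim.samples, params.exposure_rule)
    smoker = np.array([c.smoker for c in calls])
    if smoker.all() or not smoker.any():
        raise ValueError("exposure classification produced a single class")

    biomarker_ids = set(sim.truth.get("biomarker_features", {}).values())
    modes: dict[Mode, ModeResult] = {}
    for table in (sim.hilic, sim.c18):
        modes[table.mode] = _run_mode(
            table, sim.samples, smoker, biomarker_ids, sim.pathway_db, params
        )

    manifest = {
        "n_samples": len(sim.samples),
        "n_smokers": int(smoker.sum()),
        "stages": {
            m.value: {
                "n_features_input": len(res.qc_report),
                "n_features_post_qc": len(res.retained_ids),
                "n_features_processed": len(res.processed),
                "n_selected": int(res.selection["selected"].sum()),
                "n_enriched_pathways": len(res.enrichment),
            }
            for m, res in modes.items()
        },
    }
    return PipelineResult(calls=calls, modes=modes, manifest=manifest)
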