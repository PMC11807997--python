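"""End-to-end orchestration of the staging analysis.

Runs, in order: QC CV filtering and group-wise KNN imputation per ion mode;
an overall PLS-DA per mode; per pairwise comparison an OPLS-DA screen
(VIP / Wilcoxon p / fold change), optional permutation validation, pathway
over-representation, and the key-panel + logistic staging model with
resampling validation; plus the cohort-description table. Every stage's
output is a plain dataclass/DataFrame so drivers can serialise what they
need.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .io import (
    FeatureTable, SampleMetadata, PathwayMap, Comparison, COMPARISONS,
)
from .config import PipelineConfig
from .preprocess import preprocess_table, QCFilterReport, ImputationReport
from .latent import autoscale, fit_plsda, PLSModel, permutation_test, PermutationResult
from .screen import screen_comparison, ComparisonScreen
from .enrich import enrich, enrichment_frame, EnrichmentResult
from .staging import stage_comparison, StagingOutputs
from .cohortstats import cohort_table


@dataclass
class PipelineResult:
    config: PipelineConfig
    tables: dict[str, FeatureTable]                    # preprocessed, per mode
    qc_reports: dict[str, QCFilterReport]
    imputation_reports: dict[str, ImputationReport]
    plsda: dict[str, PLSModel]
    screens: dict[str, ComparisonScreen]
    permutations: dict[str, dict[str, PermutationResult]]
    enrichments: dict[str, list[EnrichmentResult]]
    staging: dict[str, StagingOutputs]
    cohort: pd.DataFrame
    comparisons: tuple[Comparison, ...] = COMPARISONS


def run_pipeline(table_neg: FeatureTable, table_pos: FeatureTable,
                 metadata: SampleMetadata, pmap: PathwayMap,
                 config: PipelineConfig | None = None,
                 run_permutations: bool = True,
                 plsda_components: int = 2) -> PipelineResult:
    config = config or PipelineConfig()
    tables: dict[str, FeatureTable] = {}
    qc_reports: dict[str, QCFilterReport] = {}
    imp_reports: dict[str, ImputationReport] = {}
    for raw in (table_neg, table_pos):
        clean, qc_rep, imp_rep = preprocess_table(
            raw, metadata, config.cv_threshold, config.knn_fraction)
        tables[raw.ion_mode] = clean
        qc_reports[raw.ion_mode] = qc_rep
        imp_reports[raw.ion_mode] = imp_rep

    plsda: dict[str, PLSModel] = {}
    for mode, table in tables.items():
        X = autoscale(table.data.T, config.log_transform)
        labels = metadata.groups.loc[table.sample_ids].to_numpy()
        plsda[mode] = fit_plsda(X, labels, plsda_components)

    screens: dict[str, ComparisonScreen] = {}
    permutations: dict[str, dict[str, PermutationResult]] = {}
    enrichments: dict[str, list[EnrichmentResult]] = {}
    staging: dict[str, StagingOutputs] = {}
    annotated = pmap.annotated_ids()
    for comp in COMPARISONS:
        scr = screen_comparison(tables["negative"], tables["positive"],
                                metadata, comp, config, compute_q2=True)
        screens[comp.name] = scr
        if run_permutations:
            permutations[comp.name] = {}
            for mode, table in tables.items():
                ids = (set(metadata.ids_in_group(comp.case_group))
                       | set(metadata.ids_in_group(comp.reference_group)))
                sub = table.subset_samples(sorted(s for s in table.sample_ids if s in ids))
                labels = metadata.groups.loc[sub.sample_ids].to_numpy()
                permutations[comp.name][mode] = permutation_test(
                    sub.data.T, labels, config.n_ortho,
                    n_perm=config.n_permutations, seed=config.seed,
                    folds=config.cv_folds, log_transform=config.log_transform,
                    case_group=comp.case_group,
                )
        background = sorted(
            (set(tables["negative"].feature_ids) | set(tables["positive"].feature_ids))
            & annotated
        )
        diff_annotated = sorted(set(scr.differential_ids) & set(background))
        enrichments[comp.name] = enrich(diff_annotated, background, pmap)
        staging[comp.name] = stage_comparison(
            scr, tables["negative"], tables["positive"], metadata, comp,
            enrichment=enrichments[comp.name], config=config, seed=config.seed,
        )

    cohort = cohort_table(metadata)
    return PipelineResult(
        config=config, tables=tables, qc_reports=qc_reports,
        imputation_reports=imp_reports, plsda=plsda, screens=screens,
        permutations=permutations, enrichments=enrichments,
        staging=staging, cohort=cohort,
    )


def write_results(result: PipelineResult, outdir) -> None:
    """Serialise every stage's tables under ``outdir`` as TSV/JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for mode, rep in result.qc_reports.items():
        pd.DataFrame({
            "feature_id": rep.cv.index, "qc_cv": rep.cv.values,
            "retained": [f in set(rep.retained) for f in rep.cv.index],
        }).to_csv(outdir / f"qc_filter_{mode}.tsv", sep="\t", index=False)
    for comp, scr in result.screens.items():
        scr.to_frame().to_csv(outdir / f"screen_{comp}.tsv", sep="\t", index=False)
        scr.top_regulated().to_csv(outdir / f"top15_{comp}.tsv", sep="\t", index=False)
    for comp, res in result.enrichments.items():
        enrichment_frame(res).to_csv(outdir / f"enrichment_{comp}.tsv",
                                     sep="\t", index=False)
    model_summary = []
    for comp, scr in result.screens.items():
        for mode, model in scr.models.items():
            row = {"comparison": comp, "ion_mode": mode,
                   "r2x_pred": model.r2x_pred, "r2x_ortho": model.r2x_ortho,
                   "r2y": model.r2y, "q2": model.q2,
                   "n_up": scr.summary.per_mode[mode]["up"],
                   "n_down": scr.summary.per_mode[mode]["down"]}
            perm = result.permutations.get(comp, {}).get(mode)
            if perm is not None:
                row["perm_p_r2"] = perm.p_r2
                row["perm_p_q2"] = perm.p_q2
            model_summary.append(row)
    pd.DataFrame(model_summary).to_csv(outdir / "oplsda_summary.tsv",
                                       sep="\t", index=False)
    for comp, stg in result.staging.items():
        pd.DataFrame(stg.panel.features, columns=["feature_id", "importance"]) \
            .to_csv(outdir / f"key_panel_{comp}.tsv", sep="\t", index=False)
        stg.probabilities.to_csv(outdir / f"probabilities_{comp}.tsv",
                                 sep="\t", index=False)
        pd.DataFrame({"fpr": stg.roc.fpr, "tpr": stg.roc.tpr}) \
            .to_csv(outdir / f"roc_{comp}.tsv", sep="\t", index=False)
        pd.DataFrame({"test_auc": stg.resampling.test_auc,
                      "test_accuracy": stg.resampling.test_accuracy}) \
            .to_csv(outdir / f"resampling_{comp}.tsv", sep="\t", index=False)
        with open(outdir / f"staging_model_{comp}.json", "w") as fh:
            json.dump({
                "comparison": comp,
                "case_group": stg.model.case_group,
                "feature_ids": stg.model.feature_ids,
                "coefficients": list(map(float, stg.model.coefficients)),
                "intercept": stg.model.intercept,
                "combined_auc": stg.roc.auc,
                "per_feature_auc": stg.per_feature_auc,
                "resampling_mean_auc": stg.resampling.mean_auc,
                "resampling_mean_accuracy": stg.resampling.mean_accuracy,
            }, fh, indent=2)
    result.cohort.to_csv(outdir / "cohort_table.tsv", sep="\t", index=False)
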