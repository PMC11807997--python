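"""Differential-metabolite screening: VIP, Wilcoxon rank-sum p, fold change.

A feature is called differential for a pairwise stage comparison when all
three criteria hold simultaneously: VIP > 1 on the predictive OPLS-DA
component, two-sided Wilcoxon rank-sum p < 0.05, and fold change outside
the [0.8, 1.25] band (all inequalities strict). Fold change is the ratio of
raw-intensity group means with the later disease stage in the numerator, so
"up" means elevated in the more advanced group. Raw p-values drive the
call, mirroring the screening protocol; a Benjamini-Hochberg adjusted
column is emitted for information only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FeatureTable, SampleMetadata, Comparison
from .config import PipelineConfig
from .latent import autoscale, fit_oplsda, q2_cross_validate, OPLSModel


def wilcoxon_rank_sum(values_case, values_ref) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact enumeration when both groups have <= 8 observations and there are
    no ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    case = np.asarray(values_case, dtype=float)
    ref = np.asarray(values_ref, dtype=float)
    if case.size < 2 or ref.size < 2:
        raise ValueError("both groups need at least 2 values")
    pooled = np.concatenate([case, ref])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (case.size <= 8 and ref.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(case, ref, alternative="two-sided",
                             method=method, use_continuity=True)
    return float(res.pvalue)


def fold_change(values_case, values_ref) -> float:
    """Arithmetic mean(case) / mean(reference) on raw intensities.

    Returns NaN (record flagged non-significant downstream) when the
    reference mean is zero.
    """
    mean_case = float(np.mean(values_case))
    mean_ref = float(np.mean(values_ref))
    if mean_ref == 0:
        return float("nan")
    return mean_case / mean_ref


@dataclass
class DifferentialRecord:
    feature_id: str
    ion_mode: str
    comparison: str
    vip: float
    p_value: float
    fold_change: float
    status: str = "ns"  # {"up", "down", "ns"}

    @property
    def log2_fc(self) -> float:
        fc = self.fold_change
        return float(np.log2(fc)) if fc and fc > 0 and np.isfinite(fc) else float("nan")


def classify_status(vip: float, p: float, fc: float,
                    config: PipelineConfig) -> str:
    """Conjunctive up/down/ns call with strict inequalities at every
    threshold (VIP > 1, p < 0.05, FC > 1.25 or FC < 0.8)."""
    if not np.isfinite(fc):
        return "ns"
    if vip > config.vip_threshold and p < config.p_threshold:
        if fc > config.fc_high:
            return "up"
        if fc < config.fc_low:
            return "down"
    return "ns"


@dataclass
class ScreenSummary:
    comparison: str
    n_up: int
    n_down: int
    n_ns: int
    n_total: int
    per_mode: dict[str, dict[str, int]]


@dataclass
class ComparisonScreen:
    """Full screening output for one pairwise comparison."""

    comparison: str
    records: list[DifferentialRecord]
    summary: ScreenSummary
    models: dict[str, OPLSModel]  # ion mode -> fitted OPLS-DA

    @property
    def differential_ids(self) -> list[str]:
        return [r.feature_id for r in self.records if r.status != "ns"]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [{
                "feature_id": r.feature_id,
                "ion_mode": r.ion_mode,
                "comparison": r.comparison,
                "vip": r.vip,
                "p_value": r.p_value,
                "fold_change": r.fold_change,
                "log2_fc": r.log2_fc,
                "status": r.status,
            } for r in self.records]
        )
        with np.errstate(divide="ignore"):
            df["neg_log10_p"] = -np.log10(df["p_value"])
        df["bh_adjusted_p"] = multipletests(df["p_value"], method="fdr_bh")[1]
        return df

    def top_regulated(self, n: int = 15) -> pd.DataFrame:
        """Top-n up and top-n down significant features by |log2 FC|
        (the bar-chart companion of the volcano plot)."""
        df = self.to_frame()
        sig = df[df["status"] != "ns"].copy()
        sig["abs_log2_fc"] = sig["log2_fc"].abs()
        parts = []
        for status in ("up", "down"):
            parts.append(
                sig[sig["status"] == status]
                .sort_values(["abs_log2_fc", "feature_id"], ascending=[False, True])
                .head(n)
            )
        return pd.concat(parts, ignore_index=True).drop(columns="abs_log2_fc")


def screen_comparison(table_neg: FeatureTable, table_pos: FeatureTable,
                      metadata: SampleMetadata, comparison: Comparison,
                      config: PipelineConfig | None = None,
                      compute_q2: bool = False) -> ComparisonScreen:
    """Run the three-criterion screen for one stage comparison.

    An OPLS-DA model is fitted per ion mode independently (VIP source); the
    Wilcoxon test and fold change use the raw intensities of the two groups.
    Records from both modes are merged (feature ids carry their mode
    prefix). Ordering of features and samples in the inputs does not affect
    the records.
    """
    config = config or PipelineConfig()
    case_ids = metadata.ids_in_group(comparison.case_group)
    ref_ids = metadata.ids_in_group(comparison.reference_group)
    if not case_ids or not ref_ids:
        raise ValueError(
            f"comparison {comparison.name}: group(s) absent from metadata"
        )
    records: list[DifferentialRecord] = []
    models: dict[str, OPLSModel] = {}
    per_mode: dict[str, dict[str, int]] = {}
    for table in (table_neg, table_pos):
        sub = table.subset_samples(
            [s for s in table.sample_ids if s in set(case_ids) | set(ref_ids)]
        )
        if sub.missing_mask.any():
            raise ValueError("screen requires preprocessed (complete) tables")
        labels = np.array(
            [comparison.case_group if s in set(case_ids) else comparison.reference_group
             for s in sub.sample_ids]
        )
        # canonical sample order so input column order cannot matter
        order = np.argsort(np.asarray(sub.sample_ids, dtype=object))
        mat = sub.data.T.iloc[order]
        labels = labels[order]
        X = autoscale(mat.sort_index(axis=1), config.log_transform)
        model = fit_oplsda(X, labels, config.n_ortho,
                           case_group=comparison.case_group)
        if compute_q2:
            model.q2 = q2_cross_validate(
                mat.sort_index(axis=1), labels, config.n_ortho,
                config.cv_folds, config.seed, config.log_transform,
                case_group=comparison.case_group,
            )
        models[table.ion_mode] = model
        vip_by_feature = dict(zip(X.feature_ids, model.vip))
        mode_counts = {"up": 0, "down": 0, "ns": 0}
        for fid in table.feature_ids:
            case_vals = sub.data.loc[fid, [s for s in sub.sample_ids if s in set(case_ids)]]
            ref_vals = sub.data.loc[fid, [s for s in sub.sample_ids if s in set(ref_ids)]]
            p = wilcoxon_rank_sum(case_vals, ref_vals)
            fc = fold_change(case_vals, ref_vals)
            vip = float(vip_by_feature[fid])
            status = classify_status(vip, p, fc, config)
            mode_counts[status] += 1
            records.append(DifferentialRecord(
                feature_id=fid, ion_mode=table.ion_mode,
                comparison=comparison.name, vip=vip, p_value=p,
                fold_change=fc, status=status,
            ))
        per_mode[table.ion_mode] = mode_counts
    records.sort(key=lambda r: r.feature_id)
    n_up = sum(r.status == "up" for r in records)
    n_down = sum(r.status == "down" for r in records)
    summary = ScreenSummary(
        comparison=comparison.name, n_up=n_up, n_down=n_down,
        n_ns=len(records) - n_up - n_down, n_total=len(records),
        per_mode=per_mode,
    )
    return ComparisonScreen(comparison.name, records, summary, models)
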