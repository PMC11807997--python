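"""Synthetic three-stage urine-metabolomics cohorts with planted ground truth.

The generator emulates the design of a staged cohort study — CN, MCI and AD
groups of configurable size (defaults 62/43/57), two independent ion-mode
feature tables, pooled-QC replicate injections with per-feature technical
variability, log-normal feature intensities, differential features planted
with specified fold changes for specific pairwise comparisons,
intensity-dependent plus completely-random missingness, and a pathway map
whose "enriched" pathways are stacked with planted features — and records
everything it planted in a :class:`SyntheticTruth` registry so that every
downstream pipeline stage becomes a recoverable-parameter test.

Model
-----
Each feature ``i`` draws a baseline log-intensity ``mu_i ~ N(baseline_log_mean,
feature_log_spread)`` (natural-log scale). A biological sample in group ``g``
observes ``exp(N(mu_i + delta_ig, baseline_log_sd))`` where ``delta_ig`` is 0
except for planted effects, which add ``ln(FC)`` to the case group of their
comparison so the ratio of group means equals FC in expectation. Pooled-QC
replicates are log-normal around the pooled biological mean with the
feature's technical CV held exactly (mean-preserving parameterisation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    FeatureTable,
    SampleMetadata,
    PathwayMap,
    Comparison,
    COMPARISONS,
    GROUPS,
    DEFAULT_SEED,
)


@dataclass(frozen=True)
class PlantedEffect:
    """One planted differential feature: multiplicative FC on the raw scale
    between the case and reference group of ``comparison``."""

    feature_id: str
    comparison: str  # e.g. "CN-AD"
    fold_change: float


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort.

    Intensity parameters are on the natural-log scale; ``technical_cv_*``
    describe the per-feature QC coefficient-of-variation distribution: a
    fraction ``frac_high_cv`` of non-planted features draw their CV uniformly
    from ``technical_cv_high`` (these are the features a 30% QC-CV filter
    should remove), the rest from ``technical_cv_low``.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"CN": 62, "MCI": 43, "AD": 57}
    )
    n_features_neg: int = 80
    n_features_pos: int = 120
    n_qc: int = 20
    baseline_log_mean: float = 13.0
    baseline_log_sd: float = 0.4
    feature_log_spread: float = 1.0
    technical_cv_low: tuple[float, float] = (0.05, 0.25)
    technical_cv_high: tuple[float, float] = (0.35, 0.60)
    frac_high_cv: float = 0.05
    planted_effects: list[PlantedEffect] | None = None  # None -> defaults
    missing_rate_random: float = 0.02
    missing_intensity_quantile: float = 0.05
    missing_low_prob: float = 0.5
    n_pathways: int = 12
    pathway_size: int = 10
    n_enriched_pathways: int = 3
    enriched_fraction: float = 0.8
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"group_sizes: unknown group {g!r}")
            if n <= 0:
                raise ValueError(f"group_sizes[{g}] must be > 0")
        for name in ("n_features_neg", "n_features_pos", "n_qc", "n_pathways", "pathway_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("missing_rate_random", "missing_intensity_quantile",
                     "missing_low_prob", "frac_high_cv", "enriched_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.baseline_log_sd < 0 or self.feature_log_spread < 0:
            raise ValueError("log-scale spreads must be non-negative")
        if self.planted_effects is None:
            self.planted_effects = default_planted_effects(
                self.n_features_neg, self.n_features_pos
            )
        ids = set(feature_ids(self.n_features_neg, self.n_features_pos))
        for eff in self.planted_effects:
            if eff.fold_change <= 0:
                raise ValueError(
                    f"planted_effects: fold_change must be > 0 for {eff.feature_id}"
                )
            Comparison.from_name(eff.comparison)  # validates the contrast
            if eff.feature_id not in ids:
                raise ValueError(f"planted_effects: unknown feature {eff.feature_id!r}")
        if self.n_enriched_pathways > self.n_pathways:
            raise ValueError("n_enriched_pathways exceeds n_pathways")


def feature_ids(n_neg: int, n_pos: int) -> list[str]:
    neg = [f"neg_f{i:03d}" for i in range(n_neg)]
    pos = [f"pos_f{i:03d}" for i in range(n_pos)]
    return neg + pos


def default_planted_effects(n_neg: int, n_pos: int) -> list[PlantedEffect]:
    """20 planted features per pairwise comparison (10 up at FC 2.0, 10 down
    at FC 0.5), split between ion modes proportionally and disjoint across
    comparisons."""
    ids = feature_ids(n_neg, n_pos)
    neg_per, pos_per = 8, 12  # 20 per comparison
    need = 3 * neg_per, 3 * pos_per
    if n_neg < need[0] or n_pos < need[1]:
        raise ValueError(
            f"default planted effects need >= {need[0]} negative and "
            f"{need[1]} positive features"
        )
    effects: list[PlantedEffect] = []
    for c_idx, comp in enumerate(COMPARISONS):
        block = ids[c_idx * neg_per:(c_idx + 1) * neg_per] + [
            ids[n_neg + c_idx * pos_per + j] for j in range(pos_per)
        ]
        half = len(block) // 2
        for fid in block[:half]:
            effects.append(PlantedEffect(fid, comp.name, 2.0))
        for fid in block[half:]:
            effects.append(PlantedEffect(fid, comp.name, 0.5))
    return effects


@dataclass
class SyntheticTruth:
    """Registry of everything the generator planted."""

    differential_features: dict[str, dict[str, float]]  # comparison -> {fid: FC}
    enriched_pathways: dict[str, str]  # pathway_id -> comparison it is enriched for
    qc_excluded_features: set[str]  # features generated with technical CV > 0.30
    technical_cv: dict[str, float]

    @property
    def enriched_pathway_ids(self) -> set[str]:
        return set(self.enriched_pathways)

    def planted_ids(self, comparison: str | None = None) -> set[str]:
        if comparison is not None:
            return set(self.differential_features.get(comparison, {}))
        out: set[str] = set()
        for d in self.differential_features.values():
            out |= set(d)
        return out

    def to_json_dict(self) -> dict:
        return {
            "differential_features": self.differential_features,
            "enriched_pathways": self.enriched_pathways,
            "qc_excluded_features": sorted(self.qc_excluded_features),
            "technical_cv": self.technical_cv,
        }


def _draw_technical_cv(spec: CohortSpec, ids: list[str], planted: set[str],
                       rng: np.random.Generator) -> pd.Series:
    """Per-feature technical CV; only non-planted features may draw a
    high (filter-worthy) CV so planted effects survive preprocessing."""
    cv = pd.Series(
        rng.uniform(*spec.technical_cv_low, size=len(ids)), index=ids
    )
    eligible = [f for f in ids if f not in planted]
    n_high = int(round(spec.frac_high_cv * len(eligible)))
    if n_high:
        high = rng.choice(len(eligible), size=n_high, replace=False)
        for k in high:
            cv.loc[eligible[k]] = rng.uniform(*spec.technical_cv_high)
    return cv


def _simulate_mode(spec: CohortSpec, mode: str, ids: list[str],
                   sample_ids: list[str], groups: pd.Series,
                   cv: pd.Series, rng: np.random.Generator) -> FeatureTable:
    """Biological intensities + QC replicates + missingness for one ion mode."""
    n_f, n_s = len(ids), len(sample_ids)
    mu = rng.normal(spec.baseline_log_mean, spec.feature_log_spread, size=n_f)
    # per-feature, per-group log offsets realising the planted fold changes
    offset = pd.DataFrame(0.0, index=ids, columns=list(GROUPS))
    for eff in spec.planted_effects:
        if eff.feature_id in offset.index:
            comp = Comparison.from_name(eff.comparison)
            offset.loc[eff.feature_id, comp.case_group] = (
                offset.loc[eff.feature_id, comp.reference_group]
                + math.log(eff.fold_change)
            )
    log_means = np.empty((n_f, n_s))
    for j, sid in enumerate(sample_ids):
        log_means[:, j] = mu + offset[groups[sid]].to_numpy()
    bio = np.exp(rng.normal(log_means, spec.baseline_log_sd))
    table = pd.DataFrame(bio, index=ids, columns=sample_ids)

    # missingness on biological samples: left-censoring below a low-intensity
    # quantile plus completely-at-random dropout
    flat = table.to_numpy()
    thresh = np.quantile(flat, spec.missing_intensity_quantile)
    low = (flat < thresh) & (rng.uniform(size=flat.shape) < spec.missing_low_prob)
    mcar = rng.uniform(size=flat.shape) < spec.missing_rate_random
    flat[low | mcar] = np.nan
    table = pd.DataFrame(flat, index=ids, columns=sample_ids)

    ft = FeatureTable(mode, table)
    return generate_qc_replicates(ft, spec.n_qc, cv.loc[ids], rng)


def generate_qc_replicates(table: FeatureTable, n_qc: int, technical_cv,
                           seed_or_rng) -> FeatureTable:
    """Append pooled-QC replicate columns to ``table``.

    Each QC replicate draws, per feature, from a log-normal centred on the
    pooled mean of the observed biological intensities with coefficient of
    variation ``technical_cv`` (scalar or per-feature); the parameterisation
    is mean-preserving, so the expected QC mean is the pooled mean and the
    expected QC CV is exactly the requested one. ``technical_cv = 0`` yields
    replicates identical to the pooled mean.
    """
    if n_qc < 2:
        raise ValueError("n_qc must be >= 2 (a CV is undefined on fewer replicates)")
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    cv = np.broadcast_to(
        np.asarray(technical_cv, dtype=float).reshape(-1), (table.n_features,)
    ).copy()
    if np.any(cv < 0):
        raise ValueError("technical_cv must be non-negative")
    pooled = np.nanmean(table.intensities, axis=1)
    sigma = np.sqrt(np.log1p(cv ** 2))  # log-normal sd giving exactly this CV
    z = rng.standard_normal((table.n_features, n_qc))
    qc = pooled[:, None] * np.exp(sigma[:, None] * z - (sigma ** 2 / 2)[:, None])
    qc_cols = [f"QC{k + 1:02d}" for k in range(n_qc)]
    out = pd.concat(
        [table.data, pd.DataFrame(qc, index=table.feature_ids, columns=qc_cols)],
        axis=1,
    )
    return FeatureTable(table.ion_mode, out)


def _build_pathway_map(spec: CohortSpec, truth_diff: dict[str, dict[str, float]],
                       all_ids: list[str], rng: np.random.Generator
                       ) -> tuple[PathwayMap, dict[str, str]]:
    """Pathway map whose first ``n_enriched_pathways`` pathways are stacked
    with planted features of one comparison each (round-robin)."""
    planted_all: set[str] = set()
    for d in truth_diff.values():
        planted_all |= set(d)
    non_planted = [f for f in all_ids if f not in planted_all]
    entries: dict[str, tuple[str, frozenset]] = {}
    enriched: dict[str, str] = {}
    comps = [c.name for c in COMPARISONS]
    for k in range(spec.n_pathways):
        pid = f"map{k + 1:03d}"
        if k < spec.n_enriched_pathways:
            comp = comps[k % len(comps)]
            pool = sorted(truth_diff[comp])
            n_plant = min(int(round(spec.enriched_fraction * spec.pathway_size)), len(pool))
            members = list(rng.choice(pool, size=n_plant, replace=False))
            fill = rng.choice(non_planted, size=spec.pathway_size - n_plant, replace=False)
            members += list(fill)
            entries[pid] = (f"Enriched pathway {comp}", frozenset(members))
            enriched[pid] = comp
        else:
            members = rng.choice(non_planted, size=spec.pathway_size, replace=False)
            entries[pid] = (f"Background pathway {k + 1}", frozenset(members))
    return PathwayMap(entries), enriched


def _simulate_covariates(groups: pd.Series, rng: np.random.Generator) -> pd.DataFrame:
    """Demographics, comorbidities and cognitive scores with stage-dependent
    distributions loosely following a staged dementia cohort."""
    params = {  # group -> (age mean, APOE carrier rate, MMSE mean, MoCA mean)
        "CN": (69.0, 0.23, 27.0, 23.0),
        "MCI": (73.5, 0.49, 24.0, 17.5),
        "AD": (78.0, 0.47, 14.5, 8.0),
    }
    rows = []
    for sid, g in groups.items():
        age_mu, apoe_rate, mmse_mu, moca_mu = params[g]
        rows.append({
            "sample_id": sid,
            "age": int(np.clip(rng.normal(age_mu, 5.5), 52, 95)),
            "gender": "male" if rng.uniform() < 0.42 else "female",
            "smoking": "yes" if rng.uniform() < 0.20 else "no",
            "hypertension": "yes" if rng.uniform() < 0.42 else "no",
            "diabetes": "yes" if rng.uniform() < 0.20 else "no",
            "hyperlipidemia": "yes" if rng.uniform() < 0.50 else "no",
            "heart_disease": "yes" if rng.uniform() < 0.22 else "no",
            "cerebrovascular_disease": "yes" if rng.uniform() < 0.20 else "no",
            "family_history": "yes" if rng.uniform() < 0.18 else "no",
            "apoe_e4": "carrier" if rng.uniform() < apoe_rate else "non-carrier",
            "mmse": int(np.clip(rng.normal(mmse_mu, 3.0), 0, 30)),
            "moca": int(np.clip(rng.normal(moca_mu, 3.5), 0, 30)),
        })
    return pd.DataFrame(rows).set_index("sample_id")


def generate_cohort(spec: CohortSpec) -> tuple[
    FeatureTable, FeatureTable, SampleMetadata, PathwayMap, SyntheticTruth
]:
    """Generate the full synthetic study: one feature table per ion mode
    (QC columns appended), sample metadata, a pathway map, and the ground
    truth registry. Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)

    sample_ids: list[str] = []
    groups: dict[str, str] = {}
    for g in GROUPS:  # fixed CN, MCI, AD order for reproducible layout
        for i in range(spec.group_sizes.get(g, 0)):
            sid = f"{g}{i + 1:03d}"
            sample_ids.append(sid)
            groups[sid] = g
    group_series = pd.Series(groups)

    neg_ids = feature_ids(spec.n_features_neg, spec.n_features_pos)[: spec.n_features_neg]
    pos_ids = feature_ids(spec.n_features_neg, spec.n_features_pos)[spec.n_features_neg:]
    planted_all = {e.feature_id for e in spec.planted_effects}
    cv = _draw_technical_cv(spec, neg_ids + pos_ids, planted_all, rng)

    table_neg = _simulate_mode(spec, "negative", neg_ids, sample_ids, group_series, cv, rng)
    table_pos = _simulate_mode(spec, "positive", pos_ids, sample_ids, group_series, cv, rng)

    covars = _simulate_covariates(group_series, rng)
    qc_cols = [c for c in table_neg.sample_ids if c not in sample_ids]
    meta = pd.DataFrame(index=sample_ids + qc_cols)
    meta["group"] = [groups.get(s, "QC") for s in meta.index]
    meta["is_qc"] = (meta["group"] == "QC").astype(int)
    meta = meta.join(covars)
    metadata = SampleMetadata(meta)

    truth_diff: dict[str, dict[str, float]] = {c.name: {} for c in COMPARISONS}
    for eff in spec.planted_effects:
        truth_diff[eff.comparison][eff.feature_id] = eff.fold_change
    pmap, enriched = _build_pathway_map(spec, truth_diff, neg_ids + pos_ids, rng)

    truth = SyntheticTruth(
        differential_features=truth_diff,
        enriched_pathways=enriched,
        qc_excluded_features=set(cv.index[cv > 0.30]),
        technical_cv={k: float(v) for k, v in cv.items()},
    )
    return table_neg, table_pos, metadata, pmap, truth
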