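"""QC-based feature filtering and group-wise K-nearest-neighbour imputation.

Features whose pooled-QC coefficient of variation exceeds 30% are removed as
technically unreliable; remaining missing values are imputed with a KNN
scheme whose neighbourhood size is 10% of each diagnostic group's sample
count, neighbours being sought within the same group only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FeatureTable, SampleMetadata, GROUPS


@dataclass
class QCFilterReport:
    """Per-feature QC CV (sample sd / mean on raw intensities) and the
    retain/exclude partition at the applied threshold. Features with an
    undefined CV (QC mean 0 or < 2 observed QC values) are excluded."""

    cv: pd.Series  # NaN where undefined
    retained: list[str]
    excluded: list[str]
    threshold: float


@dataclass
class ImputationReport:
    k_per_group: dict[str, int]
    imputed_cells_per_group: dict[str, int]
    fraction: float


def cv_filter(table: FeatureTable, qc_ids, threshold: float = 0.30
              ) -> tuple[FeatureTable, QCFilterReport]:
    """Remove features with QC CV strictly greater than ``threshold``.

    CV = sample (n-1) standard deviation / mean, computed per feature on the
    raw QC intensities. A CV exactly at the threshold is retained (the
    exclusion rule is "over" the threshold). Features whose CV is undefined
    (all-missing QC values, fewer than two observed replicates, or zero QC
    mean) are excluded and their CV reported as NaN.
    """
    qc_ids = list(qc_ids)
    if len(qc_ids) < 2:
        raise ValueError("cv_filter needs at least 2 QC samples")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    qc = table.data[qc_ids]
    n_obs = qc.notna().sum(axis=1)
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    cv = sd / mean
    cv[(n_obs < 2) | (mean == 0)] = np.nan
    keep = cv.notna() & (cv <= threshold)
    retained = list(table.data.index[keep])
    excluded = list(table.data.index[~keep])
    report = QCFilterReport(cv=cv, retained=retained, excluded=excluded,
                            threshold=threshold)
    return table.subset_features(retained), report


def knn_k(fraction: float, group_size: int) -> int:
    """k = max(1, fraction x group size), rounded half-up."""
    return max(1, int(np.floor(fraction * group_size + 0.5)))


def _impute_group(block: pd.DataFrame, k: int) -> tuple[pd.DataFrame, int]:
    """KNN-impute one diagnostic group's sub-matrix (features x samples).

    The distance between two samples is the Euclidean distance over features
    observed in both, scaled by the shared-feature count (root mean squared
    difference), so samples sharing few features are not spuriously close.
    The imputed value is the unweighted mean of the k nearest neighbours'
    observed values for that feature; a neighbour missing the feature is
    skipped in favour of the next nearest. Distance ties break on sample id.
    """
    samples = list(block.columns)
    X = block.to_numpy()  # features x samples
    obs = ~np.isnan(X)
    n_s = len(samples)

    # pairwise scaled distances
    dist = np.full((n_s, n_s), np.inf)
    for a in range(n_s):
        for b in range(a + 1, n_s):
            shared = obs[:, a] & obs[:, b]
            n_shared = int(shared.sum())
            if n_shared == 0:
                continue
            diff = X[shared, a] - X[shared, b]
            dist[a, b] = dist[b, a] = np.sqrt(np.sum(diff ** 2) / n_shared)

    order_cache: dict[int, list[int]] = {}

    def neighbour_order(j: int) -> list[int]:
        if j not in order_cache:
            others = [b for b in range(n_s) if b != j]
            others.sort(key=lambda b: (dist[j, b], samples[b]))
            order_cache[j] = others
        return order_cache[j]

    out = X.copy()
    n_imputed = 0
    missing_rows, missing_cols = np.where(~obs)
    for i, j in zip(missing_rows, missing_cols):
        donors = []
        for b in neighbour_order(j):
            if obs[i, b] and np.isfinite(dist[j, b]):
                donors.append(X[i, b])
                if len(donors) == k:
                    break
        if not donors:
            raise ValueError(
                f"feature {block.index[i]!r} has no observed value in group; "
                "cannot impute"
            )
        out[i, j] = float(np.mean(donors))
        n_imputed += 1
    return pd.DataFrame(out, index=block.index, columns=block.columns), n_imputed


def knn_impute(table: FeatureTable, metadata: SampleMetadata,
               fraction: float = 0.10) -> tuple[FeatureTable, ImputationReport]:
    """Impute missing cells within each diagnostic group independently.

    k is derived per group as max(1, round(fraction x group size)). QC
    columns present in the table are passed through untouched. Raises if a
    feature is missing in every sample of some group (no donor exists).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    data = table.data.copy()
    k_per_group: dict[str, int] = {}
    imputed: dict[str, int] = {}
    for g in GROUPS:
        ids = [s for s in metadata.ids_in_group(g) if s in data.columns]
        if not ids:
            continue
        if len(ids) < 2:
            raise ValueError(f"group {g} has fewer than 2 samples; cannot impute")
        k = knn_k(fraction, len(ids))
        block = data[ids]
        if block.isna().any().any():
            all_missing = block.index[block.isna().all(axis=1)]
            if len(all_missing):
                raise ValueError(
                    f"feature(s) {list(all_missing)} missing in all samples of group {g}"
                )
            filled, n = _impute_group(block, k)
            data[ids] = filled
        else:
            n = 0
        k_per_group[g] = k
        imputed[g] = n
    report = ImputationReport(k_per_group=k_per_group,
                              imputed_cells_per_group=imputed,
                              fraction=fraction)
    return FeatureTable(table.ion_mode, data), report


def preprocess_table(table: FeatureTable, metadata: SampleMetadata,
                     cv_threshold: float = 0.30, knn_fraction: float = 0.10
                     ) -> tuple[FeatureTable, QCFilterReport, ImputationReport]:
    """CV-filter on the QC replicates, then impute, then drop QC columns.

    Returns the complete biological-samples-only table ready for modelling.
    """
    qc_ids = [s for s in metadata.qc_ids if s in table.sample_ids]
    filtered, qc_report = cv_filter(table, qc_ids, cv_threshold)
    imputed, imp_report = knn_impute(filtered, metadata, knn_fraction)
    bio = [s for s in imputed.sample_ids if s not in qc_ids]
    return imputed.subset_samples(bio), qc_report, imp_report
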