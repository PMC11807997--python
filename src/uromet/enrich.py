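"""Pathway over-representation analysis via the hypergeometric upper tail.

For each pathway, the overlap x between the differential set (size n) and
the pathway's annotated members (K of the N background features) is scored
with p = P[X >= x] under the hypergeometric null of drawing n features from
the background at random. The background is the set of annotated,
QC-passing features; differential sets from both ion modes are merged
before testing (pathway identity is mode-agnostic).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import PathwayMap


@dataclass
class EnrichmentResult:
    pathway_id: str
    pathway_name: str
    n_background: int      # N
    n_in_pathway: int      # K (annotated members present in the background)
    n_differential: int    # n
    n_overlap: int         # x
    p_value: float
    bh_adjusted_p: float = float("nan")
    overlap_ids: tuple[str, ...] = ()

    @property
    def rich_factor(self) -> float:
        return self.n_overlap / self.n_in_pathway if self.n_in_pathway else 0.0


def hypergeom_upper_tail(x: int, N: int, K: int, n: int) -> float:
    """P[X >= x] for X ~ Hypergeometric(N, K, n); x = 0 gives p = 1."""
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def enrich(differential_ids, background_ids, pmap: PathwayMap) -> list[EnrichmentResult]:
    """Score every pathway for over-representation of the differential set.

    Pathway membership is intersected with the background before counting,
    so K reflects testable features only. Results are sorted by raw p (ties
    by pathway id); BH adjustment runs across all tested pathways; a
    pathway with zero overlap reports p = 1.
    """
    background = set(background_ids)
    diff = set(differential_ids)
    stray = diff - background
    if stray:
        raise ValueError(
            f"differential feature(s) absent from background: {sorted(stray)[:5]}"
        )
    N = len(background)
    n = len(diff)
    results: list[EnrichmentResult] = []
    for pid in sorted(pmap.pathway_ids):
        members = pmap.members(pid) & background
        K = len(members)
        overlap = sorted(members & diff)
        x = len(overlap)
        p = hypergeom_upper_tail(x, N, K, n) if K else 1.0
        results.append(EnrichmentResult(
            pathway_id=pid, pathway_name=pmap.name(pid),
            n_background=N, n_in_pathway=K, n_differential=n,
            n_overlap=x, p_value=p, overlap_ids=tuple(overlap),
        ))
    adj = multipletests([r.p_value for r in results], method="fdr_bh")[1]
    for r, a in zip(results, adj):
        r.bh_adjusted_p = float(a)
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view including bubble-plot coordinates (rich factor vs
    -log10 p, bubble size = overlap count)."""
    import numpy as np

    df = pd.DataFrame([{
        "pathway_id": r.pathway_id,
        "pathway_name": r.pathway_name,
        "n_background": r.n_background,
        "n_in_pathway": r.n_in_pathway,
        "n_differential": r.n_differential,
        "n_overlap": r.n_overlap,
        "rich_factor": r.rich_factor,
        "p_value": r.p_value,
        "bh_adjusted_p": r.bh_adjusted_p,
        "overlap_ids": ";".join(r.overlap_ids),
    } for r in results])
    with np.errstate(divide="ignore"):
        df["neg_log10_p"] = -np.log10(df["p_value"])
    return df
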