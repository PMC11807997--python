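"""Pathway over-representation of each comparison's differential set.

Merges the differential calls of both ion modes, restricts to annotated
features, and tests every pathway with the hypergeometric upper tail;
checks that the pathways stacked with planted features outrank the
background pathways.
"""

import json
from pathlib import Path

import pandas as pd

from uromet.enrich import enrich, enrichment_frame
from uromet.io import read_pathway_map

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    pmap = read_pathway_map(BASE / "cohort" / "pathways.tsv")
    with open(BASE / "cohort" / "truth.json") as fh:
        truth = json.load(fh)
    enriched_truth = truth["enriched_pathways"]
    annotated = pmap.annotated_ids()
    out = BASE / "enrichment"
    out.mkdir(parents=True, exist_ok=True)
    for comp in ("CN-AD", "CN-MCI", "MCI-AD"):
        screen = pd.read_csv(BASE / "screen" / f"screen_{comp}.tsv", sep="\t")
        background = sorted(set(screen["feature_id"]) & annotated)
        diff = sorted(set(screen.loc[screen["status"] != "ns", "feature_id"])
                      & annotated)
        results = enrich(diff, background, pmap)
        enrichment_frame(results).to_csv(out / f"enrichment_{comp}.tsv",
                                         sep="\t", index=False)
        own = [pid for pid, c in enriched_truth.items() if c == comp]
        top = results[0]
        print(f"{comp}: {len(diff)}/{len(background)} annotated features "
              f"differential; top pathway {top.pathway_id} "
              f"({top.pathway_name}, x={top.n_overlap}/{top.n_in_pathway}, "
              f"p={top.p_value:.2e}); truth pathway for this comparison: {own}")


if __name__ == "__main__":
    main()
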