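"""Generate the synthetic staged cohort that drives the whole analysis.

Emulates a three-stage urine-metabolomics study: 62 CN / 43 MCI / 57 AD
participants, two independent ion-mode feature tables (80 negative, 120
positive features), 20 pooled-QC replicate injections, 20 planted
differential features per pairwise comparison (half at FC 2.0, half at
FC 0.5), intensity-dependent plus random missingness, and a 12-pathway map
whose first three pathways are stacked with planted features. Everything
planted is recorded in truth.json so later steps can be scored against it.
"""

import json
from pathlib import Path

from uromet import CohortSpec, generate_cohort
from uromet.io import (write_feature_table, write_metadata, write_pathway_map)

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20250127


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    spec = CohortSpec(seed=SEED)
    neg, pos, meta, pmap, truth = generate_cohort(spec)
    write_feature_table(neg, OUT / "features_negative.tsv")
    write_feature_table(pos, OUT / "features_positive.tsv")
    write_metadata(meta, OUT / "metadata.tsv")
    write_pathway_map(pmap, OUT / "pathways.tsv")
    with open(OUT / "truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=2)
    n_missing = int(neg.missing_mask.sum() + pos.missing_mask.sum())
    print(f"cohort: {meta.group_sizes()} + {len(meta.qc_ids)} QC injections")
    print(f"features: {neg.n_features} negative, {pos.n_features} positive; "
          f"{n_missing} missing cells")
    print(f"planted: "
          + ", ".join(f"{k}: {len(v)}" for k, v in truth.differential_features.items())
          + f"; {len(truth.qc_excluded_features)} features with technical CV > 30%")
    print(f"wrote inputs to {OUT}")


if __name__ == "__main__":
    main()
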