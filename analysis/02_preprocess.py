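"""QC filtering and imputation of the simulated cohort.

Removes features whose pooled-QC coefficient of variation exceeds 30%,
then imputes remaining missing values group-wise with KNN (k = 10% of the
group size), producing one complete biological-samples matrix per ion mode.
"""

from pathlib import Path

import pandas as pd

from uromet.io import read_feature_table, read_metadata, write_feature_table
from uromet.preprocess import preprocess_table

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    meta = read_metadata(BASE / "cohort" / "metadata.tsv")
    out = BASE / "preprocessed"
    out.mkdir(parents=True, exist_ok=True)
    for mode in ("negative", "positive"):
        table = read_feature_table(BASE / "cohort" / f"features_{mode}.tsv", mode)
        clean, qc_rep, imp_rep = preprocess_table(table, meta)
        write_feature_table(clean, out / f"clean_{mode}.tsv")
        pd.DataFrame({
            "feature_id": qc_rep.cv.index,
            "qc_cv": qc_rep.cv.values,
            "retained": [f in set(qc_rep.retained) for f in qc_rep.cv.index],
        }).to_csv(out / f"qc_filter_{mode}.tsv", sep="\t", index=False)
        print(f"{mode}: excluded {len(qc_rep.excluded)}/{table.n_features} "
              f"features with QC CV > {qc_rep.threshold:.0%}; "
              f"k per group {imp_rep.k_per_group}; "
              f"imputed cells {imp_rep.imputed_cells_per_group}")
    print(f"wrote complete matrices to {out}")


if __name__ == "__main__":
    main()
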