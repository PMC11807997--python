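"""Tabular I/O and the pipeline's central data model.

The pipeline operates on per-ionization-mode feature tables (features as
rows, samples as columns), a sample-metadata table carrying the diagnostic
group (CN / MCI / AD) and QC flags, and a pathway-annotation map. All three
round-trip through plain TSV/CSV so every stage's inputs and outputs are
inspectable text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("CN", "MCI", "AD")
#: disease-stage ordering used to orient every pairwise comparison
GROUP_ORDER = {"CN": 0, "MCI": 1, "AD": 2}
ION_MODES = ("negative", "positive")
ION_PREFIX = {"negative": "neg_", "positive": "pos_"}

#: cell tokens treated as missing on read; "0" is deliberately absent —
#: a zero intensity is a measurement, not a missing value
MISSING_TOKENS = ("", "NA", "NaN", "nan")

DEFAULT_SEED = 20250127


@dataclass
class FeatureTable:
    """Per-ion-mode intensity matrix (features x samples), NaN = missing.

    Attributes
    ----------
    ion_mode : {"negative", "positive"}
    data : pandas.DataFrame
        Rows indexed by feature id, columns by sample id; float values with
        NaN marking missing cells. Zeros are kept as measured intensities.
    """

    ion_mode: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.ion_mode not in ION_MODES:
            raise ValueError(f"unknown ion_mode {self.ion_mode!r}; expected one of {ION_MODES}")
        self.data = self.data.astype(float)
        dup = self.data.index[self.data.index.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate feature ids: {sorted(set(dup))}")
        if len(self.data.columns[self.data.columns.duplicated()]):
            raise ValueError("duplicate sample ids")
        vals = self.data.to_numpy()
        if np.any(vals[np.isfinite(vals)] < 0):
            raise ValueError("negative intensities are not allowed")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def intensities(self) -> np.ndarray:
        """Features x samples float matrix with NaN for missing cells."""
        return self.data.to_numpy()

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.data.to_numpy())

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(self.ion_mode, self.data.loc[list(feature_ids)].copy())

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.ion_mode, self.data[list(sample_ids)].copy())

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.ion_mode, self.data.copy())


@dataclass
class SampleMetadata:
    """Sample annotations: diagnostic group, QC flag, and covariates.

    ``table`` is indexed by sample id and has at least a ``group`` column
    with values in {CN, MCI, AD, QC}; every additional column is treated as
    a covariate (age, gender, comorbidities, cognitive scores, ...).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "group" not in self.table.columns:
            raise ValueError("metadata requires a 'group' column")
        bad = set(self.table["group"]) - set(GROUPS) - {"QC"}
        if bad:
            raise ValueError(f"unknown group token(s): {sorted(bad)}; expected CN/MCI/AD/QC")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate sample ids in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    @property
    def qc_ids(self) -> list[str]:
        return list(self.table.index[self.table["group"] == "QC"])

    @property
    def biological_ids(self) -> list[str]:
        return list(self.table.index[self.table["group"] != "QC"])

    def ids_in_group(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def group_sizes(self) -> dict[str, int]:
        return {g: int((self.table["group"] == g).sum()) for g in GROUPS}

    @property
    def covariates(self) -> pd.DataFrame:
        return self.table.drop(columns=["group", "is_qc"], errors="ignore")


@dataclass(frozen=True)
class Comparison:
    """A pairwise disease-stage contrast, reference before case.

    The case group is always the later stage, so fold changes read as
    "up/down in the more advanced group".
    """

    reference_group: str
    case_group: str

    def __post_init__(self) -> None:
        if GROUP_ORDER[self.reference_group] >= GROUP_ORDER[self.case_group]:
            raise ValueError(
                f"reference {self.reference_group} must precede case "
                f"{self.case_group} in the staging order CN < MCI < AD"
            )

    @property
    def name(self) -> str:
        return f"{self.reference_group}-{self.case_group}"

    @classmethod
    def from_name(cls, name: str) -> "Comparison":
        ref, case = name.split("-")
        return cls(ref, case)


#: the three staging contrasts analysed throughout
COMPARISONS = (
    Comparison("CN", "AD"),
    Comparison("CN", "MCI"),
    Comparison("MCI", "AD"),
)


@dataclass
class PathwayMap:
    """pathway_id -> (pathway_name, set of metabolite/feature ids)."""

    entries: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, (name, members) in self.entries.items():
            if not members:
                raise ValueError(f"pathway {pid} has an empty member set")

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.entries)

    def members(self, pathway_id: str) -> frozenset[str]:
        return self.entries[pathway_id][1]

    def name(self, pathway_id: str) -> str:
        return self.entries[pathway_id][0]

    def annotated_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.entries.values():
            out |= members
        return frozenset(out)


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_feature_table(path, ion_mode: str, missing_tokens=MISSING_TOKENS) -> FeatureTable:
    """Read a features x samples intensity table from TSV/CSV.

    Row 1 holds sample ids, column 1 feature ids. Empty cells and the
    configured sentinel tokens become missing; any other non-numeric cell
    raises with its row and column. Delimiter is auto-detected (tab/comma).
    """
    path = Path(path)
    sep = _detect_sep(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate feature id(s) in {path.name}: {sorted(set(dup))}")
    sentinel = set(missing_tokens)
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            tok = cell.strip()
            if tok in sentinel:
                values[i, j] = np.nan
            else:
                try:
                    values[i, j] = float(tok)
                except ValueError:
                    raise ValueError(
                        f"non-numeric cell {cell!r} at feature {raw.index[i]!r}, "
                        f"sample {col!r} in {path.name}"
                    ) from None
    data = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    data.index.name = None
    data.columns.name = None
    return FeatureTable(ion_mode, data)


def write_feature_table(table: FeatureTable, path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table.data.to_csv(path, sep=sep, index_label="feature_id", na_rep="NA")


def read_metadata(path) -> SampleMetadata:
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "group": str})
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"metadata file {path.name} lacks required column {col!r}")
    df = df.set_index("sample_id")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep="\t", index_label="sample_id")


def read_pathway_map(path) -> PathwayMap:
    """Read a long-format pathway map (pathway_id, pathway_name, metabolite_id).

    Repeated (pathway, metabolite) rows collapse to set semantics.
    """
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("pathway_id", "pathway_name", "metabolite_id"):
        if col not in df.columns:
            raise ValueError(f"pathway file {path.name} lacks required column {col!r}")
    entries: dict[str, tuple[str, frozenset]] = {}
    for pid, sub in df.groupby("pathway_id", sort=True):
        names = sub["pathway_name"].unique()
        entries[str(pid)] = (str(names[0]), frozenset(sub["metabolite_id"].astype(str)))
    return PathwayMap(entries)


def write_pathway_map(pmap: PathwayMap, path) -> None:
    rows = [
        {"pathway_id": pid, "pathway_name": name, "metabolite_id": mid}
        for pid, (name, members) in pmap.entries.items()
        for mid in sorted(members)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
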