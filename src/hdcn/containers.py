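"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MIXED = "mixed"
REFERENCE = "reference"
GROUPS = (MIXED, REFERENCE)

#: The fixed 10-compartment vocabulary used for localization prediction.
COMPARTMENTS = (
    "nucleus",
    "cytosol",
    "mitochondria",
    "endoplasmic_reticulum",
    "golgi_apparatus",
    "plasma_membrane",
    "vesicles",
    "cytoskeleton",
    "peroxisome",
    "lysosome",
)

_NUCLEOTIDES = frozenset("ACGTN")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative FPKM-scale values.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns.
    groups
        Mapping ``sample_id -> {"mixed", "reference"}`` covering every
        sample in ``values``.
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = v.columns[
                [not np.issubdtype(d, np.number) for d in v.dtypes]
            ][0]
            raise ValueError(f"non-numeric expression values in sample {bad!r}")
        if not np.all(np.isfinite(arr)):
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value for gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative value for gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        missing = [s for s in v.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples missing from group table: {missing}")
        bad_groups = {g for g in self.groups.values()} - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown group labels: {sorted(bad_groups)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    @property
    def mixed_samples(self) -> list[str]:
        return self.samples_in_group(MIXED)

    @property
    def reference_samples(self) -> list[str]:
        return self.samples_in_group(REFERENCE)

    def subset(
        self, genes: list[str] | None = None, samples: list[str] | None = None
    ) -> "ExpressionMatrix":
        v = self.values
        if genes is not None:
            v = v.loc[genes]
        if samples is not None:
            v = v[samples]
        return ExpressionMatrix(v, {s: self.groups[s] for s in v.columns})

    def require_two_groups(self) -> None:
        if not self.mixed_samples or not self.reference_samples:
            raise ValueError("both 'mixed' and 'reference' groups must be non-empty")


@dataclass
class ClonotypeTable:
    """Clonotype records: (sample_id, v_gene, j_gene, junction_nt, count)."""

    records: pd.DataFrame  # columns: sample_id, v_gene, j_gene, junction_nt, count

    COLUMNS = ("sample_id", "v_gene", "j_gene", "junction_nt", "count")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.records
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"clonotype table missing columns: {sorted(missing)}")
        counts = df["count"]
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == counts.astype(np.int64)):
                raise ValueError("clonotype counts must be integers")
            df["count"] = counts.astype(np.int64)
        if (df["count"] < 1).any():
            row = df[df["count"] < 1].iloc[0]
            raise ValueError(
                f"count < 1 for sample {row['sample_id']!r}, "
                f"junction {row['junction_nt']!r}"
            )
        for junction in df["junction_nt"]:
            if not junction or not set(junction) <= _NUCLEOTIDES:
                raise ValueError(f"illegal junction sequence: {junction!r}")

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.records["sample_id"].unique())

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class LocalizationAnnotation:
    """Single-label protein -> compartment annotation over a 10-label vocabulary."""

    mapping: dict[str, str]
    compartments: tuple[str, ...] = field(default=COMPARTMENTS)

    def __post_init__(self) -> None:
        if len(self.compartments) != 10:
            raise ValueError("compartment vocabulary must have exactly 10 labels")
        vocab = set(self.compartments)
        unknown = {c for c in self.mapping.values() if c not in vocab}
        if unknown:
            raise ValueError(f"unknown compartment labels: {sorted(unknown)}")

    def __contains__(self, protein: str) -> bool:
        return protein in self.mapping

    def __getitem__(self, protein: str) -> str:
        return self.mapping[protein]
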