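"""Core data containers for FPKM expression analysis.

The pipeline operates on three containers:

* :class:`ExpressionMatrix` — replicate-level FPKM, genes x samples.
* :class:`SampleMetadata` — per-sample cell class, long-axis region and
  replicate index.  A *population* is a (cell_class, region) pair; the
  hippocampal design profiles eight of them (dorsal/ventral dentate granule
  cells, hilar mossy cells, dorsal/ventral CA3, CA2, dorsal/ventral CA1).
* :class:`PopulationMatrix` — population-averaged FPKM, genes x populations.

Gene identifiers are opaque strings; no symbol/accession mapping is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CELL_CLASSES = ("GC", "MC", "CA3", "CA2", "CA1")
REGIONS = ("dorsal", "ventral", "none")

#: The eight profiled populations, in circuit order.
DEFAULT_POPULATIONS: tuple[tuple[str, str], ...] = (
    ("GC", "dorsal"),
    ("GC", "ventral"),
    ("MC", "none"),
    ("CA3", "dorsal"),
    ("CA3", "ventral"),
    ("CA2", "none"),
    ("CA1", "dorsal"),
    ("CA1", "ventral"),
)


def population_label(cell_class: str, region: str) -> str:
    """Human-readable label for a (cell_class, region) population.

    Populations without a dorsal/ventral split (mossy cells, CA2) are labelled
    by class alone.
    """
    if region == "none":
        return cell_class
    return f"{cell_class}-{region}"


def parse_population_label(label: str) -> tuple[str, str]:
    if "-" in label:
        cls, region = label.split("-", 1)
    else:
        cls, region = label, "none"
    if cls not in CELL_CLASSES:
        raise ValueError(f"unknown cell class in population label {label!r}")
    if region not in REGIONS:
        raise ValueError(f"unknown region in population label {label!r}")
    return cls, region


def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dup = index[index.duplicated()][0]
        raise ValueError(f"duplicate {what} {dup!r}")


@dataclass(frozen=True)
class ExpressionMatrix:
    """Dense FPKM matrix, genes as rows, samples as columns.

    All values must be finite and non-negative; gene and sample identifiers
    must be unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise TypeError("ExpressionMatrix.data must be a pandas DataFrame")
        _check_unique(df.index, "gene id")
        _check_unique(df.columns, "sample id")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = df.columns[df.dtypes.apply(lambda d: not np.issubdtype(d, np.number))]
            raise ValueError(f"non-numeric expression values in sample(s) {list(bad)}")
        if np.isnan(values).any():
            g, s = np.argwhere(np.isnan(values))[0]
            raise ValueError(
                f"missing value at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative FPKM at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset(
        self,
        genes: Iterable[str] | None = None,
        samples: Iterable[str] | None = None,
    ) -> "ExpressionMatrix":
        df = self.data
        if genes is not None:
            genes = list(genes)
            missing = [g for g in genes if g not in df.index]
            if missing:
                raise KeyError(f"genes not in matrix: {missing[:5]}")
            df = df.loc[genes]
        if samples is not None:
            samples = list(samples)
            missing = [s for s in samples if s not in df.columns]
            if missing:
                raise KeyError(f"samples not in matrix: {missing[:5]}")
            df = df[samples]
        return ExpressionMatrix(df.copy())

    def drop_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        drop = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.drop(index=drop))


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample annotations keyed by sample id.

    ``table`` columns: ``cell_class``, ``region``, ``replicate`` (1-based).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        required = {"cell_class", "region", "replicate"}
        if not required.issubset(df.columns):
            raise ValueError(f"metadata must have columns {sorted(required)}")
        _check_unique(df.index, "sample id")
        bad_cls = set(df["cell_class"]) - set(CELL_CLASSES)
        if bad_cls:
            raise ValueError(f"unknown cell class(es) {sorted(bad_cls)}")
        bad_reg = set(df["region"]) - set(REGIONS)
        if bad_reg:
            raise ValueError(f"unknown region(s) {sorted(bad_reg)}")
        if (df["replicate"].astype(int) < 1).any():
            raise ValueError("replicate indices must be positive integers")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def populations(self) -> list[tuple[str, str]]:
        """Populations in order of first appearance."""
        seen: dict[tuple[str, str], None] = {}
        for _, row in self.table.iterrows():
            seen.setdefault((row["cell_class"], row["region"]), None)
        return list(seen)

    @property
    def population_labels(self) -> list[str]:
        return [population_label(c, r) for c, r in self.populations]

    def samples_in(self, cell_class: str, region: str) -> list[str]:
        df = self.table
        mask = (df["cell_class"] == cell_class) & (df["region"] == region)
        return list(df.index[mask])

    def population_of(self, sample_id: str) -> tuple[str, str]:
        row = self.table.loc[sample_id]
        return row["cell_class"], row["region"]

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        meta_ids = set(self.table.index)
        mat_ids = set(matrix.sample_ids)
        if meta_ids != mat_ids:
            missing = sorted(mat_ids - meta_ids)
            extra = sorted(meta_ids - mat_ids)
            raise ValueError(
                f"metadata/matrix sample mismatch: missing={missing[:5]}, extra={extra[:5]}"
            )


@dataclass(frozen=True)
class PopulationMatrix:
    """Population-averaged FPKM: one column per (cell_class, region) pair."""

    data: pd.DataFrame
    populations: tuple[tuple[str, str], ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.populations) != self.data.shape[1]:
            raise ValueError("populations must match data columns")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def population_labels(self) -> list[str]:
        return list(self.data.columns)

    def classes_with_both_poles(self) -> list[str]:
        by_class: dict[str, set[str]] = {}
        for cls, region in self.populations:
            by_class.setdefault(cls, set()).add(region)
        return [c for c, regions in by_class.items() if {"dorsal", "ventral"} <= regions]


def aggregate_replicates(
    matrix: ExpressionMatrix, meta: SampleMetadata
) -> PopulationMatrix:
    """Average replicate FPKM into one column per population.

    Gene order is preserved; each population's value is the arithmetic mean of
    its replicates' FPKM.
    """
    meta.validate_against(matrix)
    pops = meta.populations
    cols = {}
    for cls, region in pops:
        samples = meta.samples_in(cls, region)
        if not samples:
            raise ValueError(f"population {population_label(cls, region)} has no samples")
        cols[population_label(cls, region)] = matrix.data[samples].mean(axis=1)
    out = pd.DataFrame(cols, index=matrix.data.index)
    return PopulationMatrix(out, tuple(pops))
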