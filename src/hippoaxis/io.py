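"""Delimited-text I/O for expression matrices, metadata, gene lists and GMT sets.

FPKM values are serialized with 6 significant digits (typical of upstream
quantification output); TSV is the default dialect with CSV selectable by
delimiter or file suffix.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datamodel import ExpressionMatrix, SampleMetadata

FLOAT_FORMAT = "%.6g"


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_matrix(path: str | Path, delimiter: str | None = None) -> ExpressionMatrix:
    """Read a genes-by-samples FPKM matrix.

    First column holds gene ids, header row holds sample ids.  Duplicate gene
    ids, missing cells, and negative or non-numeric values are hard errors.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {path}")
    try:
        df = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
    return ExpressionMatrix(df)


def write_matrix(
    matrix: ExpressionMatrix | pd.DataFrame,
    path: str | Path,
    delimiter: str | None = None,
) -> Path:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    df.to_csv(path, sep=sep, float_format=FLOAT_FORMAT, index_label="gene_id")
    return path


def load_metadata(path: str | Path, delimiter: str | None = None) -> SampleMetadata:
    """Read 4-column sample metadata (sample_id, cell_class, region, replicate)."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df["replicate"] = df["replicate"].astype(int)
    return SampleMetadata(df)


def write_metadata(
    meta: SampleMetadata, path: str | Path, delimiter: str | None = None
) -> Path:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    meta.table.to_csv(path, sep=sep, index_label="sample_id")
    return path


def load_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> Path:
    path = Path(path)
    path.write_text("".join(f"{g}\n" for g in genes))
    return path


def load_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read annotation sets in GMT format (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> Path:
    path = Path(path)
    lines = []
    for name, genes in sets.items():
        lines.append("\t".join([name, "na", *genes]))
    path.write_text("".join(f"{line}\n" for line in lines))
    return path


class _JSONEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, Path):
            return str(o)
        return super().default(o)


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_JSONEncoder) + "\n")
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
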