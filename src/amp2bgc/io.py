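"""Readers and writers for the plain-text formats the pipeline consumes.

FASTA via Bio.SeqIO (with stricter contracts layered on top: duplicate ids
and non-FASTA content are hard errors), QIIME2-style feature tables as plain
TSV or BIOM v1 JSON (dense or sparse), and the CSV conventions shared by all
outputs (comma-separated, UTF-8, LF, floats at 6 significant digits).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from amp2bgc.errors import DataError

logger = logging.getLogger(__name__)


def format_float(x: float) -> str:
    """6-significant-digit float formatting used in every CSV this package writes."""
    if isinstance(x, (int, np.integer)) or float(x).is_integer():
        return str(int(x))
    return f"{float(x):.6g}"


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (id, uppercase sequence) pairs, order preserved.

    The id is the first whitespace-delimited token of the header.  Duplicate
    ids, empty files and non-FASTA content are errors.
    """
    path = Path(path)
    text = path.read_text()
    stripped = [(i, ln) for i, ln in enumerate(text.splitlines(), start=1) if ln.strip()]
    if not stripped:
        raise DataError(f"{path}: empty FASTA file")
    first_lineno, first_line = stripped[0]
    if not first_line.lstrip().startswith(">"):
        raise DataError(f"{path}:{first_lineno}: not FASTA content (expected '>')")
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with path.open() as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            rid = rec.id
            if rid in seen:
                raise DataError(f"{path}: duplicate sequence id {rid!r}")
            seen.add(rid)
            records.append((rid, str(rec.seq).upper()))
    if not records:
        raise DataError(f"{path}: no FASTA records parsed")
    return records


def write_fasta(path: str | Path, records: list[tuple[str, str]], width: int = 80) -> None:
    with Path(path).open("w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class FeatureTable:
    """Features x samples abundance matrix (QIIME2 export semantics)."""

    data: pd.DataFrame  # index = feature ids, columns = sample ids

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise DataError("feature table ids must be unique")
        if (self.data.to_numpy() < 0).any():
            raise DataError("feature table contains negative abundances")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def read_feature_table(path: str | Path, fmt: str = "auto") -> FeatureTable:
    """Read a feature table from TSV or BIOM v1 JSON (dense or sparse).

    ``fmt`` is one of ``auto``/``tsv``/``biom``; auto-detection looks at the
    file content, not the extension.  BIOM v2 (HDF5, binary) is rejected with
    an explicit message.
    """
    path = Path(path)
    head = path.open("rb").read(8)
    if head.startswith(b"\x89HDF"):
        raise DataError(
            f"{path}: BIOM v2 (HDF5) is not supported; export BIOM v1 JSON or TSV"
        )
    if fmt == "auto":
        fmt = "biom" if path.read_text().lstrip().startswith("{") else "tsv"
    if fmt == "biom":
        doc = json.loads(path.read_text())
        rows = [r["id"] for r in doc["rows"]]
        cols = [c["id"] for c in doc["columns"]]
        mat = np.zeros((len(rows), len(cols)), dtype=float)
        if doc.get("matrix_type") == "sparse":
            for r, c, v in doc["data"]:
                mat[int(r), int(c)] = v
        else:
            mat[:] = np.asarray(doc["data"], dtype=float)
        df = pd.DataFrame(mat, index=rows, columns=cols)
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
        # QIIME2 exports often start with a '# Constructed from biom file' line
        if df.index.size and str(df.index[0]).startswith("# Constructed"):
            df = pd.read_csv(path, sep="\t", index_col=0, skiprows=1)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df = df.astype(float)
    else:
        raise DataError(f"unknown feature-table format {fmt!r}")
    return FeatureTable(df)


def write_feature_table_tsv(path: str | Path, table: FeatureTable) -> None:
    out = table.data.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")


def write_feature_table_biom(path: str | Path, table: FeatureTable, table_id: str = "amp2bgc") -> None:
    """Write BIOM v1 JSON (sparse) as QIIME-compatible plain text."""
    df = table.data
    data = [
        [int(i), int(j), float(df.iat[i, j])]
        for i in range(df.shape[0])
        for j in range(df.shape[1])
        if df.iat[i, j] != 0
    ]
    doc = {
        "id": table_id,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "amp2bgc",
        "date": "1970-01-01T00:00:00",
        "matrix_type": "sparse",
        "matrix_element_type": "float",
        "shape": [df.shape[0], df.shape[1]],
        "rows": [{"id": str(r), "metadata": None} for r in df.index],
        "columns": [{"id": str(c), "metadata": None} for c in df.columns],
        "data": data,
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")
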