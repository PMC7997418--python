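"""Tabular I/O shared by the pipeline stages.

All tables are header-first UTF-8 CSV; floats are serialized at full
precision so runs under the same seed are byte-identical and diff-able.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


class SchemaError(ValueError):
    """An input table violates the expected schema."""


def read_table(path: str | Path, required: list[str],
               numeric: list[str] | None = None) -> pd.DataFrame:
    """Read a CSV and validate required columns (and numeric types).

    Errors name the offending file and column, and the first bad row for
    numeric coercion failures.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col in numeric or []:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(f"{path}: column {col!r} not numeric at row {row} "
                              f"(value {df[col][row]!r})")
        df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format="%.17g")
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_fasta(entries, path: str | Path) -> Path:
    """Write sequence entries (with sequences) as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for e in entries:
        if e.sequence is None:
            continue
        records.append(SeqRecord(Seq(e.sequence), id=e.accession,
                                 description=e.source))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        seqio_write(records, fh, "fasta")
    return path
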