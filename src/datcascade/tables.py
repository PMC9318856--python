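"""Tab-delimited table I/O with light schema validation.

Every on-disk artifact of the pipeline is a UTF-8 TSV with a header row,
'.' as the decimal separator and one record per line.  Schemas declare the
required columns and their types; extra columns are preserved untouched.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "SchemaError",
    "SCHEMAS",
    "read_table",
    "write_table",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


#: required column -> pandas dtype kind ('f' float-like, 'i' integer-like,
#: 'O' free text).  Numeric kinds accept any numeric column.
SCHEMAS: dict[str, Mapping[str, str]] = {
    "sample_sheet": {
        "sample_id": "O",
        "pair": "O",
        "condition": "O",
        "replicate": "i",
        "batch": "O",
    },
    "de_table": {
        "gene_id": "O",
        "base_mean": "f",
        "log2fc": "f",
        "se": "f",
        "wald_stat": "f",
        "pvalue": "f",
        "padj": "f",
    },
    "survival": {
        "patient_id": "O",
        "os_time": "f",
        "os_event": "i",
        "pfs_time": "f",
        "pfs_event": "i",
    },
    "qpcr": {
        "gene_id": "O",
        "condition": "O",
        "replicate": "i",
        "ct_target": "f",
        "ct_reference": "f",
    },
    "screen": {
        "gene_id": "O",
        "replicate": "i",
        "colonies_sirna": "i",
        "colonies_nc": "i",
    },
    "truth": {
        "gene_id": "O",
    },
}


def _check_kind(series: pd.Series, kind: str, column: str, path: str) -> None:
    actual = series.dtype.kind
    if kind in ("f", "i"):
        if actual not in "fiu":
            bad = series[pd.to_numeric(series, errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise SchemaError(
                f"{path}: column '{column}' must be numeric; "
                f"first offending row index: {row}"
            )
    # 'O' columns accept anything


def read_table(path: str | Path, schema: str | None = None) -> pd.DataFrame:
    """Read a TSV, optionally validating it against a named schema.

    Raises :class:`SchemaError` naming the offending column for missing
    columns, non-numeric cells in numeric columns, or duplicate gene ids.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if schema is not None:
        spec = SCHEMAS[schema]
        for column, kind in spec.items():
            if column not in df.columns:
                raise SchemaError(f"{path}: missing required column '{column}'")
            _check_kind(df[column], kind, column, str(path))
        if "gene_id" in spec and schema != "qpcr" and schema != "screen":
            dups = df["gene_id"][df["gene_id"].duplicated()]
            if len(dups):
                raise SchemaError(
                    f"{path}: duplicate gene_id '{dups.iloc[0]}'"
                )
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV that round-trips through :func:`read_table` at full
    precision (floats serialized with repr-level digits)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
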