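"""Table reading/writing with schema validation.

Delimiter is inferred from the file extension (``.csv`` -> comma, anything
else -> tab) unless given explicitly.  Mandatory columns are checked by
name; declared numeric columns are parsed with row-numbered error messages;
unknown columns are preserved untouched so tables can carry annotation
through the pipeline.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

#: Column schemas: name -> (mandatory columns, numeric columns)
SCHEMAS = {
    "assays": (("peptide", "allele", "assay_method", "outcome"), ()),
    "curated": (("peptide", "allele", "label"), ("label",)),
    "features": (("peptide", "allele", "ic50_nm", "tap", "tpm"),
                 ("ic50_nm", "tap", "tpm")),
    "candidates": (("peptide", "allele", "ic50", "tap", "tpm", "immunogenicity"),
                   ("ic50", "tap", "tpm", "immunogenicity")),
    "scored": (("peptide", "allele"), ()),
}


class SchemaError(ValueError):
    """Table does not match its declared schema."""


def _delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_table(path: str | Path, schema: str | None = None,
               delimiter: str | None = None) -> pd.DataFrame:
    """Read a TSV/CSV table, validating against a named schema if given."""
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter(path, delimiter))
    if schema is not None:
        mandatory, numeric = SCHEMAS[schema]
        missing = [c for c in mandatory if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{path}: missing mandatory column(s) {missing} for schema "
                f"{schema!r} (found {list(df.columns)})"
            )
        for col in numeric:
            parsed = pd.to_numeric(df[col], errors="coerce")
            bad = parsed.isna() & df[col].notna()
            if bad.any():
                row = int(bad.idxmax()) + 2  # 1-based + header line
                raise SchemaError(
                    f"{path}: column {col!r} has non-numeric value "
                    f"{df[col][bad.idxmax()]!r} at line {row}"
                )
            df[col] = parsed
    return df


def write_table(df: pd.DataFrame, path: str | Path,
                delimiter: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_delimiter(path, delimiter), index=False)
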