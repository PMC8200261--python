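"""Table schemas and schema-validated CSV round-trips.

All artifacts are RFC-4180 CSV with a header row, ISO-8601 timestamps and
a leading comment line carrying the schema name and version so files are
self-describing and diff-friendly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .features import feature_columns


class SchemaError(ValueError):
    """Columns of a table do not match its declared schema."""


@dataclass(frozen=True)
class TableSchema:
    name: str
    version: str
    #: column -> kind: str | float | int | bool | datetime; a trailing '?'
    #: marks the column nullable.
    columns: Mapping[str, str]


ENCOUNTERS_SCHEMA = TableSchema(
    "encounters",
    "v1",
    {
        "encounter_id": "str",
        "patient_id": "str",
        "age": "float",
        "unit_type": "str",
        "admit_time": "datetime",
        "discharge_time": "datetime",
        "hospice_flag": "bool",
    },
)

EVENTS_SCHEMA = TableSchema(
    "events",
    "v1",
    {
        "encounter_id": "str",
        "timestamp": "datetime",
        "event_type": "str",
        "vital_kind": "str?",
        "value": "float?",
        "oxygen_supplemental": "bool?",
        "note_concepts": "str?",
    },
)

OUTCOMES_SCHEMA = TableSchema(
    "outcomes",
    "v1",
    {"encounter_id": "str", "event_time": "float", "component": "str"},
)

FEATURES_SCHEMA = TableSchema(
    "features",
    "v1",
    {"encounter_id": "str", **{c: "int" for c in feature_columns()}},
)

SCORES_SCHEMA = TableSchema(
    "scores",
    "v1",
    {
        "encounter_id": "str",
        "patient_hour": "int",
        "system": "str",
        "score": "float?",
        "category": "str?",
    },
)


def write_table(df: pd.DataFrame, path: str | Path, schema: TableSchema) -> Path:
    """Write a schema-validated CSV with a versioned comment header."""
    _check_columns(df.columns, schema)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df[list(schema.columns)].copy()
    for col, kind in schema.columns.items():
        if kind.rstrip("?") == "datetime":
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    with open(path, "w", newline="") as fh:
        fh.write(f"# schema: {schema.name} {schema.version}\n")
        out.to_csv(fh, index=False, lineterminator="\n")
    return path


def read_table(path: str | Path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a CSV written by :func:`write_table` (or any
    export with the same columns)."""
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    _check_columns(df.columns, schema)
    for col, kind in schema.columns.items():
        base = kind.rstrip("?")
        nullable = kind.endswith("?")
        s = df[col]
        if nullable:
            s = s.mask(s == "", other=pd.NA)
        if base == "datetime":
            df[col] = pd.to_datetime(s)
        elif base == "float":
            df[col] = pd.to_numeric(s, errors="raise").astype(float)
        elif base == "int":
            df[col] = pd.to_numeric(s, errors="raise").astype(int)
        elif base == "bool":
            if nullable:
                df[col] = s.map({"True": True, "False": False, pd.NA: pd.NA})
            else:
                df[col] = s.map({"True": True, "False": False})
                if df[col].isna().any():
                    raise SchemaError(f"{col}: non-boolean values present")
        else:
            df[col] = s
    return df


def _check_columns(columns, schema: TableSchema) -> None:
    got = list(columns)
    want = list(schema.columns)
    missing = [c for c in want if c not in got]
    extra = [c for c in got if c not in want]
    if missing or extra:
        raise SchemaError(
            f"table does not match schema {schema.name} {schema.version}: "
            f"missing={missing}, extra={extra}"
        )
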