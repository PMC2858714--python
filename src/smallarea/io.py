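"""CSV / YAML / JSON readers and writers for the package data model."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataValidationError, SchemeError
from .schemes import QidScheme, QuasiIdentifier
from .uniqueness import RecordTable

__all__ = [
    "read_records", "write_records",
    "read_pop_table", "write_pop_table",
    "load_scheme", "save_scheme",
    "write_report", "validate_report",
]


def read_records(
    path, area_col: str = "area", sampling_fraction: float = 1.0
) -> RecordTable:
    """Read a person-level CSV (one row per person, text area code column)."""
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=True)
    except pd.errors.ParserError as exc:
        raise DataValidationError(f"malformed record CSV {path}: {exc}") from exc
    if area_col not in df.columns:
        raise DataValidationError(
            f"{path}: missing area column {area_col!r}; found {list(df.columns)}"
        )
    bad = df.index[df[area_col].isna()]
    if len(bad):
        # +2: one for the header line, one for 0- vs 1-based indexing
        lines = [int(i) + 2 for i in bad[:10]]
        raise DataValidationError(f"{path}: missing area codes on lines {lines}")
    return RecordTable(df, area_col=area_col, sampling_fraction=sampling_fraction)


def write_records(records: RecordTable, path) -> None:
    records.df.to_csv(path, index=False)


def read_pop_table(path, area_col: str = "area", pop_col: str = "population") -> pd.Series:
    """Read an area -> population-count lookup; duplicate area codes are an error."""
    df = pd.read_csv(path, dtype={area_col: str})
    for col in (area_col, pop_col):
        if col not in df.columns:
            raise DataValidationError(f"{path}: missing column {col!r}")
    dupes = df[area_col][df[area_col].duplicated()].unique()
    if len(dupes):
        raise DataValidationError(f"{path}: duplicate area codes {sorted(dupes)[:10]}")
    counts = pd.to_numeric(df[pop_col], errors="coerce")
    bad = df.index[counts.isna() | (counts < 1)]
    if len(bad):
        raise DataValidationError(
            f"{path}: non-positive or non-numeric populations on lines "
            f"{[int(i) + 2 for i in bad[:10]]}"
        )
    return pd.Series(
        counts.astype(int).to_numpy(), index=pd.Index(df[area_col], name="area"),
        name="population",
    )


def write_pop_table(counts: pd.Series, path) -> None:
    counts.rename_axis("area").rename("population").reset_index().to_csv(
        path, index=False
    )


def load_scheme(path) -> QidScheme:
    """Load a quasi-identifier scheme from a YAML config file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "variables" not in raw:
        raise SchemeError(f"{path}: scheme file needs a 'variables' list")
    variables = []
    for entry in raw["variables"]:
        try:
            variables.append(
                QuasiIdentifier(
                    name=str(entry["name"]),
                    n_categories=int(entry["n_categories"]),
                    utility_class=entry.get("utility_class", "sensitive"),
                    ethnicity_group_member=bool(
                        entry.get("ethnicity_group_member", False)
                    ),
                )
            )
        except (KeyError, TypeError) as exc:
            raise SchemeError(f"{path}: malformed variable entry {entry!r}") from exc
    return QidScheme(
        variables=tuple(variables),
        ethnicity_variants=tuple(raw.get("ethnicity_variants", ())),
    )


def save_scheme(scheme: QidScheme, path) -> None:
    payload = {
        "variables": [
            {
                "name": v.name,
                "n_categories": v.n_categories,
                "utility_class": v.utility_class,
                "ethnicity_group_member": v.ethnicity_group_member,
            }
            for v in scheme.variables
        ],
        "ethnicity_variants": list(scheme.ethnicity_variants),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False), encoding="utf-8")


# ---------------------------------------------------------------------------
# suppression-report JSON
# ---------------------------------------------------------------------------

_SCHEMA_PATH = Path(__file__).parent / "schemas" / "suppression_report.json"


def _report_schema() -> dict:
    return json.loads(_SCHEMA_PATH.read_text(encoding="utf-8"))


def validate_report(payload: dict) -> None:
    """Check a suppression-report dict against the shipped schema.

    Minimal structural validator: required keys, primitive types, and the
    per-area entry layout.  Raises :class:`DataValidationError` on the first
    violation.
    """
    schema = _report_schema()
    _validate_node(payload, schema, "$")


_TYPES = {
    "object": dict, "array": list, "string": str,
    "number": (int, float), "integer": int, "boolean": bool,
}


def _validate_node(value, schema: dict, where: str) -> None:
    expected = schema.get("type")
    if expected is not None:
        if expected == "number" and isinstance(value, bool):
            raise DataValidationError(f"{where}: expected number, got bool")
        if not isinstance(value, _TYPES[expected]):
            raise DataValidationError(
                f"{where}: expected {expected}, got {type(value).__name__}"
            )
    if expected == "object":
        for key in schema.get("required", ()):
            if key not in value:
                raise DataValidationError(f"{where}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                _validate_node(value[key], sub, f"{where}.{key}")
    elif expected == "array" and "items" in schema:
        for i, item in enumerate(value):
            _validate_node(item, schema["items"], f"{where}[{i}]")
    if "enum" in schema and value not in schema["enum"]:
        raise DataValidationError(f"{where}: {value!r} not in {schema['enum']}")


def write_report(payload: dict, path) -> None:
    validate_report(payload)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
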