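"""Delimited-text I/O and schema validation for exposure tables.

All tables are comma-separated UTF-8 text with a header row and ``NA``
for missing values.  Validation enforces the structural rules the
analysis depends on, most importantly that stage-at-parasitism is
present exactly when the host was parasitized, and reports row-level
diagnostics instead of failing opaquely.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import pandas as pd

from .params import STAGES
from .simulate import EXPOSURE_COLUMNS, REFERENCE_COLUMNS

_BOOL_COLS = ("host_died", "host_emerged", "parasitized")


class SchemaError(ValueError):
    """A table failed validation; ``diagnostics`` lists the violations."""

    def __init__(self, message: str, diagnostics: pd.DataFrame):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class ValidationResult:
    ok: bool
    table: pd.DataFrame | None
    diagnostics: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["row", "column", "rule", "message"])
    )


def write_exposure_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, na_rep="NA")


def write_reference_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, na_rep="NA")


def read_exposure_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    for col in _BOOL_COLS:
        if col in df.columns:
            df[col] = df[col].map({True: True, False: False, "True": True, "False": False})
    return df


def read_reference_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=["NA"])


def validate_exposure_table(source) -> ValidationResult:
    """Validate an exposure table (path or DataFrame).

    Checks the column schema, value ranges, and the structural
    missingness rules; returns row/column diagnostics on failure.
    """
    diags: list[dict] = []

    def add(row, column, rule, message):
        diags.append({"row": row, "column": column, "rule": rule, "message": message})

    if not isinstance(source, pd.DataFrame):
        try:
            df = read_exposure_csv(source)
        except pd.errors.EmptyDataError:
            add(None, None, "nonempty", "file has no content")
            return ValidationResult(False, None, pd.DataFrame(diags))
    else:
        df = source.copy()
    if len(df) == 0:
        add(None, None, "nonempty", "table has no rows")
        return ValidationResult(False, None, pd.DataFrame(diags))

    missing_cols = [c for c in EXPOSURE_COLUMNS if c not in df.columns]
    for c in missing_cols:
        add(None, c, "columns", f"required column {c!r} missing")
    if missing_cols:
        return ValidationResult(False, None, pd.DataFrame(diags))

    if df["host_id"].duplicated().any():
        for r in df.index[df["host_id"].duplicated()]:
            add(int(r), "host_id", "unique-id", "duplicate host_id")

    age = pd.to_numeric(df["age_at_exposure"], errors="coerce")
    for r in df.index[age.isna() | (age <= 0)]:
        add(int(r), "age_at_exposure", "positive-age", "age must be a positive number")

    for col in _BOOL_COLS:
        vals = df[col]
        bad = ~vals.isin([True, False])
        for r in df.index[bad]:
            add(int(r), col, "boolean", f"{col} must be true/false")

    stage = df["stage_at_parasitism"]
    known = stage.isna() | stage.isin(STAGES)
    for r in df.index[~known]:
        add(int(r), "stage_at_parasitism", "stage-labels", f"unknown stage {stage[r]!r}")

    par = df["parasitized"] == True  # noqa: E712 - may hold non-bool junk
    has_stage = stage.notna()
    for r in df.index[par & ~has_stage]:
        add(int(r), "stage_at_parasitism", "stage-iff-parasitized", "parasitized host lacks a stage")
    for r in df.index[~par & has_stage]:
        add(int(r), "stage_at_parasitism", "stage-iff-parasitized", "unparasitized host has a stage")

    eggs = pd.to_numeric(df["n_eggs"], errors="coerce")
    for r in df.index[par & (eggs.isna() | (eggs < 1))]:
        add(int(r), "n_eggs", "eggs-when-parasitized", "parasitized host needs n_eggs >= 1")
    for r in df.index[~par & eggs.notna()]:
        add(int(r), "n_eggs", "eggs-when-parasitized", "unparasitized host has n_eggs")

    for col in ("sex", "development_time", "emergence_mass", "hind_tibia_length"):
        present = df[col].notna()
        for r in df.index[present & ~par]:
            add(int(r), col, "traits-only-if-parasitized", f"{col} present on unparasitized host")

    diagnostics = pd.DataFrame(diags, columns=["row", "column", "rule", "message"])
    return ValidationResult(len(diags) == 0, df if len(diags) == 0 else None, diagnostics)


def validate_reference_table(source) -> ValidationResult:
    diags: list[dict] = []
    df = source if isinstance(source, pd.DataFrame) else read_reference_csv(source)
    if len(df) == 0:
        diags.append({"row": None, "column": None, "rule": "nonempty", "message": "no rows"})
        return ValidationResult(False, None, pd.DataFrame(diags))
    for c in REFERENCE_COLUMNS:
        if c not in df.columns:
            diags.append({"row": None, "column": c, "rule": "columns", "message": f"missing column {c!r}"})
    if not diags:
        bad_stage = ~df["stage"].isin(STAGES)
        for r in df.index[bad_stage]:
            diags.append({"row": int(r), "column": "stage", "rule": "stage-labels", "message": "unknown stage"})
        bad_mass = pd.to_numeric(df["dry_biomass"], errors="coerce") <= 0
        for r in df.index[bad_mass.fillna(True)]:
            diags.append({"row": int(r), "column": "dry_biomass", "rule": "positive-biomass", "message": "biomass must be > 0"})
    diagnostics = pd.DataFrame(diags, columns=["row", "column", "rule", "message"])
    return ValidationResult(len(diags) == 0, df if len(diags) == 0 else None, diagnostics)
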