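"""Data model and table input/output.

All tables are pandas DataFrames exchanged as plain CSV (UTF-8, header row,
dot decimal separator).  Every percentage column is stored in percent units
(0-100) so the analysis thresholds (0.01 %WBC inclusion, 0.1 %WBC change
floor) can be compared against values exactly as printed.

Table kinds
-----------
``barcode_counts``
    One row per (mouse, time point, cell type, barcode) with the raw
    sequencing read count for that barcode.
``facs_panel``
    One row per (mouse, time point, cell type) with the FACS fractions
    needed to scale barcode read fractions to population abundance:
    the cell type's share of white blood cells, the donor chimerism within
    the cell type, and the GFP+ (barcoded) share among donor cells.
``mice``
    Mouse metadata: identifier, optional ground-truth aging group, and the
    month of the end time point (15, or 12 for mice that reached
    end-of-life early).
``clone_abundance``
    One row per (mouse, time point, cell type, barcode) with abundance in
    %WBC for blood cell types or % of all HSCs for the HSC compartment.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd


class CellType(str, enum.Enum):
    """Cell compartments tracked by the pipeline.

    Lineage-bias computations use exactly GR (granulocytes, myeloid) and B
    (B cells, lymphoid); HSC is used by the expansion and differentiation
    stages.  CD4/CD8 T-cell codes are accepted in input tables but ignored
    by the lineage-bias stages.
    """

    GR = "GR"
    B = "B"
    HSC = "HSC"
    CD4 = "CD4"
    CD8 = "CD8"


#: Blood cell types that participate in the lineage-bias analysis.
BLOOD_CELL_TYPES = (CellType.GR.value, CellType.B.value)


class TimePoint(str, enum.Enum):
    """Named time points of the transplantation time course.

    ``initial`` is 4 months post-transplantation (hematopoiesis stabilised),
    ``pre_divergent`` is 9 months (just before early- and delayed-aging mice
    diverge) and ``end`` is 15 months, or 12 for mice that reached their
    end-of-life before the 15-month mark.  ``mid`` is an optional
    intermediate time point used only by the temporal-dynamics export.
    """

    INITIAL = "initial"
    MID = "mid"
    PRE_DIVERGENT = "pre_divergent"
    END = "end"


#: Canonical ordering of time point labels (strictly increasing in months).
TIMEPOINT_ORDER = ("initial", "mid", "pre_divergent", "end")

#: Default month assignment per label.
TIMEPOINT_MONTHS = {"initial": 4, "mid": 6, "pre_divergent": 9, "end": 15}


class SchemaError(ValueError):
    """Raised when an input table violates its documented schema."""


@dataclass(frozen=True)
class TableSchema:
    name: str
    columns: tuple[str, ...]
    key: tuple[str, ...]
    numeric: tuple[str, ...]
    percent: tuple[str, ...] = ()


SCHEMAS: dict[str, TableSchema] = {
    "barcode_counts": TableSchema(
        name="barcode_counts",
        columns=("mouse_id", "time_point", "cell_type", "barcode_id", "read_count"),
        key=("mouse_id", "time_point", "cell_type", "barcode_id"),
        numeric=("read_count",),
    ),
    "facs_panel": TableSchema(
        name="facs_panel",
        columns=(
            "mouse_id",
            "time_point",
            "cell_type",
            "celltype_pct_of_wbc",
            "donor_pct",
            "gfp_pct_among_donor",
        ),
        key=("mouse_id", "time_point", "cell_type"),
        numeric=("celltype_pct_of_wbc", "donor_pct", "gfp_pct_among_donor"),
        percent=("celltype_pct_of_wbc", "donor_pct", "gfp_pct_among_donor"),
    ),
    "mice": TableSchema(
        name="mice",
        columns=("mouse_id", "group_truth", "end_month"),
        key=("mouse_id",),
        numeric=("end_month",),
    ),
    "clone_abundance": TableSchema(
        name="clone_abundance",
        columns=("mouse_id", "time_point", "cell_type", "barcode_id", "abundance"),
        key=("mouse_id", "time_point", "cell_type", "barcode_id"),
        numeric=("abundance",),
    ),
}


def validate_table(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    """Check ``df`` against the schema for table ``kind``.

    Returns the validated frame (with numeric columns coerced).  Raises
    :class:`SchemaError` naming the offending column or row on missing
    columns, non-numeric cells, duplicate keys, negative counts or
    out-of-range percentages.
    """
    try:
        schema = SCHEMAS[kind]
    except KeyError:
        raise SchemaError(f"unknown table kind {kind!r}") from None

    for col in schema.columns:
        if col not in df.columns:
            raise SchemaError(f"table {kind!r} is missing required column {col!r}")

    df = df.loc[:, list(schema.columns)].copy()
    for col in schema.numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"table {kind!r}: non-numeric value in column {col!r} at row {row}"
            )
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise SchemaError(f"table {kind!r}: missing value in column {col!r} at row {row}")
        df[col] = coerced

    dup = df.duplicated(subset=list(schema.key))
    if dup.any():
        row = int(dup.idxmax())
        raise SchemaError(
            f"table {kind!r}: duplicate key {tuple(df.loc[row, list(schema.key)])} at row {row}"
        )

    if kind == "barcode_counts" and (df["read_count"] < 0).any():
        row = int((df["read_count"] < 0).idxmax())
        raise SchemaError(f"table {kind!r}: negative read_count at row {row}")
    if kind == "clone_abundance" and (df["abundance"] < 0).any():
        row = int((df["abundance"] < 0).idxmax())
        raise SchemaError(f"table {kind!r}: negative abundance at row {row}")
    for col in schema.percent:
        out = (df[col] < 0) | (df[col] > 100)
        if out.any():
            row = int(out.idxmax())
            raise SchemaError(
                f"table {kind!r}: column {col!r} outside [0, 100] at row {row}"
            )
    return df


def load_table(path, kind: str) -> pd.DataFrame:
    """Read a CSV table of the given kind and validate it."""
    df = pd.read_csv(path, dtype=str)
    return validate_table(df, kind)


def write_table(df: pd.DataFrame, path, kind: str | None = None) -> None:
    """Write a table as canonical CSV (validating first when ``kind`` given)."""
    if kind is not None:
        df = validate_table(df, kind)
    df.to_csv(path, index=False)


def timepoint_months(label: str, end_month: int = 15) -> float:
    """Months post-transplantation for a time point label."""
    if label == TimePoint.END.value:
        return float(end_month)
    return float(TIMEPOINT_MONTHS[label])
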