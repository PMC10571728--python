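"""Readers and writers for every table the pipeline consumes or emits.

All tables are plain CSV with snake_case headers; a mapping layer loads
genuine Skyline transition exports (``dialect="skyline"``).  Missing areas
are empty fields and stay distinct from 0 (0 means an integrated but empty
peak).  Every reader validates its schema and raises :class:`SchemaError`
with row-numbered diagnostics.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd


class SchemaError(ValueError):
    """Input table violates the documented schema or an invariant."""


TRANSITION_COLUMNS = [
    "sample_id", "plate", "well", "protein", "peptide",
    "precursor_charge", "fragment", "product_charge", "label",
    "area", "rt_min", "irt_ref", "dotp",
]
TRANSITION_KEY = [
    "sample_id", "peptide", "precursor_charge", "fragment",
    "product_charge", "label",
]
PANEL_COLUMNS = ["protein", "peptide", "standard_id", "spike_conc_pmol_per_ul"]
MANIFEST_COLUMNS = ["sample_id", "plate", "well", "sample_type", "cancer", "sex"]

# Header translation for Skyline transition-report exports.
SKYLINE_HEADER_MAP = {
    "Replicate Name": "sample_id",
    "Protein Name": "protein",
    "Peptide Modified Sequence": "peptide",
    "Precursor Charge": "precursor_charge",
    "Fragment Ion": "fragment",
    "Product Charge": "product_charge",
    "Isotope Label Type": "label",
    "Area": "area",
    "Retention Time": "rt_min",
    "iRT": "irt_ref",
    "Library Dot Product": "dotp",
}


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def _numeric(df: pd.DataFrame, column: str, what: str) -> pd.Series:
    raw = df[column]
    converted = pd.to_numeric(raw, errors="coerce")
    bad = converted.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise SchemaError(
            f"{what}: non-numeric value {raw[bad].iloc[0]!r} in column "
            f"'{column}' at file row {row}")
    return converted


def read_transition_report(path: str | Path, dialect: str = "native") -> pd.DataFrame:
    """Load and validate a transition-level quantification report.

    Parameters
    ----------
    path:
        CSV file with the documented snake_case header (or a Skyline
        export when ``dialect="skyline"``).
    dialect:
        ``"native"`` or ``"skyline"``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    if dialect == "skyline":
        df = df.rename(columns=SKYLINE_HEADER_MAP)
        if "plate" not in df.columns:
            df["plate"] = ""
        if "well" not in df.columns:
            df["well"] = ""
        if "irt_ref" not in df.columns:
            df["irt_ref"] = np.nan
    elif dialect != "native":
        raise ValueError(f"unknown dialect {dialect!r}")
    _require_columns(df, TRANSITION_COLUMNS, "transition report")
    df = df[TRANSITION_COLUMNS].copy()

    for col in ("area", "rt_min", "irt_ref", "dotp"):
        df[col] = _numeric(df, col, "transition report")
    for col in ("precursor_charge", "product_charge"):
        vals = _numeric(df, col, "transition report")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 2
            raise SchemaError(f"transition report: empty '{col}' at file row {row}")
        df[col] = vals.astype(int)
        if (df[col] < 1).any():
            raise SchemaError(f"transition report: '{col}' must be >= 1")

    label_norm = df["label"].str.lower()
    bad = ~label_norm.isin(["light", "heavy"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise SchemaError(
            f"transition report: label must be 'light' or 'heavy', got "
            f"{df['label'][bad].iloc[0]!r} at file row {row}")
    df["label"] = label_norm

    if (df["area"].dropna() < 0).any():
        raise SchemaError("transition report: negative area")

    dup = df.duplicated(subset=TRANSITION_KEY, keep=False)
    if dup.any():
        rows = (np.flatnonzero(dup.to_numpy())[:2] + 2).tolist()
        raise SchemaError(
            f"transition report: duplicate (sample, peptide, charges, fragment, "
            f"label) key at file rows {rows}")
    return df


def write_transition_report(path: str | Path, df: pd.DataFrame) -> None:
    df[TRANSITION_COLUMNS].to_csv(path, index=False)


def read_panel(path: str | Path) -> pd.DataFrame:
    """Load the spike-in panel (protein, peptide, spiked concentration)."""
    df = pd.read_csv(path, dtype={"protein": str, "peptide": str, "standard_id": str})
    _require_columns(df, PANEL_COLUMNS, "panel")
    df = df[PANEL_COLUMNS].copy()
    conc = _numeric(df, "spike_conc_pmol_per_ul", "panel")
    if conc.isna().any() or (conc <= 0).any():
        raise SchemaError("panel: spike_conc_pmol_per_ul must be present and > 0")
    df["spike_conc_pmol_per_ul"] = conc
    dup = df.duplicated(subset=["protein", "peptide"], keep=False)
    if dup.any():
        rows = (np.flatnonzero(dup.to_numpy())[:2] + 2).tolist()
        raise SchemaError(f"panel: duplicate (protein, peptide) at file rows {rows}")
    return df


def write_panel(path: str | Path, df: pd.DataFrame) -> None:
    df[PANEL_COLUMNS].to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate the sample manifest."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, MANIFEST_COLUMNS, "manifest")
    df = df[MANIFEST_COLUMNS].copy()
    if df["sample_id"].duplicated().any():
        dup_id = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise SchemaError(f"manifest: duplicate sample_id {dup_id!r}")
    bad_type = ~df["sample_type"].isin(["patient", "pool"])
    if bad_type.any():
        raise SchemaError(
            f"manifest: sample_type must be patient|pool, got "
            f"{df['sample_type'][bad_type].iloc[0]!r}")
    pool_with_cancer = (df["sample_type"] == "pool") & (df["cancer"].str.strip() != "")
    if pool_with_cancer.any():
        row = int(np.flatnonzero(pool_with_cancer.to_numpy())[0]) + 2
        raise SchemaError(f"manifest: pool row carries a cancer label at file row {row}")
    return df


def write_manifest(path: str | Path, df: pd.DataFrame) -> None:
    df[MANIFEST_COLUMNS].to_csv(path, index=False)


# ----------------------------------------------------------------------
# Output tables
# ----------------------------------------------------------------------

def write_matrix(path: str | Path, matrix: pd.DataFrame) -> None:
    """Write a wide samples x analytes concentration matrix."""
    out = matrix.copy()
    out.index.name = "sample_id"
    out.to_csv(path)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="sample_id")


def write_de_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_de_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json_report(path: str | Path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)


def read_json_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# Aliases matching the module surface named in the docs.
write_classifier_report = write_json_report
read_classifier_report = read_json_report
write_qc_report = write_json_report
read_qc_report = read_json_report
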