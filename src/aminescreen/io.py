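"""Readers, writers and validation for the long-format screen tables.

All tables are tidy: one row per measured well (growth) or per well x
metabolite (metabolomics), with the batch, acquisition order, 96-well plate,
well coordinate and sample role carried on every row. Batch acquisition
order is first-class because the drift correction operates on it.

Sample roles
------------
``experimental``           compound-treated culture well
``dmso_control``           solvent-only culture well (plate-matched reference)
``tetracycline_control``   the plate's single antibiotic control well
``blank``                  medium/solvent blank in the acquisition sequence
``qc``                     pooled quality-control injection
``standard``               calibration-standard injection (levels 1-6)
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROLES = (
    "experimental",
    "dmso_control",
    "tetracycline_control",
    "blank",
    "qc",
    "standard",
)

CULTURE_ROLES = ("experimental", "dmso_control", "tetracycline_control")

#: columns required in a metabolite measurement table
METABOLITE_COLUMNS = (
    "batch_id",
    "acquisition_index",
    "plate_id",
    "well",
    "role",
    "species",
    "replicate",
    "compound_id",
    "metabolite",
    "raw_conc_uM",
)

#: columns required in a growth (absorbance) table
GROWTH_COLUMNS = (
    "batch_id",
    "plate_id",
    "well",
    "role",
    "species",
    "replicate",
    "compound_id",
    "raw_absorbance",
    "blank",
)

#: optional growth columns filled with defaults when absent
GROWTH_OPTIONAL = ("compound_background",)

LIBRARY_COLUMNS = ("compound_id", "name", "library_class")

LIBRARY_CLASSES = ("drug", "pesticide", "industrial", "sweetener")


class SchemaError(ValueError):
    """A required column is missing or mistyped."""


class ValidationError(ValueError):
    """Table contents violate a structural invariant."""


def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing required column(s): {', '.join(missing)}")


def read_measurements(
    path,
    schema: str = "metabolite",
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a long-format measurement table (CSV/TSV) and validate it.

    Parameters
    ----------
    path
        File with a header row, UTF-8.
    schema
        ``"metabolite"`` (concentrations) or ``"growth"`` (absorbances).
    column_map
        Optional mapping from the file's column names to the canonical
        names, for tables exported with different headers.
    sep
        Field separator; inferred from the filename (``.tsv`` -> tab) when
        omitted.
    """
    if schema not in ("metabolite", "growth"):
        raise ValueError(f"schema must be 'metabolite' or 'growth', got {schema!r}")
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"well": "string"})
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = METABOLITE_COLUMNS if schema == "metabolite" else GROWTH_COLUMNS
    _require_columns(df, required, schema)
    if schema == "growth":
        for col in GROWTH_OPTIONAL:
            if col not in df.columns:
                logger.info("growth table has no %r column; defaulting to 0", col)
                df[col] = 0.0
    return coerce_measurements(df, schema=schema)


def coerce_measurements(df: pd.DataFrame, schema: str = "metabolite") -> pd.DataFrame:
    """Coerce dtypes and run structural validation without changing values."""
    df = df.copy()
    for col in ("batch_id", "plate_id", "well", "role", "species"):
        if col in df.columns:
            df[col] = df[col].astype("string")
    df["compound_id"] = df["compound_id"].astype("string")
    df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype("Int64")
    if schema == "metabolite":
        df["acquisition_index"] = pd.to_numeric(df["acquisition_index"], errors="raise")
        if (df["acquisition_index"].dropna() % 1 != 0).any():
            raise SchemaError("acquisition_index must be integral")
        df["acquisition_index"] = df["acquisition_index"].astype("int64")
        if (df["acquisition_index"] < 0).any():
            raise ValidationError("acquisition_index must be non-negative")
        df["metabolite"] = df["metabolite"].astype("string")
        df["raw_conc_uM"] = pd.to_numeric(df["raw_conc_uM"], errors="coerce")
        dup = df.duplicated(["batch_id", "acquisition_index", "metabolite"])
        if dup.any():
            pair = df.loc[dup, ["batch_id", "acquisition_index"]].iloc[0]
            raise ValidationError(
                "duplicate (batch_id, acquisition_index) within a metabolite: "
                f"({pair['batch_id']}, {pair['acquisition_index']})"
            )
    else:
        for col in ("raw_absorbance", "blank", "compound_background"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
    bad_roles = set(df["role"].dropna().unique()) - set(ROLES)
    if bad_roles:
        raise ValidationError(f"unknown sample role(s): {sorted(bad_roles)}")
    validate_plate_layout(df)
    return df


def validate_plate_layout(df: pd.DataFrame) -> list[str]:
    """Check per-plate control structure; warn (never mutate) on violations.

    Each 96-well plate is expected to carry 10-13 DMSO control wells and
    exactly one tetracycline control well. Experimental rows must name a
    compound; DMSO control rows must not.
    """
    warnings: list[str] = []
    exp = df[df["role"] == "experimental"]
    if exp["compound_id"].isna().any():
        raise ValidationError("experimental rows must carry a compound_id")
    dmso = df[df["role"] == "dmso_control"]
    if dmso["compound_id"].notna().any():
        raise ValidationError("dmso_control rows must not carry a compound_id")
    plates = df[df["role"].isin(CULTURE_ROLES) & df["plate_id"].notna()]
    for (batch, plate), sub in plates.groupby(["batch_id", "plate_id"], observed=True):
        wells = sub.drop_duplicates("well")
        n_dmso = int((wells["role"] == "dmso_control").sum())
        n_tet = int((wells["role"] == "tetracycline_control").sum())
        if not 10 <= n_dmso <= 13:
            warnings.append(f"plate {plate} (batch {batch}): {n_dmso} DMSO controls, expected 10-13")
        if n_tet != 1:
            warnings.append(f"plate {plate} (batch {batch}): {n_tet} tetracycline wells, expected 1")
    for msg in warnings:
        logger.warning("%s", msg)
    return warnings


def read_compound_library(path, sep: str | None = None) -> pd.DataFrame:
    """Read the compound-library metadata table.

    The ``therapeutic_classes`` field is a ``;``-separated label list in the
    file and a Python set in memory; an empty field parses to the empty set.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    _require_columns(df, LIBRARY_COLUMNS, "compound library")
    if df["compound_id"].duplicated().any():
        dup = df.loc[df["compound_id"].duplicated(), "compound_id"].iloc[0]
        raise ValidationError(f"duplicate compound_id in library: {dup!r}")
    bad = set(df["library_class"].dropna().unique()) - set(LIBRARY_CLASSES)
    if bad:
        raise ValidationError(f"unknown library_class value(s): {sorted(bad)}")
    if df["library_class"].isna().any():
        raise ValidationError("library_class must be present for every compound")
    if "therapeutic_classes" not in df.columns:
        df["therapeutic_classes"] = ""
    df["therapeutic_classes"] = df["therapeutic_classes"].map(parse_class_field)
    if "antibiotic_class" not in df.columns:
        df["antibiotic_class"] = pd.NA
    return df


def parse_class_field(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or pd.isna(value):
        return frozenset()
    if isinstance(value, frozenset):
        return value
    labels = [part.strip() for part in str(value).split(";")]
    return frozenset(lbl for lbl in labels if lbl)


def format_class_field(value: frozenset[str] | str) -> str:
    if isinstance(value, (set, frozenset)):
        return ";".join(sorted(value))
    return str(value)


def write_results(tables: Mapping[str, pd.DataFrame], out_dir) -> dict[str, str]:
    """Write named tables as CSV under ``out_dir``.

    Column order is preserved as given, floats keep full round-trip
    precision (``repr`` formatting), and missing values serialise as empty
    fields, so a rerun on identical input is byte-identical.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    written: dict[str, str] = {}
    for name, table in tables.items():
        path = os.path.join(out_dir, f"{name}.csv")
        out = table.copy()
        for col in out.columns:
            if out[col].map(lambda v: isinstance(v, (set, frozenset))).any():
                out[col] = out[col].map(format_class_field)
        out.to_csv(path, index=False, na_rep="")
        written[name] = path
    return written
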