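"""Validated readers and writers for plate maps, readings and metric tables.

The entry format is a pair of CSVs: a *plate map* annotating each well
(model line, drug, dose, role) and a *readings* file with the raw
luminescence per well. The exit format is a *metrics* CSV with one row of
dose-response statistics per (model, drug) pair, using the literal string
``NA`` for metrics that are undefined (for example a GR50 when the fitted
curve never crosses 0.5).
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import numpy as np
import pandas as pd

ROLES = ("treated", "vehicle", "day0")

#: µM per unit, for the optional dose_unit column.
_UNIT_TO_UM = {"um": 1.0, "µm": 1.0, "μm": 1.0, "nm": 1e-3, "mm": 1e3, "m": 1e6}

PLATE_MAP_COLUMNS = [
    "plate_id", "well", "model_id", "drug_id", "dose_uM", "role", "bio_rep", "tech_rep",
]
READINGS_COLUMNS = ["plate_id", "well", "luminescence"]

#: Column order of metrics.csv. Concentrations are µM.
METRIC_COLUMNS = [
    "model_id", "drug_id", "GR50", "GEC50", "GR_inf", "hill", "GR_aoc",
    "cytostatic_uM", "EC50", "IC50", "GI50", "fit_type_gr", "fit_type_rv", "n_points",
]
_FLOAT_METRICS = ["GR50", "GEC50", "GR_inf", "hill", "GR_aoc", "cytostatic_uM", "EC50", "IC50", "GI50"]

_WELL_RE = re.compile(r"^([A-Pa-p])(\d{1,2})$")


@dataclasses.dataclass(frozen=True)
class PlateRecord:
    """One well: annotation plus its raw luminescence reading."""

    plate_id: str
    well: str
    model_id: str
    drug_id: str
    dose_uM: float
    role: str
    bio_rep: int
    tech_rep: int
    luminescence: float


class ScreenFormatError(ValueError):
    """A plate map / readings / metrics file violated its schema."""


def normalize_well(well: str) -> str:
    """Normalize a well name to row letter + two-digit column ("a1" -> "A01")."""
    m = _WELL_RE.match(str(well).strip())
    if not m:
        raise ScreenFormatError(f"invalid well name {well!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if not 1 <= col <= 24:
        raise ScreenFormatError(f"well column out of range in {well!r}")
    return f"{row}{col:02d}"


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ScreenFormatError(f"{what} is missing columns {missing}")


def read_screen(plate_map_path: str | Path, readings_path: str | Path) -> pd.DataFrame:
    """Read and join a plate map with its readings into validated records.

    Returns a DataFrame with one row per well (the :class:`PlateRecord`
    fields as columns). Every readings row must match exactly one map row
    on (plate_id, well); doses are converted to µM if the map carries a
    ``dose_unit`` column.

    Raises
    ------
    ScreenFormatError
        On unmatched or duplicate wells, negative luminescence, or any
        role/dose inconsistency.
    """
    pm = pd.read_csv(plate_map_path, dtype={"plate_id": str, "well": str})
    rd = pd.read_csv(readings_path, dtype={"plate_id": str, "well": str})
    _require_columns(pm, PLATE_MAP_COLUMNS, "plate map")
    _require_columns(rd, READINGS_COLUMNS, "readings file")

    pm = pm.copy()
    pm["well"] = pm["well"].map(normalize_well)
    rd = rd.copy()
    rd["well"] = rd["well"].map(normalize_well)

    if "dose_unit" in pm.columns:
        factors = pm["dose_unit"].astype(str).str.strip().str.lower().map(_UNIT_TO_UM)
        if factors.isna().any():
            bad = pm.loc[factors.isna(), "dose_unit"].unique()
            raise ScreenFormatError(f"unknown dose units {list(bad)}")
        pm["dose_uM"] = pm["dose_uM"].astype(float) * factors
        pm = pm.drop(columns=["dose_unit"])

    for df, what in ((pm, "plate map"), (rd, "readings")):
        dup = df.duplicated(subset=["plate_id", "well"])
        if dup.any():
            key = df.loc[dup, ["plate_id", "well"]].iloc[0]
            raise ScreenFormatError(
                f"duplicate (plate, well) in {what}: {key.plate_id}/{key.well}"
            )

    merged = rd.merge(pm, on=["plate_id", "well"], how="left", indicator=True)
    unmatched = merged["_merge"] == "left_only"
    if unmatched.any():
        key = merged.loc[unmatched, ["plate_id", "well"]].iloc[0]
        raise ScreenFormatError(f"unmatched well {key.plate_id}/{key.well} in readings")
    merged = merged.drop(columns=["_merge"])

    merged["luminescence"] = merged["luminescence"].astype(float)
    if (merged["luminescence"] < 0).any():
        key = merged.loc[merged["luminescence"] < 0, ["plate_id", "well"]].iloc[0]
        raise ScreenFormatError(f"negative luminescence at {key.plate_id}/{key.well}")
    merged["dose_uM"] = merged["dose_uM"].astype(float)
    merged["bio_rep"] = merged["bio_rep"].astype(int)
    merged["tech_rep"] = merged["tech_rep"].astype(int)
    if (merged["bio_rep"] < 1).any() or (merged["tech_rep"] < 1).any():
        raise ScreenFormatError("bio_rep and tech_rep must be positive integers")

    bad_role = ~merged["role"].isin(ROLES)
    if bad_role.any():
        raise ScreenFormatError(
            f"unknown role {merged.loc[bad_role, 'role'].iloc[0]!r}; expected {ROLES}"
        )
    merged["drug_id"] = merged["drug_id"].fillna("").astype(str)

    controls = merged["role"].isin(("vehicle", "day0"))
    if (merged.loc[controls, "dose_uM"] != 0).any() or (merged.loc[controls, "drug_id"] != "").any():
        raise ScreenFormatError("vehicle/day0 wells must have empty drug_id and dose 0")
    treated = merged["role"] == "treated"
    if (merged.loc[treated, "dose_uM"] <= 0).any() or (merged.loc[treated, "drug_id"] == "").any():
        raise ScreenFormatError("treated wells must have dose > 0 and a drug_id")

    return merged[PLATE_MAP_COLUMNS + ["luminescence"]]


def records_to_dataclasses(records: pd.DataFrame) -> list[PlateRecord]:
    """Materialize validated record rows as :class:`PlateRecord` objects."""
    return [PlateRecord(**row) for row in records.to_dict("records")]


def write_screen(records: pd.DataFrame, plate_map_path: str | Path,
                 readings_path: str | Path) -> tuple[Path, Path]:
    """Split validated records back into plate-map and readings CSVs."""
    plate_map_path, readings_path = Path(plate_map_path), Path(readings_path)
    records[PLATE_MAP_COLUMNS].to_csv(plate_map_path, index=False)
    records[READINGS_COLUMNS].to_csv(readings_path, index=False)
    return plate_map_path, readings_path


def validate_metrics(table: pd.DataFrame) -> pd.DataFrame:
    """Check a metrics table and return it with canonical column order."""
    _require_columns(table, METRIC_COLUMNS, "metrics table")
    dup = table.duplicated(subset=["model_id", "drug_id"])
    if dup.any():
        key = table.loc[dup, ["model_id", "drug_id"]].iloc[0]
        raise ScreenFormatError(f"duplicate metrics row for {key.model_id}/{key.drug_id}")
    fitted = table["fit_type_gr"].notna()
    if table.loc[fitted, "GR_aoc"].isna().any():
        raise ScreenFormatError("GR_aoc must not be NA when a GR fit exists")
    return table[METRIC_COLUMNS]


def write_metrics(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a metrics table with ``NA`` sentinels; round-trips via read_metrics."""
    table = validate_metrics(table)
    path = Path(path)
    table.to_csv(path, index=False, na_rep="NA")
    return path


def read_metrics(path: str | Path) -> pd.DataFrame:
    """Read a metrics CSV written by :func:`write_metrics`."""
    df = pd.read_csv(
        path,
        dtype={"model_id": str, "drug_id": str, "fit_type_gr": str, "fit_type_rv": str},
        na_values=["NA"], keep_default_na=False,
    )
    df = validate_metrics(df)
    for col in _FLOAT_METRICS:
        df[col] = df[col].astype(float)
    df["n_points"] = df["n_points"].astype(int)
    return df


def empty_metrics() -> pd.DataFrame:
    """An empty metrics table with the canonical schema."""
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in METRIC_COLUMNS})
    for col in _FLOAT_METRICS:
        df[col] = df[col].astype(float)
    df["n_points"] = df["n_points"].astype(int)
    return df
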