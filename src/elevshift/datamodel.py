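"""Domain types and validated CSV ingest for occurrence and resurvey tables.

The pipeline's canonical in-memory container is a :class:`pandas.DataFrame`
with the documented column schema; the dataclasses here describe one row
and carry the per-field invariants used during validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig

HISTORICAL = "historical"
CURRENT = "current"


class HabitatPreference(str, Enum):
    """Six non-overlapping habitat-preference categories for the species pool."""

    forest = "forest"
    generalist = "generalist"
    grassland = "grassland"
    semi_natural = "semi_natural"
    subalpine = "subalpine"
    wetland = "wetland"


HABITAT_CATEGORIES: tuple[str, ...] = tuple(h.value for h in HabitatPreference)

OCCURRENCE_COLUMNS: tuple[str, ...] = (
    "site_id",
    "species_id",
    "year",
    "elevation_m",
    "count",
    "habitat_pref",
    "protected",
)

RESURVEY_COLUMNS: tuple[str, ...] = (
    "site_id",
    "species_id",
    "year_initial",
    "doy_initial",
    "year_second",
    "doy_second",
    "size_initial",
    "survived",
    "habitat_altered",
    "elevation_m",
    "habitat_pref",
)


@dataclass(frozen=True)
class OccurrenceRecord:
    """One georeferenced sighting of a species.

    ``count`` is the number of individuals observed (>= 1), ``elevation_m``
    metres above sea level.
    """

    site_id: str
    species_id: str
    year: int
    elevation_m: float
    count: int
    habitat_pref: HabitatPreference
    protected: bool | None = None


@dataclass(frozen=True)
class ResurveyRecord:
    """A paired initial/second visit of one population with survival outcome."""

    site_id: str
    species_id: str
    year_initial: int
    doy_initial: int
    year_second: int
    doy_second: int
    size_initial: int
    survived: int
    habitat_altered: str
    elevation_m: float
    habitat_pref: HabitatPreference


class SchemaError(ValueError):
    """A required column is missing or the header does not match the schema."""


class RecordValidationError(ValueError):
    """One or more rows violate the record invariants; message lists row numbers."""


def period_label(year: int | np.ndarray, config: AnalysisConfig):
    """Label a calendar year historical (<= boundary) or current (> boundary)."""
    return np.where(np.asarray(year) <= config.period_boundary_year, HISTORICAL, CURRENT)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[out.isna() & df[col].notna()]
    if len(bad):
        rows = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise RecordValidationError(f"{path}: non-numeric values in column '{col}' at file row(s) {rows}")
    return out


def _collect_violations(df: pd.DataFrame, mask: pd.Series, reason: str, bucket: List[str]) -> None:
    for i in df.index[mask]:
        bucket.append(f"row {i + 2}: {reason}")


def read_occurrences(path: str | Path, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Read and validate an occurrence CSV.

    Returns a DataFrame with the documented columns plus a ``period``
    column (historical/current, derived from the configured boundary
    year).  Rows violating the record invariants raise a
    :class:`RecordValidationError` listing the offending file rows.
    Extra columns are preserved but ignored by the pipeline.
    """
    config = config or AnalysisConfig()
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, [c for c in OCCURRENCE_COLUMNS if c != "protected"], path)
    df = df.reset_index(drop=True)
    df["year"] = _numeric(df, "year", path)
    df["elevation_m"] = _numeric(df, "elevation_m", path)
    df["count"] = _numeric(df, "count", path)

    problems: List[str] = []
    _collect_violations(df, df["count"] < 1, "count must be >= 1", problems)
    _collect_violations(df, df["elevation_m"] < 0, "elevation_m must be >= 0", problems)
    y0, y1 = config.study_window
    _collect_violations(
        df, (df["year"] < y0) | (df["year"] > y1), f"year outside study window {y0}-{y1}", problems
    )
    bad_hab = ~df["habitat_pref"].isin(HABITAT_CATEGORIES)
    _collect_violations(df, bad_hab, f"habitat_pref not one of {HABITAT_CATEGORIES}", problems)
    if problems:
        raise RecordValidationError(f"{path}: invalid occurrence rows:\n" + "\n".join(problems))

    df["year"] = df["year"].astype(int)
    df["count"] = df["count"].astype(int)
    if "protected" not in df.columns:
        df["protected"] = pd.NA
    df["period"] = period_label(df["year"].to_numpy(), config)
    return df


def read_resurvey(path: str | Path, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Read and validate a resurvey CSV (paired initial/second visits)."""
    config = config or AnalysisConfig()
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, RESURVEY_COLUMNS, path)
    df = df.reset_index(drop=True)
    for col in ("year_initial", "doy_initial", "year_second", "doy_second", "size_initial", "survived", "elevation_m"):
        df[col] = _numeric(df, col, path)

    problems: List[str] = []
    _collect_violations(df, df["year_second"] <= df["year_initial"], "year_second must exceed year_initial", problems)
    _collect_violations(df, ~df["survived"].isin([0, 1]), "survived must be 0 or 1", problems)
    _collect_violations(df, df["size_initial"] < 1, "size_initial must be >= 1", problems)
    for col in ("doy_initial", "doy_second"):
        _collect_violations(df, (df[col] < 1) | (df[col] > 366), f"{col} must be in 1..366", problems)
    _collect_violations(df, ~df["habitat_altered"].astype(str).isin(["yes", "no"]), "habitat_altered must be yes/no", problems)
    _collect_violations(df, ~df["habitat_pref"].isin(HABITAT_CATEGORIES), f"habitat_pref not one of {HABITAT_CATEGORIES}", problems)
    if problems:
        raise RecordValidationError(f"{path}: invalid resurvey rows:\n" + "\n".join(problems))

    for col in ("year_initial", "doy_initial", "year_second", "doy_second", "size_initial", "survived"):
        df[col] = df[col].astype(int)
    return df


def read_temperatures(path: str | Path) -> pd.DataFrame:
    """Read per-record mean annual temperature values (site_id, species_id, mat_c)."""
    df = pd.read_csv(path)
    _require_columns(df, ["site_id", "species_id", "mat_c"], path)
    df["mat_c"] = _numeric(df, "mat_c", path)
    return df


def read_landolt(path: str | Path) -> pd.DataFrame:
    """Read a species-level ecological indicator lookup (light/moisture/temperature, 1-5)."""
    df = pd.read_csv(path)
    _require_columns(df, ["species_id", "light", "moisture", "temperature"], path)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a pipeline table deterministically (fixed float format, no index)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")


def standardize(values: np.ndarray) -> np.ndarray:
    """Centre to mean 0 and scale to sample SD 1 (divisor n-1)."""
    values = np.asarray(values, dtype=float)
    sd = np.std(values, ddof=1)
    return (values - values.mean()) / sd


def standardize_elevation(df: pd.DataFrame, group_col: str = "species_id", elev_col: str = "elevation_m") -> pd.DataFrame:
    """Add a per-species standardized elevation column ``elevation_std``.

    Within each species, elevation is centred to mean 0 and scaled to
    sample SD 1 so that elevational positions are comparable among
    species: the most negative values correspond to the rear (low)
    edge.  Species with fewer than two distinct elevations cannot be
    standardized; their rows get ``NaN`` and a warning is emitted.
    """
    df = df.copy()
    out = np.full(len(df), np.nan)
    degenerate: List[str] = []
    for sp, idx in df.groupby(group_col, sort=False).groups.items():
        vals = df.loc[idx, elev_col].to_numpy(dtype=float)
        if len(vals) < 2 or np.std(vals, ddof=1) == 0:
            degenerate.append(str(sp))
            continue
        out[df.index.get_indexer(idx)] = standardize(vals)
    if degenerate:
        warnings.warn(
            f"standardize_elevation: excluded {len(degenerate)} species with <2 distinct elevations: "
            + ", ".join(sorted(degenerate)[:10]),
            stacklevel=2,
        )
    df["elevation_std"] = out
    return df


def records_to_frame(records: Iterable[OccurrenceRecord | ResurveyRecord]) -> pd.DataFrame:
    """Convert row dataclasses to the canonical DataFrame representation."""
    rows = []
    for r in records:
        d = r.__dict__.copy()
        if isinstance(d.get("habitat_pref"), HabitatPreference):
            d["habitat_pref"] = d["habitat_pref"].value
        rows.append(d)
    return pd.DataFrame(rows)
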