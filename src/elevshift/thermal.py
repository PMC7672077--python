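"""Realized thermal niche breadth and per-category ecological summaries.

The realized thermal niche of a species is summarized by the 5% and 95%
quantiles of the mean annual temperature (MAT) over its occurrence
records in the study area; the breadth is their difference.  The
quantile convention is shared with the range-edge computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from .quantiles import empirical_quantile


@dataclass(frozen=True)
class NicheBreadth:
    """Coldest/hottest realized MAT (5/95% quantiles) and their difference."""

    species_id: str
    mat_cold_c: float
    mat_hot_c: float
    n_records: int

    @property
    def breadth_c(self) -> float:
        return self.mat_hot_c - self.mat_cold_c


def niche_breadth(
    mat_values: np.ndarray,
    species_id: str = "",
    q: Tuple[float, float] = (0.05, 0.95),
    min_records: int = 10,
) -> NicheBreadth:
    """Realized thermal niche breadth of one species from per-record MAT."""
    x = np.asarray(mat_values, dtype=float)
    if x.size < min_records:
        raise ValueError(f"{species_id or 'species'}: need at least {min_records} MAT records, got {x.size}")
    cold, hot = empirical_quantile(x, list(q))
    return NicheBreadth(species_id=species_id, mat_cold_c=float(cold), mat_hot_c=float(hot), n_records=int(x.size))


def niche_breadth_table(temperatures: pd.DataFrame, min_records: int = 10) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species niche breadths plus a table of species with too few records."""
    rows, insufficient = [], []
    for sp, grp in temperatures.groupby("species_id", sort=True):
        try:
            nb = niche_breadth(grp["mat_c"].to_numpy(), species_id=sp, min_records=min_records)
        except ValueError:
            insufficient.append({"species_id": sp, "n_records": len(grp)})
            continue
        rows.append(
            {
                "species_id": sp,
                "mat_cold_c": nb.mat_cold_c,
                "mat_hot_c": nb.mat_hot_c,
                "breadth_c": nb.breadth_c,
                "n_records": nb.n_records,
            }
        )
    return (
        pd.DataFrame(rows, columns=["species_id", "mat_cold_c", "mat_hot_c", "breadth_c", "n_records"]),
        pd.DataFrame(insufficient, columns=["species_id", "n_records"]),
    )


def category_summaries(
    species_table: pd.DataFrame,
    variables: Tuple[str, ...] = ("light", "moisture", "temperature", "breadth_c"),
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-category median and interquartile range of indicator values.

    ``species_table`` has one row per species with ``habitat_pref`` and
    the indicator/breadth columns; species missing a variable are listed
    in the second return value and excluded from that variable's summary.
    """
    rows, missing = [], []
    for var in variables:
        if var not in species_table.columns:
            continue
        miss = species_table[species_table[var].isna()]
        for _, r in miss.iterrows():
            missing.append({"species_id": r["species_id"], "variable": var})
        ok = species_table.dropna(subset=[var])
        for cat, grp in ok.groupby("habitat_pref", sort=True):
            q1, med, q3 = np.quantile(grp[var].to_numpy(dtype=float), [0.25, 0.5, 0.75])
            rows.append(
                {
                    "habitat_pref": cat,
                    "variable": var,
                    "median": float(med),
                    "q1": float(q1),
                    "q3": float(q3),
                    "n_species": len(grp),
                }
            )
    return (
        pd.DataFrame(rows, columns=["habitat_pref", "variable", "median", "q1", "q3", "n_species"]),
        pd.DataFrame(missing, columns=["species_id", "variable"]),
    )
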