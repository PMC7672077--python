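"""Temporal trends in population size per habitat-preference category.

For each category, population count is modelled with a Poisson GLMM
(log link) on centred calendar year, species-standardized elevation
(linear + quadratic) and the time × elevation interaction, with crossed
random intercepts for species and for observation (OLRE, absorbing
extra-Poisson variation).  Species below the per-period record threshold
are excluded first, mirroring the range-shift stage's filter.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .datamodel import CURRENT, HISTORICAL, standardize_elevation
from .glmm import fit_glmm
from .modelfit import ModelFit

logger = logging.getLogger(__name__)

ABUNDANCE_TERMS = ("time", "elevation", "elevation_sq", "time_x_elevation")


def abundance_design(records: pd.DataFrame, config: AnalysisConfig) -> Tuple[np.ndarray, np.ndarray, np.ndarray, List[str], Dict[str, List[int]]]:
    """Build response, design matrix and species codes for the abundance model.

    Expects an ``elevation_std`` column (per-species standardization on
    the records entering the model).  Time is calendar year centred on
    the study-window midpoint, in years.
    """
    t = records["year"].to_numpy(dtype=float) - config.midpoint_year
    z = records["elevation_std"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(records)), t, z, z * z, t * z])
    y = records["count"].to_numpy(dtype=float)
    species, _ = pd.factorize(records["species_id"])
    coef_names = ["intercept", "time", "elevation", "elevation_sq", "time_x_elevation"]
    terms = {"time": [1], "elevation": [2], "elevation_sq": [3], "time_x_elevation": [4]}
    return y, X, species, coef_names, terms


def filter_by_period_counts(records: pd.DataFrame, config: AnalysisConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Keep species with >= min_records_per_period in both periods."""
    keep, excl = [], []
    for sp, grp in records.groupby("species_id", sort=True):
        n_h = int((grp["period"] == HISTORICAL).sum())
        n_c = int((grp["period"] == CURRENT).sum())
        if min(n_h, n_c) < config.min_records_per_period:
            excl.append({"species_id": sp, "n_historical": n_h, "n_current": n_c})
        else:
            keep.append(grp)
    kept = pd.concat(keep) if keep else records.iloc[:0]
    return kept, pd.DataFrame(excl, columns=["species_id", "n_historical", "n_current"])


def fit_abundance_model(
    records: pd.DataFrame,
    config: AnalysisConfig | None = None,
    use_lrt: bool = False,
    apply_filter: bool = True,
) -> ModelFit:
    """Fit the Poisson-OLRE GLMM for one habitat category's records."""
    config = config or AnalysisConfig()
    if apply_filter:
        records, excl = filter_by_period_counts(records, config)
        if len(excl):
            logger.info("abundance model: excluded %d species below the record threshold", len(excl))
    if records.empty:
        raise ValueError("no records left after the per-period species filter")
    if "elevation_std" not in records.columns or records["elevation_std"].isna().any():
        records = standardize_elevation(records).dropna(subset=["elevation_std"])
    y, X, species, coef_names, terms = abundance_design(records, config)
    return fit_glmm(y, X, species, family="poisson", coef_names=coef_names, terms=terms, olre=True, use_lrt=use_lrt)


def fit_abundance_by_category(
    occurrences: pd.DataFrame,
    config: AnalysisConfig | None = None,
    use_lrt: bool = False,
) -> Dict[str, ModelFit]:
    """Fit the abundance model separately for every habitat category present."""
    config = config or AnalysisConfig()
    fits: Dict[str, ModelFit] = {}
    for cat, grp in occurrences.groupby("habitat_pref", sort=True):
        try:
            fits[cat] = fit_abundance_model(grp, config, use_lrt=use_lrt)
        except ValueError as err:
            logger.warning("abundance model skipped for %s: %s", cat, err)
    return fits


def predict_surface(
    fit: ModelFit,
    time_grid: np.ndarray,
    z_grid: np.ndarray,
    z_observed_range: Tuple[float, float] | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Population-level predicted mean count over a (time, elevation) grid.

    Random effects are set to zero; the interval comes from the
    fixed-effect covariance on the link scale.  Grid points outside the
    observed standardized-elevation range trigger an extrapolation
    warning flag in the output.
    """
    from scipy import stats as _st

    if not fit.converged:
        raise ValueError("cannot predict from a non-converged fit")
    tt, zz = np.meshgrid(np.asarray(time_grid, float), np.asarray(z_grid, float), indexing="ij")
    t, z = tt.ravel(), zz.ravel()
    X = np.column_stack([np.ones(t.size), t, z, z * z, t * z])
    eta = X @ fit.coefficients
    if fit.cov is None:
        raise ValueError("fit carries no covariance matrix")
    se_eta = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov, X))
    crit = _st.norm.ppf(0.5 + level / 2)
    out = pd.DataFrame(
        {
            "time": t,
            "elevation_std": z,
            "mean_count": np.exp(eta),
            "ci_low": np.exp(eta - crit * se_eta),
            "ci_high": np.exp(eta + crit * se_eta),
        }
    )
    if z_observed_range is not None:
        lo, hi = z_observed_range
        out["extrapolated"] = (out["elevation_std"] < lo) | (out["elevation_std"] > hi)
        if out["extrapolated"].any():
            logger.warning("predict_surface: grid extends beyond the observed elevation range")
    return out
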