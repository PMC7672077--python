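"""Resurvey-based local-survival analysis.

Filters the paired initial/second visits (phenology window, species
rarity in the initial survey, minimum years between surveys), fits a
binomial GLMM of survival on elapsed time, log initial population size,
standardized elevation, habitat alteration and habitat preference with a
species random intercept, checks fixed-effect collinearity with
(generalized) variance inflation factors, models habitat alteration
against raw elevation with a plain binomial GLM, and optionally
simplifies the survival model by backward deletion of non-significant
terms.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import AnalysisConfig
from .datamodel import HABITAT_CATEGORIES, standardize_elevation
from .glmm import fit_glmm
from .modelfit import ModelFit

logger = logging.getLogger(__name__)

SURVIVAL_TERMS = ("time_elapsed", "log_size", "elevation_std", "habitat_altered", "habitat_pref")


def filter_resurvey(records: pd.DataFrame, config: AnalysisConfig | None = None) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Apply the three resurvey exclusion rules; return kept rows and a ledger.

    Rules (order-independent, evaluated on the raw table):

    * ``phenology`` — |doy_second - doy_initial| larger than the window;
    * ``rarity`` — species with fewer initial records than the minimum;
    * ``elapsed`` — revisits after fewer years than the minimum.
    """
    config = config or AnalysisConfig()
    df = records.reset_index(drop=True)
    phen = (df["doy_second"] - df["doy_initial"]).abs() > config.phenology_window_days
    initial_counts = df.groupby("species_id")["species_id"].transform("size")
    rare = initial_counts < config.min_initial_records_per_species
    elapsed = (df["year_second"] - df["year_initial"]) < config.min_years_between_surveys
    ledger = {
        "phenology": int(phen.sum()),
        "rarity": int(rare.sum()),
        "elapsed": int(elapsed.sum()),
    }
    kept = df[~(phen | rare | elapsed)].copy()
    return kept, ledger


def survival_design(records: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray, np.ndarray, List[str], Dict[str, List[int]]]:
    """Response, design matrix, species codes and term map for the survival model.

    Habitat preference enters as a fixed factor with ``forest`` as the
    (alphabetical) reference level; only categories present in the data
    get a column.
    """
    y = records["survived"].to_numpy(dtype=float)
    cols = [np.ones(len(records))]
    coef_names = ["intercept"]
    terms: Dict[str, List[int]] = {}

    def add(name: str, values: np.ndarray, term: str) -> None:
        terms.setdefault(term, []).append(len(cols))
        cols.append(values.astype(float))
        coef_names.append(name)

    add("time_elapsed", (records["year_second"] - records["year_initial"]).to_numpy(), "time_elapsed")
    add("log_size", np.log(records["size_initial"].to_numpy(dtype=float)), "log_size")
    add("elevation_std", records["elevation_std"].to_numpy(), "elevation_std")
    add("habitat_altered", (records["habitat_altered"] == "yes").to_numpy(), "habitat_altered")
    present = [c for c in HABITAT_CATEGORIES if c in set(records["habitat_pref"])]
    for cat in present[1:]:
        add(f"habitat_pref[{cat}]", (records["habitat_pref"] == cat).to_numpy(), "habitat_pref")
    X = np.column_stack(cols)
    species, _ = pd.factorize(records["species_id"])
    return y, X, species, coef_names, terms


def fit_survival_model(
    records: pd.DataFrame,
    config: AnalysisConfig | None = None,
    use_lrt: bool = False,
    terms_to_drop: Tuple[str, ...] = (),
) -> ModelFit:
    """Binomial GLMM: survival ~ time + log(size) + elevation + alteration
    + habitat preference, with species random intercept."""
    if records["species_id"].nunique() < 2:
        raise ValueError("survival model needs at least 2 species")
    if "elevation_std" not in records.columns or records["elevation_std"].isna().any():
        records = standardize_elevation(records).dropna(subset=["elevation_std"])
    y, X, species, coef_names, terms = survival_design(records)
    if terms_to_drop:
        keep = [0] + sorted(i for t, idx in terms.items() if t not in terms_to_drop for i in idx)
        name_map = {i: j for j, i in enumerate(keep)}
        X = X[:, keep]
        coef_names = [coef_names[i] for i in keep]
        terms = {t: [name_map[i] for i in idx] for t, idx in terms.items() if t not in terms_to_drop}
    return fit_glmm(y, X, species, family="binomial", coef_names=coef_names, terms=terms, use_lrt=use_lrt)


def vif(design: np.ndarray, coef_names: List[str], terms: Dict[str, List[int]] | None = None) -> pd.DataFrame:
    """(Generalized) variance inflation factors of a fixed-effect design.

    Numeric single-column terms get the classical VIF = 1/(1 - R_j^2);
    multi-column (categorical) terms get the generalized VIF
    ``det(R_11) det(R_22) / det(R)`` together with its 1/(2 df) power,
    which is comparable across terms of different dimension.  The
    intercept column (constant) is excluded.  Rank-deficient designs
    raise, naming the aliased columns.
    """
    X = np.asarray(design, dtype=float)
    keep = [j for j in range(X.shape[1]) if np.std(X[:, j]) > 0]
    names = [coef_names[j] for j in keep]
    Xc = X[:, keep]
    rank = np.linalg.matrix_rank(Xc)
    if rank < Xc.shape[1]:
        _, R = np.linalg.qr(Xc)
        aliased = [names[j] for j in np.flatnonzero(np.abs(np.diag(R)) < 1e-8 * np.abs(np.diag(R)).max())]
        raise ValueError(f"design is rank deficient; aliased column(s): {aliased}")
    Xs = (Xc - Xc.mean(axis=0)) / Xc.std(axis=0, ddof=1)
    R = np.corrcoef(Xs, rowvar=False)
    if terms is None:
        terms = {n: [j] for j, n in enumerate(coef_names) if j in keep}
    detR = np.linalg.det(R)
    rows = []
    for term, idx in terms.items():
        pos = [keep.index(j) for j in idx if j in keep]
        if not pos:
            continue
        other = [j for j in range(len(keep)) if j not in pos]
        d1 = np.linalg.det(R[np.ix_(pos, pos)])
        d2 = np.linalg.det(R[np.ix_(other, other)]) if other else 1.0
        gvif = d1 * d2 / detR
        df = len(pos)
        rows.append({"term": term, "df": df, "gvif": gvif, "gvif_scaled": gvif ** (1.0 / (2 * df))})
    return pd.DataFrame(rows)


def survival_vif(records: pd.DataFrame) -> pd.DataFrame:
    """VIFs of the survival model's fixed-effect design."""
    if "elevation_std" not in records.columns or records["elevation_std"].isna().any():
        records = standardize_elevation(records).dropna(subset=["elevation_std"])
    _, X, _, coef_names, terms = survival_design(records)
    return vif(X, coef_names, terms)


def fit_alteration_model(records: pd.DataFrame) -> ModelFit:
    """Plain binomial GLM: habitat alteration ~ raw elevation."""
    if len(records) < 10:
        raise ValueError("alteration model needs at least 10 records")
    y = (records["habitat_altered"] == "yes").to_numpy(dtype=float)
    flags: List[str] = []
    X = sm.add_constant(records["elevation_m"].to_numpy(dtype=float))
    if y.min() == y.max():
        flags.append("complete separation: all records in one alteration class")
        coefs = np.array([np.nan, np.nan])
        ses = np.array([np.nan, np.nan])
        ll = np.nan
        converged = False
        chisq, p = np.nan, np.nan
        cov = None
    else:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        coefs = np.asarray(res.params, float)
        ses = np.asarray(res.bse, float)
        ll = float(res.llf)
        converged = bool(res.converged)
        zval = coefs[1] / ses[1]
        chisq = float(zval**2)
        from scipy import stats as _st

        p = float(_st.chi2.sf(chisq, 1))
        cov = np.asarray(res.cov_params(), float)
    return ModelFit(
        terms=["elevation_m"],
        coef_names=["intercept", "elevation_m"],
        coefficients=coefs,
        standard_errors=ses,
        term_chisq={"elevation_m": chisq},
        term_df={"elevation_m": 1},
        term_p={"elevation_m": p},
        loglik=ll,
        converged=converged,
        n_obs=len(records),
        n_species=records["species_id"].nunique(),
        flags=flags,
        cov=cov,
    )


def backward_simplify(
    records: pd.DataFrame,
    config: AnalysisConfig | None = None,
    threshold_p: float = 0.10,
    use_lrt: bool = False,
) -> Tuple[ModelFit, ModelFit, List[Dict[str, float]]]:
    """Backward deletion of non-significant survival-model terms.

    Repeatedly drops the highest-p fixed term with p > ``threshold_p``
    (a main effect is protected while any interaction containing it is
    present) and refits, returning (full fit, reduced fit, removal
    trace).
    """
    full = fit_survival_model(records, config, use_lrt=use_lrt)
    dropped: List[str] = []
    trace: List[Dict[str, float]] = []
    current = full
    while True:
        protected = set()
        for t in current.terms:
            if "_x_" in t:
                protected.update(t.split("_x_"))
        # threshold >= 1 means "strip every unprotected term" (p never exceeds 1)
        candidates = {
            t: p
            for t, p in current.term_p.items()
            if (p > threshold_p or threshold_p >= 1.0) and t not in protected
        }
        if not candidates:
            break
        worst = max(candidates, key=candidates.get)
        dropped.append(worst)
        trace.append({"term": worst, "p_at_removal": current.term_p[worst]})
        current = fit_survival_model(records, config, use_lrt=use_lrt, terms_to_drop=tuple(dropped))
    return full, current, trace
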