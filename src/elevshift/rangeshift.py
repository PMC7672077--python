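"""Elevational range-shift estimation between two survey periods.

For every species with enough records in both periods the stage

1. estimates the elevational density distribution per period,
2. summarizes it as rear edge (5% quantile), optimum (highest density
   peak) and leading edge (95% quantile),
3. converts the between-period differences to annual shift rates,
4. compares the nine deciles of the two distributions with the
   Harrell–Davis estimator and a percentile bootstrap,
5. screens whole-distribution change with two-sample Kolmogorov–Smirnov
   tests corrected by Benjamini–Hochberg,
6. models shift rate against habitat-preference category (Gaussian
   linear model + Tukey HSD), and
7. classifies each rate against the regional climate-tracking band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .datamodel import CURRENT, HISTORICAL
from .density import DensityEstimate, estimate_density
from .modelfit import ModelFit
from .quantiles import empirical_quantile, harrell_davis_many, hd_weight_matrix

logger = logging.getLogger(__name__)

POSITIONS = ("rear", "optimum", "leading")
DECILES = np.round(np.arange(0.1, 0.95, 0.1), 1)


@dataclass(frozen=True)
class RangeSummary:
    """Rear edge, optimum and leading edge of one species in one period."""

    species_id: str
    period: str
    rear_m: float
    optimum_m: float
    leading_m: float
    n_records: int


@dataclass(frozen=True)
class ShiftEstimate:
    """Total and annual elevational shift at one range position (positive = upslope)."""

    species_id: str
    position: str
    total_shift_m: float
    rate_m_per_yr: float


@dataclass(frozen=True)
class DecileShift:
    """Harrell–Davis difference of one decile between periods, with bootstrap CI."""

    species_id: str
    q: float
    hd_hist_m: float
    hd_curr_m: float
    diff_m: float
    ci_low_m: float
    ci_high_m: float
    p_value: float
    significant: bool


def range_summary(
    density: DensityEstimate,
    elevations: np.ndarray,
    q_low: float = 0.05,
    q_high: float = 0.95,
) -> RangeSummary:
    """Summarize a per-period density as rear/optimum/leading elevations.

    Rear and leading edges are the ``q_low``/``q_high`` linear-interpolation
    quantiles of the raw elevation sample; the optimum is the grid
    elevation where the kernel density peaks, ties broken toward the
    lowest elevation.
    """
    x = np.asarray(elevations, dtype=float)
    rear, leading = empirical_quantile(x, [q_low, q_high])
    peaks = np.flatnonzero(density.density == density.density.max())
    if len(peaks) > 1:
        logger.info(
            "range_summary: %s/%s has %d equal-density maxima; tie broken to the lowest elevation",
            density.species_id, density.period, len(peaks),
        )
    optimum = float(density.grid[peaks[0]])
    return RangeSummary(
        species_id=density.species_id,
        period=density.period,
        rear_m=float(rear),
        optimum_m=optimum,
        leading_m=float(leading),
        n_records=density.n_records,
    )


def shift_rates(hist: RangeSummary, curr: RangeSummary, period_length_years: float) -> List[ShiftEstimate]:
    """Current-minus-historical shift and annual rate for the three positions."""
    if hist.species_id != curr.species_id:
        raise ValueError(f"species mismatch: {hist.species_id} vs {curr.species_id}")
    out = []
    for pos, h, c in (
        ("rear", hist.rear_m, curr.rear_m),
        ("optimum", hist.optimum_m, curr.optimum_m),
        ("leading", hist.leading_m, curr.leading_m),
    ):
        total = c - h
        out.append(
            ShiftEstimate(
                species_id=hist.species_id,
                position=pos,
                total_shift_m=total,
                rate_m_per_yr=total / period_length_years,
            )
        )
    return out


def decile_shift_test(
    hist: np.ndarray,
    curr: np.ndarray,
    species_id: str = "",
    B: int = 2000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
    qs: Sequence[float] = tuple(DECILES),
) -> List[DecileShift]:
    """Percentile-bootstrap comparison of decile positions between periods.

    For each probability q the point estimate is
    ``HD_q(current) - HD_q(historical)``.  Each period's sample is
    resampled with replacement B times independently; the CI is the
    (alpha/2, 1-alpha/2) percentile interval of the bootstrap
    differences and the p-value the usual two-sided bootstrap
    probability ``2 * min(p_hat, 1 - p_hat)`` with
    ``p_hat = (#{d* > 0} + 0.5 #{d* = 0}) / B``.  A decile is flagged
    significant when its CI excludes zero.
    """
    if B < 100:
        logger.warning("decile_shift_test: B=%d bootstrap replicates is very small", B)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hist = np.asarray(hist, dtype=float)
    curr = np.asarray(curr, dtype=float)
    qs = np.asarray(qs, dtype=float)

    hd_h = np.sort(hist) @ hd_weight_matrix(hist.size, qs).T
    hd_c = np.sort(curr) @ hd_weight_matrix(curr.size, qs).T
    diff = hd_c - hd_h

    boot_h = harrell_davis_many(rng.choice(hist, size=(B, hist.size), replace=True), qs)
    boot_c = harrell_davis_many(rng.choice(curr, size=(B, curr.size), replace=True), qs)
    boot_diff = boot_c - boot_h  # (B, len(qs))

    lo, hi = np.quantile(boot_diff, [alpha / 2, 1 - alpha / 2], axis=0)
    p_hat = (np.sum(boot_diff > 0, axis=0) + 0.5 * np.sum(boot_diff == 0, axis=0)) / B
    p = 2 * np.minimum(p_hat, 1 - p_hat)

    out = []
    for j, q in enumerate(qs):
        excludes_zero = lo[j] > 0 or hi[j] < 0
        out.append(
            DecileShift(
                species_id=species_id,
                q=float(q),
                hd_hist_m=float(hd_h[j]),
                hd_curr_m=float(hd_c[j]),
                diff_m=float(diff[j]),
                ci_low_m=float(lo[j]),
                ci_high_m=float(hi[j]),
                p_value=float(p[j]),
                significant=bool(excludes_zero),
            )
        )
    return out


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def ks_screen(pairs: Dict[str, Tuple[np.ndarray, np.ndarray]], alpha: float = 0.05) -> pd.DataFrame:
    """Two-sample K–S test per species with BH correction across species.

    ``pairs`` maps species id to (historical, current) elevation samples.
    Returns one row per species with the D statistic, raw and adjusted p
    and a significance flag at ``alpha``.
    """
    species = sorted(pairs)
    rows = []
    for sp in species:
        h, c = pairs[sp]
        res = stats.ks_2samp(np.asarray(h, float), np.asarray(c, float))
        rows.append({"species_id": sp, "ks_d": float(res.statistic), "p_raw": float(res.pvalue)})
    df = pd.DataFrame(rows)
    df["p_bh"] = bh_adjust(df["p_raw"].to_numpy())
    df["significant"] = df["p_bh"] <= alpha
    return df


def _compact_letter_display(categories: Sequence[str], not_different: set[tuple[str, str]]) -> Dict[str, str]:
    """Greedy insert-absorb compact letters from pairwise non-difference sets."""
    groups: List[set[str]] = []
    for cat in categories:
        placed = False
        for g in groups:
            if all((min(cat, o), max(cat, o)) in not_different for o in g):
                g.add(cat)
                placed = True
        if not placed:
            groups.append({cat})
    # drop groups fully contained in another
    groups = [g for i, g in enumerate(groups) if not any(i != j and g < h for j, h in enumerate(groups))]
    letters = {c: "" for c in categories}
    for g, letter in zip(groups, "abcdefghijklmnopqrstuvwxyz"):
        for c in sorted(g):
            letters[c] += letter
    return letters


def shift_by_habitat(rates: pd.DataFrame, position: str, alpha: float = 0.05) -> Tuple[ModelFit, pd.DataFrame, Dict[str, str]]:
    """Gaussian linear model of shift rate on habitat category, plus Tukey HSD.

    ``rates`` needs columns species_id, position, rate_m_per_yr,
    habitat_pref.  Returns the overall fit (with the habitat term's
    F-based chi-square and p), the Tukey pairwise table and a compact
    letter display.  Categories represented by a single species are kept
    in the fit but flagged as unstable for the letters.
    """
    sub = rates[rates["position"] == position]
    if sub.empty:
        raise ValueError(f"no rates for position {position!r}")
    counts = sub.groupby("habitat_pref").size()
    if (counts >= 2).sum() < 2:
        raise ValueError("need at least 2 categories with at least 2 species each")
    y = sub["rate_m_per_yr"].to_numpy(dtype=float)
    cats = sorted(sub["habitat_pref"].unique())
    X = np.column_stack([np.ones(len(sub))] + [(sub["habitat_pref"] == c).to_numpy(float) for c in cats[1:]])
    ols = sm.OLS(y, X).fit()
    k = len(cats) - 1
    group_means = sub.groupby("habitat_pref")["rate_m_per_yr"].mean()
    if np.ptp(group_means.to_numpy()) < 1e-12:
        # no between-group variation at all: nothing to explain
        fstat, p_overall, chisq = 0.0, 1.0, 0.0
    elif k > 0 and ols.df_resid > 0:
        contrast = np.zeros((k, X.shape[1]))
        contrast[:, 1:] = np.eye(k)
        ftest = ols.f_test(contrast)
        fstat, p_overall = float(ftest.fvalue), float(ftest.pvalue)
        chisq = fstat * k
    else:  # pragma: no cover - guarded by the precondition above
        fstat, p_overall, chisq = np.nan, 1.0, 0.0
    coef_names = ["intercept"] + [f"habitat[{c}]" for c in cats[1:]]
    fit = ModelFit(
        terms=["habitat_pref"],
        coef_names=coef_names,
        coefficients=np.asarray(ols.params, float),
        standard_errors=np.asarray(ols.bse, float),
        term_chisq={"habitat_pref": chisq},
        term_df={"habitat_pref": k},
        term_p={"habitat_pref": p_overall},
        loglik=float(ols.llf),
        converged=True,
        n_obs=len(sub),
        n_species=sub["species_id"].nunique(),
        cov=np.asarray(ols.cov_params(), float),
    )
    singletons = set(counts.index[counts < 2])
    if singletons:
        fit.flags.append(f"single-species categories (letters unstable): {sorted(singletons)}")

    tukey = pairwise_tukeyhsd(y, sub["habitat_pref"].to_numpy(), alpha=alpha)
    pair_df = pd.DataFrame(tukey.summary().data[1:], columns=[str(c) for c in tukey.summary().data[0]])
    pair_df = pair_df.rename(columns={"p-adj": "p_adj", "meandiff": "mean_diff"})
    not_diff = {
        (min(r["group1"], r["group2"]), max(r["group1"], r["group2"]))
        for _, r in pair_df.iterrows()
        if float(r["p_adj"]) > alpha
    }
    letters = _compact_letter_display(cats, not_diff)
    return fit, pair_df, letters


def classify_tracking(
    rate_m_per_yr: float,
    band: Tuple[float, float] = (3.8, 5.5),
    ci: Tuple[float, float] | None = None,
) -> str:
    """Classify an annual shift rate against the climate-tracking band.

    Below the band is ``lagging``, inside ``tracking``, above
    ``exceeding``.  When a CI is supplied, lagging/exceeding are only
    reported if the whole interval lies outside the band (suffix
    ``_significant``), otherwise the point classification is returned
    unadorned.
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError("band lower bound must be below upper bound")
    if rate_m_per_yr < lo:
        label = "lagging"
    elif rate_m_per_yr > hi:
        label = "exceeding"
    else:
        label = "tracking"
    if ci is not None and label in ("lagging", "exceeding"):
        ci_lo, ci_hi = ci
        if (label == "lagging" and ci_hi < lo) or (label == "exceeding" and ci_lo > hi):
            return label + "_significant"
    return label


def species_period_samples(occurrences: pd.DataFrame, config: AnalysisConfig) -> Tuple[Dict[str, Tuple[np.ndarray, np.ndarray]], pd.DataFrame]:
    """Split occurrences into per-species (historical, current) elevation samples.

    Species with fewer than ``min_records_per_period`` records in either
    period are excluded and listed in the returned exclusions table.
    """
    pairs: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    excl = []
    for sp, grp in occurrences.groupby("species_id", sort=True):
        h = grp.loc[grp["period"] == HISTORICAL, "elevation_m"].to_numpy(dtype=float)
        c = grp.loc[grp["period"] == CURRENT, "elevation_m"].to_numpy(dtype=float)
        if min(h.size, c.size) < config.min_records_per_period:
            excl.append(
                {
                    "species_id": sp,
                    "n_historical": h.size,
                    "n_current": c.size,
                    "reason": f"fewer than {config.min_records_per_period} records in one period",
                }
            )
            logger.info("range shift: excluding %s (n_hist=%d, n_curr=%d)", sp, h.size, c.size)
            continue
        pairs[sp] = (h, c)
    return pairs, pd.DataFrame(excl, columns=["species_id", "n_historical", "n_current", "reason"])


def analyze_range_shifts(
    occurrences: pd.DataFrame,
    config: AnalysisConfig,
    seed: int | np.random.Generator = 0,
) -> Dict[str, pd.DataFrame]:
    """Run the full range-shift stage on an occurrence table.

    Returns a dict of tables: ``summaries`` (per species × period),
    ``rates`` (per species × position, with tracking class),
    ``deciles``, ``ks``, ``habitat_models``, ``habitat_pairwise``,
    ``exclusions``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pairs, exclusions = species_period_samples(occurrences, config)
    habitat_of = occurrences.drop_duplicates("species_id").set_index("species_id")["habitat_pref"]
    q_low, q_high = config.edge_quantiles

    summaries_rows, rate_rows, decile_rows = [], [], []
    for sp, (h, c) in pairs.items():
        dens_h = estimate_density(h, species_id=sp, period=HISTORICAL)
        dens_c = estimate_density(c, species_id=sp, period=CURRENT)
        sum_h = range_summary(dens_h, h, q_low, q_high)
        sum_c = range_summary(dens_c, c, q_low, q_high)
        for s in (sum_h, sum_c):
            summaries_rows.append(s.__dict__)
        for est in shift_rates(sum_h, sum_c, config.period_length_years):
            rate_rows.append(
                {
                    **est.__dict__,
                    "habitat_pref": habitat_of[sp],
                    "tracking": classify_tracking(est.rate_m_per_yr, config.tracking_band_m_per_yr),
                }
            )
        for d in decile_shift_test(
            h, c, species_id=sp, B=config.bootstrap_replicates, alpha=config.alpha, seed=rng
        ):
            decile_rows.append(d.__dict__)

    summaries = pd.DataFrame(summaries_rows)
    rates = pd.DataFrame(rate_rows)
    deciles = pd.DataFrame(decile_rows)
    ks = ks_screen(pairs, alpha=config.alpha) if len(pairs) >= 2 else pd.DataFrame()

    habitat_rows, pairwise_rows = [], []
    for pos in POSITIONS:
        if rates.empty:
            break
        try:
            fit, pair_df, letters = shift_by_habitat(rates, pos, alpha=config.alpha)
        except ValueError as err:
            logger.info("habitat model skipped for %s: %s", pos, err)
            continue
        habitat_rows.append(
            {
                "position": pos,
                "chisq": fit.term_chisq["habitat_pref"],
                "df": fit.term_df["habitat_pref"],
                "p": fit.term_p["habitat_pref"],
                "letters": ";".join(f"{k}={v}" for k, v in letters.items()),
            }
        )
        pair_df = pair_df.assign(position=pos)
        pairwise_rows.append(pair_df)

    return {
        "summaries": summaries,
        "rates": rates,
        "deciles": deciles,
        "ks": ks,
        "habitat_models": pd.DataFrame(habitat_rows),
        "habitat_pairwise": pd.concat(pairwise_rows, ignore_index=True) if pairwise_rows else pd.DataFrame(),
        "exclusions": exclusions,
    }


def resurvey_shift_crosscheck(
    resurvey: pd.DataFrame,
    full_rates: pd.DataFrame,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Correlate resurvey-based shift rates with full-data-set rates.

    For each species with at least ``min_resurvey_records_per_survey``
    records in the initial survey and among the surviving populations of
    the second survey, rear/optimum/leading positions are estimated from
    the two resurvey snapshots and converted to annual rates using the
    species' mean elapsed years.  Pearson correlations against the
    full-data-set rates are returned per position; with fewer than three
    qualifying species the correlation is reported as undefined (NaN).
    """
    q_low, q_high = config.edge_quantiles
    rows = []
    for sp, grp in resurvey.groupby("species_id", sort=True):
        initial = grp["elevation_m"].to_numpy(dtype=float)
        second = grp.loc[grp["survived"] == 1, "elevation_m"].to_numpy(dtype=float)
        if initial.size < config.min_resurvey_records_per_survey or second.size < config.min_resurvey_records_per_survey:
            continue
        elapsed = float((grp["year_second"] - grp["year_initial"]).mean())
        try:
            d_i = estimate_density(initial, species_id=sp, period="initial")
            d_s = estimate_density(second, species_id=sp, period="second")
        except ValueError:
            continue
        s_i = range_summary(d_i, initial, q_low, q_high)
        s_s = range_summary(d_s, second, q_low, q_high)
        rows.append(
            {
                "species_id": sp,
                "rear": (s_s.rear_m - s_i.rear_m) / elapsed,
                "optimum": (s_s.optimum_m - s_i.optimum_m) / elapsed,
                "leading": (s_s.leading_m - s_i.leading_m) / elapsed,
            }
        )
    res_rates = pd.DataFrame(rows)
    out = []
    for pos in POSITIONS:
        if len(res_rates) < 3:
            out.append({"position": pos, "n_species": len(res_rates), "r": np.nan, "p": np.nan})
            continue
        full_pos = full_rates[full_rates["position"] == pos].set_index("species_id")["rate_m_per_yr"]
        merged = res_rates.set_index("species_id")[pos].to_frame("resurvey_rate").join(full_pos, how="inner").dropna()
        if len(merged) < 3:
            out.append({"position": pos, "n_species": len(merged), "r": np.nan, "p": np.nan})
            continue
        r, p = stats.pearsonr(merged["resurvey_rate"], merged["rate_m_per_yr"])
        out.append({"position": pos, "n_species": len(merged), "r": float(r), "p": float(p)})
    return pd.DataFrame(out)
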