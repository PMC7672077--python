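"""Resurvey filtering, survival GLMM, VIFs, alteration model, backward deletion."""

import itertools

import numpy as np
import pandas as pd
import pytest

from elevshift.config import AnalysisConfig
from elevshift.datamodel import standardize_elevation
from elevshift.survival import (
    backward_simplify,
    filter_resurvey,
    fit_alteration_model,
    fit_survival_model,
    survival_vif,
    vif,
)
from elevshift.synth import (
    AbundanceCoefficients,
    SpeciesScenario,
    SurvivalCoefficients,
    simulate_occurrences,
    simulate_resurvey,
)

from conftest import make_resurvey_frame


class TestFilterResurvey:
    def test_ledger_counts_one_per_rule(self, cfg, resurvey_fixture_10):
        kept, ledger = filter_resurvey(resurvey_fixture_10, cfg)
        assert len(kept) == 7
        assert ledger == {"phenology": 1, "rarity": 1, "elapsed": 1}

    def test_doy_difference_exactly_30_kept(self, cfg):
        df = make_resurvey_frame([{"doy_initial": 150, "doy_second": 180}, {}, {}, {}, {}])
        kept, ledger = filter_resurvey(df, cfg)
        assert len(kept) == 5 and ledger["phenology"] == 0

    def test_elapsed_exactly_5_kept_4_dropped(self, cfg):
        df = make_resurvey_frame(
            [{"year_initial": 2013, "year_second": 2018}, {"year_initial": 2014, "year_second": 2018}]
            + [{} for _ in range(4)]
        )
        kept, ledger = filter_resurvey(df, cfg)
        assert ledger["elapsed"] == 1
        assert "S1" not in set(kept["site_id"])

    def test_rule_order_independence(self, cfg, resurvey_fixture_10):
        """Applying the three rules in any order keeps the same record set."""
        df = resurvey_fixture_10

        def phen(d):
            return d[(d["doy_second"] - d["doy_initial"]).abs() <= cfg.phenology_window_days]

        def rare(d):
            counts = df.groupby("species_id")["species_id"].transform("size")
            ok = set(df.loc[counts >= cfg.min_initial_records_per_species, "site_id"])
            return d[d["site_id"].isin(ok)]

        def elap(d):
            return d[(d["year_second"] - d["year_initial"]) >= cfg.min_years_between_surveys]

        kept, _ = filter_resurvey(df, cfg)
        for order in itertools.permutations([phen, rare, elap]):
            cur = df
            for f in order:
                cur = f(cur)
            assert set(cur["site_id"]) == set(kept["site_id"])


def _synthetic_resurvey(cfg, seed, gam=None, n_species=20, per_species=75, p_alteration=0.37):
    cats = ["forest", "generalist", "grassland", "subalpine"]
    scs = [
        SpeciesScenario(species_id=f"sp{i:02d}", habitat_pref=cats[i % 4], mu_elev_m=1200.0,
                        sigma_elev_m=300.0, n_hist=per_species, n_curr=1)
        for i in range(n_species)
    ]
    occ = simulate_occurrences(scs, AbundanceCoefficients(), cfg, seed=seed)
    pops = occ[occ["period"] == "historical"]
    res = simulate_resurvey(pops, gam or SurvivalCoefficients(), p_alteration=p_alteration, seed=seed + 1)
    return standardize_elevation(res).dropna(subset=["elevation_std"])


class TestSurvivalModel:
    def test_recovers_generating_coefficients(self, cfg):
        gam = SurvivalCoefficients(gamma0=0.3, gamma_logsize=0.8, gamma_elev=0.5, gamma_alt=-0.9,
                                   gamma_time=-0.01, sigma_species=0.4)
        res = _synthetic_resurvey(cfg, seed=100, gam=gam)
        fit = fit_survival_model(res, cfg)
        assert fit.converged
        for name, truth in [("log_size", 0.8), ("elevation_std", 0.5), ("habitat_altered", -0.9)]:
            assert abs(fit.coef(name) - truth) < 3 * fit.se(name), name

    def test_zero_variance_limit_equals_logistic_regression(self, cfg):
        """At species variance 0 the GLMM reproduces the plain logistic GLM."""
        import statsmodels.api as sm

        from elevshift.glmm import fit_glmm
        from elevshift.survival import survival_design

        gam = SurvivalCoefficients(sigma_species=0.0)
        res = _synthetic_resurvey(cfg, seed=200, gam=gam)
        y, X, sp, names, terms = survival_design(res)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        lim = fit_glmm(y, X, sp, "binomial", names, terms, fixed_variances={"species": 0.0})
        assert np.max(np.abs(lim.coefficients - ref.params) / np.maximum(np.abs(ref.params), 1e-3)) < 1e-4

    def test_all_survived_raises_separation_flag(self, cfg):
        res = _synthetic_resurvey(cfg, seed=300)
        res["survived"] = 1
        fit = fit_survival_model(res, cfg)
        assert any("separation" in f for f in fit.flags)

    def test_needs_two_species(self, cfg):
        res = _synthetic_resurvey(cfg, seed=301)
        one = res[res["species_id"] == res["species_id"].iloc[0]]
        with pytest.raises(ValueError, match="2 species"):
            fit_survival_model(one, cfg)


class TestVif:
    def test_orthogonal_predictors_vif_one(self):
        rng = np.random.default_rng(0)
        n = 4000
        X = np.column_stack([np.ones(n), rng.normal(0, 1, n), rng.normal(0, 1, n)])
        out = vif(X, ["const", "a", "b"]).set_index("term")
        assert out.loc["a", "gvif"] == pytest.approx(1.0, abs=0.01)
        assert out.loc["b", "gvif"] == pytest.approx(1.0, abs=0.01)

    def test_correlated_pair_closed_form(self):
        """Correlation 0.9 between two predictors gives VIF = 1/(1-0.81)."""
        rng = np.random.default_rng(1)
        n = 200_000
        a = rng.normal(0, 1, n)
        b = 0.9 * a + np.sqrt(1 - 0.81) * rng.normal(0, 1, n)
        X = np.column_stack([np.ones(n), a, b])
        out = vif(X, ["const", "a", "b"]).set_index("term")
        assert out.loc["a", "gvif"] == pytest.approx(1 / (1 - 0.81), rel=0.02)

    def test_duplicated_predictor_raises(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 100)
        X = np.column_stack([np.ones(100), x, x])
        with pytest.raises(ValueError, match="rank deficient"):
            vif(X, ["const", "x", "x_copy"])

    def test_survival_design_vifs_near_one(self, cfg):
        res = _synthetic_resurvey(cfg, seed=400)
        out = survival_vif(res)
        assert (out["gvif_scaled"] < 2.0).all()


class TestAlterationModel:
    def test_independent_alteration_slope_near_zero(self, cfg):
        res = _synthetic_resurvey(cfg, seed=500)
        fit = fit_alteration_model(res)
        assert fit.converged
        assert abs(fit.coef("elevation_m")) < 3 * fit.se("elevation_m")

    def test_low_elevation_alteration_strongly_negative(self, cfg):
        """Alteration concentrated below the median elevation gives a clear negative slope."""
        res = _synthetic_resurvey(cfg, seed=600, n_species=20, per_species=20)
        med = res["elevation_m"].median()
        rng = np.random.default_rng(601)
        p = np.where(res["elevation_m"] < med, 0.85, 0.15)
        res["habitat_altered"] = np.where(rng.random(len(res)) < p, "yes", "no")
        fit = fit_alteration_model(res)
        assert fit.coef("elevation_m") < 0
        assert fit.term_p["elevation_m"] < 0.001

    def test_degenerate_class_flagged(self, cfg):
        res = _synthetic_resurvey(cfg, seed=700).head(50).copy()
        res["habitat_altered"] = "no"
        fit = fit_alteration_model(res)
        assert not fit.converged
        assert any("separation" in f for f in fit.flags)

    def test_minimum_records(self, cfg):
        res = _synthetic_resurvey(cfg, seed=800).head(5)
        with pytest.raises(ValueError, match="10 records"):
            fit_alteration_model(res)


class TestBackwardSimplify:
    def test_all_significant_keeps_full_model(self, cfg):
        gam = SurvivalCoefficients(gamma0=0.2, gamma_logsize=1.2, gamma_elev=0.9, gamma_alt=-1.5,
                                   gamma_time=-0.08, sigma_species=0.3)
        res = _synthetic_resurvey(cfg, seed=900, gam=gam, n_species=20, per_species=100)
        full, reduced, trace = backward_simplify(res, cfg, threshold_p=0.10)
        # strong effects survive; anything removed must have had p > 0.10
        assert all(t["p_at_removal"] > 0.10 for t in trace)
        for term in ("log_size", "habitat_altered", "elevation_std"):
            assert term in reduced.terms

    def test_pure_noise_term_removed(self, cfg):
        """time_elapsed has essentially no effect and should be deleted."""
        gam = SurvivalCoefficients(gamma0=0.2, gamma_logsize=1.0, gamma_elev=0.7, gamma_alt=-1.2,
                                   gamma_time=0.0, sigma_species=0.3)
        removed = 0
        for s in range(10):
            res = _synthetic_resurvey(cfg, seed=1000 + 10 * s, gam=gam)
            _, reduced, trace = backward_simplify(res, cfg, threshold_p=0.10)
            removed += "time_elapsed" not in reduced.terms
        assert removed >= 7

    def test_threshold_one_strips_everything(self, cfg):
        res = _synthetic_resurvey(cfg, seed=1100)
        _, reduced, _ = backward_simplify(res, cfg, threshold_p=1.0)
        assert reduced.terms == []
        assert reduced.coef_names == ["intercept"]

    def test_full_and_reduced_estimates_stable(self, cfg):
        gam = SurvivalCoefficients()
        res = _synthetic_resurvey(cfg, seed=1200, gam=gam, n_species=20, per_species=100)
        full, reduced, _ = backward_simplify(res, cfg, threshold_p=0.10)
        for term in reduced.terms:
            if term in full.coef_names and term in reduced.coef_names:
                assert abs(full.coef(term) - reduced.coef(term)) < 0.5 * max(full.se(term), 0.05)
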