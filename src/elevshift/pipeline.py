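"""End-to-end orchestration: staged pipeline runs and the run manifest.

All randomness flows from one root seed: each stage draws from a named
substream (``SeedSequence(root, spawn_key=(stage,))``) so stages can be
re-run independently yet reproducibly.  The manifest records the config
hash, seed, library versions and per-stage row counts; it contains no
timestamps, so identical runs produce byte-identical manifests.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .datamodel import (
    read_landolt,
    read_occurrences,
    read_resurvey,
    read_temperatures,
    standardize_elevation,
    write_table,
)
from .rangeshift import analyze_range_shifts, resurvey_shift_crosscheck
from .survival import backward_simplify, filter_resurvey, fit_alteration_model, survival_vif
from .synth import (
    default_scenarios,
    sample_resurvey_populations,
    scenario_echo,
    simulate_resurvey,
    simulate_study_occurrences,
    simulate_temperatures,
    synthetic_landolt_table,
)
from .thermal import category_summaries, niche_breadth_table
from .trends import fit_abundance_by_category, predict_surface

logger = logging.getLogger(__name__)

STAGE_KEYS = {"simulate": 0, "range_shift": 1, "trends": 2, "survival": 3, "niche": 4}


def stage_rng(root_seed: int, stage: str) -> np.random.Generator:
    """Named, independent random substream for one pipeline stage."""
    return np.random.default_rng(np.random.SeedSequence(root_seed, spawn_key=(STAGE_KEYS[stage],)))


def run_simulate(out_dir: Path, config: AnalysisConfig, seed: int) -> Dict[str, int]:
    """Generate the packaged synthetic scenario into occurrence/resurvey/temperature CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = stage_rng(seed, "simulate")
    scenarios = default_scenarios()
    occ = simulate_study_occurrences(scenarios, config=config, seed=rng)
    pops = sample_resurvey_populations(occ, seed=rng)
    res = simulate_resurvey(pops, seed=rng)
    temps = simulate_temperatures(occ, seed=rng)
    landolt = synthetic_landolt_table(scenarios)
    write_table(occ.drop(columns=["period"]), out_dir / "occurrences.csv")
    write_table(res, out_dir / "resurvey.csv")
    write_table(temps, out_dir / "temperatures.csv")
    write_table(landolt, out_dir / "landolt.csv")
    (out_dir / "scenarios.json").write_text(json.dumps(scenario_echo(scenarios), indent=1))
    return {"occurrences": len(occ), "resurvey": len(res), "temperatures": len(temps)}


def run_range_shift(input_dir: Path, out_dir: Path, config: AnalysisConfig, seed: int) -> Dict[str, int]:
    """Range-shift stage: summaries, rates, deciles, K–S screen, habitat models."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    occ = read_occurrences(Path(input_dir) / "occurrences.csv", config)
    tables = analyze_range_shifts(occ, config, seed=stage_rng(seed, "range_shift"))
    write_table(tables["summaries"], out_dir / "range_summaries.csv")
    write_table(tables["rates"], out_dir / "shift_rates.csv")
    write_table(tables["deciles"], out_dir / "decile_shifts.csv")
    write_table(tables["ks"], out_dir / "ks_screen.csv")
    write_table(tables["habitat_models"], out_dir / "habitat_models.csv")
    write_table(tables["habitat_pairwise"], out_dir / "habitat_pairwise.csv")
    write_table(tables["exclusions"], out_dir / "range_exclusions.csv")

    resurvey_path = Path(input_dir) / "resurvey.csv"
    if resurvey_path.exists() and not tables["rates"].empty:
        res = read_resurvey(resurvey_path, config)
        cross = resurvey_shift_crosscheck(res, tables["rates"], config)
        write_table(cross, out_dir / "resurvey_crosscheck.csv")
    return {
        "species_analyzed": int(tables["summaries"]["species_id"].nunique()) if len(tables["summaries"]) else 0,
        "species_excluded": len(tables["exclusions"]),
    }


def run_trends(input_dir: Path, out_dir: Path, config: AnalysisConfig, seed: int, category: str = "all") -> Dict[str, int]:
    """Population-trend stage: per-category Poisson-OLRE GLMM fits and surfaces."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    occ = read_occurrences(Path(input_dir) / "occurrences.csv", config)
    if category != "all":
        occ = occ[occ["habitat_pref"] == category]
    fits = fit_abundance_by_category(occ, config)
    fit_rows: List[dict] = []
    pred_frames: List[pd.DataFrame] = []
    for cat, fit in fits.items():
        for term in fit.term_chisq:
            fit_rows.append(
                {
                    "habitat_pref": cat,
                    "term": term,
                    "estimate": fit.coef(term) if term in fit.coef_names else np.nan,
                    "se": fit.se(term) if term in fit.coef_names else np.nan,
                    "chisq": fit.term_chisq[term],
                    "df": fit.term_df[term],
                    "p": fit.term_p[term],
                    "var_species": fit.random_effect_variances.get("species", np.nan),
                    "var_olre": fit.random_effect_variances.get("olre", np.nan),
                    "converged": fit.converged,
                    "n_obs": fit.n_obs,
                    "n_species": fit.n_species,
                }
            )
        if fit.converged:
            t_grid = np.linspace(-config.period_length_years, config.period_length_years, 5)
            z_grid = np.linspace(-2.0, 2.0, 41)
            pred = predict_surface(fit, t_grid, z_grid, z_observed_range=(-2.0, 2.0))
            pred.insert(0, "habitat_pref", cat)
            pred_frames.append(pred)
    write_table(pd.DataFrame(fit_rows), out_dir / "abundance_fits.csv")
    if pred_frames:
        write_table(pd.concat(pred_frames, ignore_index=True), out_dir / "predictions.csv")
    return {"categories_fit": len(fits)}


def run_survival(input_dir: Path, out_dir: Path, config: AnalysisConfig, seed: int) -> Dict[str, int]:
    """Survival stage: filtering ledger, binomial GLMM (full + reduced), VIF, alteration GLM."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res = read_resurvey(Path(input_dir) / "resurvey.csv", config)
    kept, ledger = filter_resurvey(res, config)
    kept = standardize_elevation(kept).dropna(subset=["elevation_std"])
    full, reduced, trace = backward_simplify(kept, config)
    rows = []
    for label, fit in (("full", full), ("reduced", reduced)):
        for term in fit.term_chisq:
            rows.append(
                {
                    "model": label,
                    "term": term,
                    "chisq": fit.term_chisq[term],
                    "df": fit.term_df[term],
                    "p": fit.term_p[term],
                    "var_species": fit.random_effect_variances.get("species", np.nan),
                    "converged": fit.converged,
                    "n_obs": fit.n_obs,
                    "n_species": fit.n_species,
                }
            )
    write_table(pd.DataFrame(rows), out_dir / "survival_fit.csv")
    write_table(survival_vif(kept), out_dir / "vif.csv")
    alt = fit_alteration_model(res)
    write_table(alt.term_table().assign(slope=alt.coefficients[1] if alt.converged else np.nan), out_dir / "alteration_fit.csv")
    write_table(
        pd.DataFrame([{"rule": k, "n_excluded": v} for k, v in ledger.items()]),
        out_dir / "survival_exclusions.csv",
    )
    return {"records_kept": len(kept), **{f"excluded_{k}": v for k, v in ledger.items()}}


def run_niche(input_dir: Path, out_dir: Path, config: AnalysisConfig, seed: int) -> Dict[str, int]:
    """Thermal-niche stage: per-species breadths and per-category summaries."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    input_dir = Path(input_dir)
    temps = read_temperatures(input_dir / "temperatures.csv")
    occ = read_occurrences(input_dir / "occurrences.csv", config)
    breadths, insufficient = niche_breadth_table(temps)
    species = occ.drop_duplicates("species_id")[["species_id", "habitat_pref"]]
    table = species.merge(breadths, on="species_id", how="left")
    landolt_path = input_dir / "landolt.csv"
    if landolt_path.exists():
        table = table.merge(read_landolt(landolt_path), on="species_id", how="left")
    summaries, missing = category_summaries(table)
    write_table(breadths, out_dir / "niche_breadth.csv")
    write_table(summaries, out_dir / "category_summaries.csv")
    if len(insufficient):
        write_table(insufficient, out_dir / "niche_insufficient.csv")
    return {"species_with_breadth": len(breadths), "species_insufficient": len(insufficient)}


def run_all(
    input_dir: str | Path | None,
    out_dir: str | Path,
    config: AnalysisConfig | None = None,
    seed: int = 0,
    simulate: bool = False,
) -> dict:
    """Execute simulate (optional) → range-shift → trends → survival → niche.

    Returns the manifest dict (also written to ``out_dir/manifest.json``).
    Any stage failure is recorded in the manifest and re-raised after
    partial outputs are retained.
    """
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if simulate:
        input_dir = out_dir / "inputs"
    if input_dir is None:
        raise ValueError("input_dir is required unless simulate=True")
    input_dir = Path(input_dir)

    manifest: dict = {
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": seed,
        "config": config.model_dump(mode="json"),
        "config_hash": config.config_hash(),
        "stages": {},
        "failed_stage": None,
    }

    stages = []
    if simulate:
        stages.append(("simulate", lambda: run_simulate(input_dir, config, seed)))
    stages += [
        ("range_shift", lambda: run_range_shift(input_dir, out_dir, config, seed)),
        ("trends", lambda: run_trends(input_dir, out_dir, config, seed)),
        ("survival", lambda: run_survival(input_dir, out_dir, config, seed)),
        ("niche", lambda: run_niche(input_dir, out_dir, config, seed)),
    ]
    for name, fn in stages:
        required = _required_inputs(name, input_dir)
        missing = [str(p) for p in required if not p.exists()]
        if missing:
            manifest["failed_stage"] = name
            manifest["stages"][name] = {"error": f"missing input file(s): {missing}"}
            _write_manifest(manifest, out_dir)
            raise FileNotFoundError(f"stage {name}: missing input file(s): {missing}")
        try:
            manifest["stages"][name] = fn()
        except Exception as err:  # record failure point, keep partial outputs
            manifest["failed_stage"] = name
            manifest["stages"][name] = {"error": str(err)}
            _write_manifest(manifest, out_dir)
            raise
    _write_manifest(manifest, out_dir)
    return manifest


def _required_inputs(stage: str, input_dir: Path) -> List[Path]:
    if stage == "simulate":
        return []
    needs = {
        "range_shift": ["occurrences.csv"],
        "trends": ["occurrences.csv"],
        "survival": ["resurvey.csv"],
        "niche": ["occurrences.csv", "temperatures.csv"],
    }
    return [input_dir / f for f in needs[stage]]


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    (Path(out_dir) / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
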