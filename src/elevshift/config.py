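"""Analysis configuration shared by every pipeline stage.

The defaults encode the study design: two 14-year survey periods
(1990–2003 vs 2004–2017), a minimum of 30 records per species and period
for range-shift estimation, the resurvey filtering rules (30-day phenology
window, at least 5 initial records per species, at least 5 years between
surveys) and the regional climate-tracking band of 3.8–5.5 m upslope per
year.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Tuple

import yaml
from pydantic import BaseModel, model_validator


class AnalysisConfig(BaseModel):
    """Tunable parameters of the full pipeline.

    Records with ``year <= period_boundary_year`` are labelled
    ``historical``, later ones ``current``.  ``edge_quantiles`` are the
    probabilities defining the rear (low-elevation) and leading
    (high-elevation) edge of a species' elevational distribution.
    ``tracking_band_m_per_yr`` is the range of upslope shift rates needed
    to keep pace with regional warming.
    """

    study_window: Tuple[int, int] = (1990, 2017)
    period_boundary_year: int = 2003
    period_length_years: float = 14.0
    min_records_per_period: int = 30
    min_resurvey_records_per_survey: int = 10
    min_initial_records_per_species: int = 5
    min_years_between_surveys: int = 5
    phenology_window_days: int = 30
    edge_quantiles: Tuple[float, float] = (0.05, 0.95)
    tracking_band_m_per_yr: Tuple[float, float] = (3.8, 5.5)
    bootstrap_replicates: int = 2000
    alpha: float = 0.05
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "AnalysisConfig":
        lo, hi = self.edge_quantiles
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"edge_quantiles must satisfy 0 < low < high < 1, got {self.edge_quantiles}")
        blo, bhi = self.tracking_band_m_per_yr
        if not blo < bhi:
            raise ValueError(f"tracking band lower bound must be below upper, got {self.tracking_band_m_per_yr}")
        if self.period_length_years <= 0:
            raise ValueError("period_length_years must be positive")
        y0, y1 = self.study_window
        if y0 > y1:
            raise ValueError("study_window start must not exceed end")
        return self

    @property
    def midpoint_year(self) -> float:
        """Centre of the study window, used to centre the time covariate."""
        return 0.5 * (self.study_window[0] + self.study_window[1])

    def config_hash(self) -> str:
        """Stable SHA-256 of the canonical JSON representation."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a JSON or YAML file.

    Field names mirror the class attributes exactly; unknown keys raise.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    unknown = set(data) - set(AnalysisConfig.model_fields)
    if unknown:
        raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
    return AnalysisConfig(**data)
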