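"""Generic fitted-model container shared by all statistical stages."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd


@dataclass
class ModelFit:
    """Coefficients, per-term tests and random-effect variances of one fit.

    ``terms`` are model terms (a categorical term owns several
    coefficients); ``coef_names`` label the individual coefficients.
    ``term_chisq``/``term_p`` hold the per-term Wald chi-square tests.
    When ``converged`` is False all inferential fields are unreliable and
    ``flags`` explains why.
    """

    terms: List[str]
    coef_names: List[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    term_chisq: Dict[str, float]
    term_df: Dict[str, int]
    term_p: Dict[str, float]
    random_effect_variances: Dict[str, float] = field(default_factory=dict)
    loglik: float = float("nan")
    converged: bool = True
    n_obs: int = 0
    n_species: int = 0
    flags: List[str] = field(default_factory=list)
    cov: np.ndarray | None = None

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.coef_names.index(name)])

    def se(self, name: str) -> float:
        return float(self.standard_errors[self.coef_names.index(name)])

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef_name": self.coef_names,
                "estimate": self.coefficients,
                "se": self.standard_errors,
            }
        )

    def term_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": list(self.term_chisq),
                "chisq": [self.term_chisq[t] for t in self.term_chisq],
                "df": [self.term_df[t] for t in self.term_chisq],
                "p": [self.term_p[t] for t in self.term_chisq],
            }
        )
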