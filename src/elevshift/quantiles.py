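"""Quantile estimators shared across the range-shift and thermal-niche stages.

Two conventions live here and nowhere else:

* ``empirical_quantile`` — the linear-interpolation sample quantile used
  for range edges (5/95%) and thermal-niche breadth.
* ``harrell_davis`` — the Harrell–Davis estimator, a Beta-weighted sum of
  all order statistics, used for the decile-wise comparison of two
  elevational distributions.  For sample size n and probability q the
  weight of the i-th order statistic is

      w_i = I_{i/n}(a, b) - I_{(i-1)/n}(a, b),   a = (n+1)q,  b = (n+1)(1-q),

  with I the regularized incomplete beta function.  The estimator is
  location-scale equivariant and smoother than a single order statistic,
  which matters for decile differences of modest samples.
"""

from __future__ import annotations

import numpy as np
from scipy import special


def empirical_quantile(sample: np.ndarray, q: float | np.ndarray) -> np.ndarray | float:
    """Linear-interpolation empirical quantile (numpy's default convention)."""
    return np.quantile(np.asarray(sample, dtype=float), q)


def hd_weights(n: int, q: float) -> np.ndarray:
    """Harrell–Davis weights over the n order statistics for probability q."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile probability must be in (0, 1), got {q}")
    if n < 2:
        raise ValueError(f"need at least 2 observations, got {n}")
    a = (n + 1) * q
    b = (n + 1) * (1.0 - q)
    edges = np.arange(n + 1) / n
    cdf = special.betainc(a, b, edges)
    return np.diff(cdf)


def harrell_davis(sample: np.ndarray, q: float) -> float:
    """Harrell–Davis estimate of the q-quantile of ``sample``."""
    x = np.sort(np.asarray(sample, dtype=float))
    return float(hd_weights(x.size, q) @ x)


def hd_weight_matrix(n: int, qs: np.ndarray) -> np.ndarray:
    """Stacked weight rows, one per probability — for vectorized bootstraps."""
    return np.vstack([hd_weights(n, float(q)) for q in np.asarray(qs, dtype=float)])


def harrell_davis_many(samples: np.ndarray, qs: np.ndarray) -> np.ndarray:
    """Harrell–Davis quantiles for each row of ``samples`` at each of ``qs``.

    ``samples`` has shape (B, n); the result has shape (B, len(qs)).
    Used to evaluate bootstrap resamples without a Python-level loop.
    """
    samples = np.asarray(samples, dtype=float)
    W = hd_weight_matrix(samples.shape[1], qs)
    return np.sort(samples, axis=1) @ W.T
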