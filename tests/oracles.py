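"""Independent brute-force oracles used only by the tests.

These deliberately avoid the library routines they check: the
regularized incomplete beta function is evaluated with the classic
Lentz continued-fraction algorithm (log-gamma from the standard
library), and the Benjamini–Hochberg adjustment is the literal step-up
minimum formula.
"""

from __future__ import annotations

import math

import numpy as np


def _betacf(a: float, b: float, x: float) -> float:
    """Continued fraction for the incomplete beta function (Lentz's method)."""
    MAXIT, EPS, FPMIN = 200, 3e-16, 1e-300
    qab, qap, qam = a + b, a + 1.0, a - 1.0
    c = 1.0
    d = 1.0 - qab * x / qap
    if abs(d) < FPMIN:
        d = FPMIN
    d = 1.0 / d
    h = d
    for m in range(1, MAXIT + 1):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1.0 + aa * d
        if abs(d) < FPMIN:
            d = FPMIN
        c = 1.0 + aa / c
        if abs(c) < FPMIN:
            c = FPMIN
        d = 1.0 / d
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1.0 + aa * d
        if abs(d) < FPMIN:
            d = FPMIN
        c = 1.0 + aa / c
        if abs(c) < FPMIN:
            c = FPMIN
        d = 1.0 / d
        de = d * c
        h *= de
        if abs(de - 1.0) < EPS:
            return h
    raise RuntimeError("betacf did not converge")


def reg_inc_beta(a: float, b: float, x: float) -> float:
    """Regularized incomplete beta I_x(a, b) by continued fraction."""
    if x <= 0.0:
        return 0.0
    if x >= 1.0:
        return 1.0
    ln_bt = math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b) + a * math.log(x) + b * math.log(1.0 - x)
    bt = math.exp(ln_bt)
    if x < (a + 1.0) / (a + b + 2.0):
        return bt * _betacf(a, b, x) / a
    return 1.0 - bt * _betacf(b, a, 1.0 - x) / b


def hd_oracle(sample, q: float) -> float:
    """Harrell–Davis quantile as a direct Beta-CDF weight sum."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    a, b = (n + 1) * q, (n + 1) * (1 - q)
    w = np.array([reg_inc_beta(a, b, (i + 1) / n) - reg_inc_beta(a, b, i / n) for i in range(n)])
    return float(w @ x)


def bh_oracle(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up: adj p_(i) = min_{k >= i} p_(k) * m / k, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for rank_i in range(m):
        adj_sorted[rank_i] = min(
            min(p[order[k]] * m / (k + 1) for k in range(rank_i, m)), 1.0
        )
    out = np.empty(m)
    out[order] = adj_sorted
    return out
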