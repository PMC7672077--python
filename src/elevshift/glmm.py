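"""Laplace-approximation GLMMs with a species random intercept and an
optional observation-level random effect (OLRE).

The two models the pipeline needs share one structure:

* Poisson, log link:  count ~ fixed effects + (1 | species) + (1 | observation)
* Binomial, logit link:  survival ~ fixed effects + (1 | species)

Estimation profiles the fixed effects and random-effect modes jointly by
penalized iteratively reweighted least squares (PIRLS) at given variance
parameters, and optimizes the Laplace-approximate deviance over the
variance parameters in an outer bounded quasi-Newton loop.  Because the
species design is an indicator matrix and the OLRE design is the
identity, every linear-algebra step reduces to dense (p + S) systems
after eliminating the OLRE block in closed form, so fits stay fast even
with one random level per observation.

Per-term inference is by Wald chi-square from the joint-Hessian
covariance of the fixed effects (a likelihood-ratio option is available
via ``use_lrt``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
from scipy import optimize, special, stats

from .modelfit import ModelFit

_VAR_FLOOR = 1e-8  # a variance below this is treated as exactly zero
_ETA_CLIP = 30.0


class SeparationError(RuntimeError):
    """Raised when a binomial fit shows signs of complete separation."""


@dataclass
class _Family:
    name: str

    def mu(self, eta: np.ndarray) -> np.ndarray:
        if self.name == "poisson":
            return np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        return 1.0 / (1.0 + np.exp(-np.clip(eta, -_ETA_CLIP, _ETA_CLIP)))

    def weights(self, mu: np.ndarray) -> np.ndarray:
        if self.name == "poisson":
            return mu
        return mu * (1.0 - mu)

    def loglik(self, y: np.ndarray, mu: np.ndarray) -> float:
        if self.name == "poisson":
            return float(np.sum(y * np.log(mu) - mu - special.gammaln(y + 1)))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))

    def start_eta(self, y: np.ndarray) -> np.ndarray:
        if self.name == "poisson":
            return np.log(np.maximum(y, 0.5))
        p = (y + 0.5) / 2.0
        return np.log(p / (1 - p))


def _pirls(
    y: np.ndarray,
    X: np.ndarray,
    species: np.ndarray,
    fam: _Family,
    var_species: float,
    var_olre: float,
    tol: float = 1e-8,
    max_iter: int = 200,
):
    """Penalized IRLS over (beta, species modes, OLRE modes) at fixed variances.

    Returns (beta, u_species, e_olre, pdev, M, wtilde, converged) where M
    is the reduced (p + S) penalized information matrix and pdev the
    penalized deviance at the solution.
    """
    n, p = X.shape
    S = int(species.max()) + 1 if species.size else 0
    use_sp = var_species > _VAR_FLOOR
    use_ol = var_olre > _VAR_FLOOR

    eta = fam.start_eta(y)
    beta = np.zeros(p)
    u = np.zeros(S)
    e = np.zeros(n)
    pdev_old = np.inf
    converged = False
    M = np.zeros((p, p))
    wt = np.ones(n)

    for _ in range(max_iter):
        mu = fam.mu(eta)
        w = np.maximum(fam.weights(mu), 1e-10)
        z = eta + (y - mu) / w
        wt = w / (1.0 + var_olre * w) if use_ol else w

        if use_sp:
            Xw = X * wt[:, None]
            XtX = X.T @ Xw
            B = np.zeros((S, p))
            np.add.at(B, species, Xw)
            d = np.bincount(species, weights=wt, minlength=S) + 1.0 / var_species
            M = np.block([[XtX, B.T], [B, np.diag(d)]])
            rhs = np.concatenate([Xw.T @ z, np.bincount(species, weights=wt * z, minlength=S)])
            sol = np.linalg.solve(M, rhs)
            beta, u = sol[:p], sol[p:]
            resid = z - X @ beta - u[species]
        else:
            Xw = X * wt[:, None]
            M = X.T @ Xw
            beta = np.linalg.solve(M, Xw.T @ z)
            u = np.zeros(S)
            resid = z - X @ beta
        e = (var_olre * w * resid) / (1.0 + var_olre * w) if use_ol else np.zeros(n)
        eta = X @ beta + (u[species] if use_sp else 0.0) + e

        mu = fam.mu(eta)
        pdev = -2.0 * fam.loglik(y, mu)
        if use_sp:
            pdev += float(u @ u) / var_species
        if use_ol:
            pdev += float(e @ e) / var_olre
        if abs(pdev - pdev_old) < tol * (abs(pdev) + 1.0):
            converged = True
            break
        pdev_old = pdev

    return beta, u, e, pdev, M, wt, converged


def _laplace_deviance(
    y: np.ndarray,
    X: np.ndarray,
    species: np.ndarray,
    fam: _Family,
    var_species: float,
    var_olre: float,
) -> tuple[float, dict]:
    """-2 x Laplace log-likelihood at the PIRLS mode for given variances."""
    beta, u, e, _, M, wt, conv = _pirls(y, X, species, fam, var_species, var_olre)
    eta = X @ beta + (u[species] if var_species > _VAR_FLOOR else 0.0) + e
    mu = fam.mu(eta)
    w = np.maximum(fam.weights(mu), 1e-10)
    ll = fam.loglik(y, mu)
    logdet = 0.0
    if var_olre > _VAR_FLOOR:
        ll -= 0.5 * float(e @ e) / var_olre
        logdet += float(np.sum(np.log1p(var_olre * w)))
        w_eff = w / (1.0 + var_olre * w)
    else:
        w_eff = w
    if var_species > _VAR_FLOOR:
        ll -= 0.5 * float(u @ u) / var_species
        S = int(species.max()) + 1
        sw = np.bincount(species, weights=w_eff, minlength=S)
        logdet += float(np.sum(np.log1p(var_species * sw)))
    ll -= 0.5 * logdet
    state = {"beta": beta, "u": u, "e": e, "M": M, "wt": wt, "converged": conv, "loglik": ll}
    return -2.0 * ll, state


def fit_glmm(
    y: np.ndarray,
    X: np.ndarray,
    species: np.ndarray,
    family: str,
    coef_names: Sequence[str],
    terms: Dict[str, List[int]],
    olre: bool = False,
    use_lrt: bool = False,
    fixed_variances: Dict[str, float] | None = None,
) -> ModelFit:
    """Fit a GLMM with species random intercept (plus OLRE if requested).

    Parameters
    ----------
    y, X
        Response vector and fixed-effect design matrix (including the
        intercept column).
    species
        Integer codes (0..S-1) mapping each observation to its species.
    family
        ``"poisson"`` (log link) or ``"binomial"`` (logit link).
    terms
        Mapping from term name to the design-column indices it owns;
        drives the per-term Wald (or LRT) chi-square tests.  The
        intercept is conventionally excluded.
    fixed_variances
        Optional ``{"species": v, "olre": v}`` to hold variances fixed
        (e.g. at 0 to recover a plain GLM) instead of estimating them.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    species = np.asarray(species, dtype=int)
    fam = _Family(family)
    if family not in ("poisson", "binomial"):
        raise ValueError(f"unsupported family {family!r}")
    n, p = X.shape
    S = int(species.max()) + 1 if species.size else 0
    flags: List[str] = []

    if family == "binomial" and (y.min() == y.max()):
        flags.append("complete separation: all outcomes identical")

    free: List[str] = []
    fixed_variances = dict(fixed_variances or {})
    if "species" not in fixed_variances:
        free.append("species")
    if olre and "olre" not in fixed_variances:
        free.append("olre")
    if not olre:
        fixed_variances.setdefault("olre", 0.0)

    def unpack(theta: np.ndarray) -> tuple[float, float]:
        vals = dict(fixed_variances)
        for name, t in zip(free, theta):
            vals[name] = float(t) ** 2
        return vals.get("species", 0.0), vals.get("olre", 0.0)

    opt_success = True
    if free:
        def objective(theta: np.ndarray) -> float:
            vs, vo = unpack(theta)
            return _laplace_deviance(y, X, species, fam, vs, vo)[0]

        x0 = np.full(len(free), 0.5)
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=[(0.0, 20.0)] * len(free),
        )
        opt_success = bool(res.success)
        var_species, var_olre = unpack(res.x)
    else:
        var_species, var_olre = unpack(np.empty(0))

    dev, state = _laplace_deviance(y, X, species, fam, var_species, var_olre)
    beta, M, wt = state["beta"], state["M"], state["wt"]
    if not state["converged"]:
        flags.append("inner PIRLS did not converge")
    if not opt_success:
        flags.append("variance optimization did not converge")

    # covariance of beta: top-left block of the inverse penalized information
    if var_species > _VAR_FLOOR:
        cov = np.linalg.inv(M)[:p, :p]
    else:
        cov = np.linalg.inv(M)
    se = np.sqrt(np.diag(cov))

    if family == "binomial" and np.any(np.abs(beta) > 15):
        big = [coef_names[i] for i in np.flatnonzero(np.abs(beta) > 15)]
        flags.append(f"possible complete separation in term(s): {big}")

    if "species" in free and var_species < _VAR_FLOOR:
        flags.append("species random-effect variance at boundary (singular)")
    if olre and "olre" in free and var_olre < _VAR_FLOOR:
        flags.append("OLRE variance at boundary (singular)")

    term_chisq: Dict[str, float] = {}
    term_df: Dict[str, int] = {}
    term_p: Dict[str, float] = {}
    for name, idx in terms.items():
        idx = list(idx)
        if use_lrt:
            keep = [j for j in range(p) if j not in idx]
            sub_terms = {k: [keep.index(j) for j in v if j in keep] for k, v in terms.items() if k != name}
            sub = fit_glmm(
                y, X[:, keep], species, family, [coef_names[j] for j in keep], sub_terms,
                olre=olre, use_lrt=False, fixed_variances=None if free else fixed_variances,
            )
            chisq = max(0.0, 2.0 * (state["loglik"] - sub.loglik))
        else:
            b = beta[idx]
            Vi = np.linalg.inv(cov[np.ix_(idx, idx)])
            chisq = float(b @ Vi @ b)
        term_chisq[name] = chisq
        term_df[name] = len(idx)
        term_p[name] = float(stats.chi2.sf(chisq, len(idx)))

    converged = state["converged"] and opt_success and not any("separation" in f for f in flags)
    return ModelFit(
        terms=list(terms),
        coef_names=list(coef_names),
        coefficients=beta,
        standard_errors=se,
        term_chisq=term_chisq,
        term_df=term_df,
        term_p=term_p,
        random_effect_variances={"species": var_species, **({"olre": var_olre} if olre else {})},
        loglik=state["loglik"],
        converged=converged,
        n_obs=n,
        n_species=S,
        flags=flags,
        cov=cov,
    )
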