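"""Random-intercept logistic regression for 95PLL risk.

Fits a generalized linear mixed model ``logit P(y_ij = 1) = x_ij' beta + b_i``
with a Gaussian random intercept ``b_i ~ N(0, sigma_b^2)`` per mouse, by
maximum likelihood with Gauss-Hermite quadrature over the random effect
(one-dimensional integral per mouse, so quadrature is essentially exact at
moderate node counts).  Population-level ("fixed-effects-only") predictions
set the random intercept to zero — the relevant quantity when scoring mice
unseen at training time.

Standard errors come from the inverse of a central-finite-difference Hessian
of the negative log-likelihood at the optimum (Wald intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = ["GlmmFit", "fit_glmm", "predict_fixed", "roc_auc"]


@dataclass
class GlmmFit:
    """Result of a random-intercept logistic fit."""

    terms: tuple[str, ...]  # fixed-effect column names (after the intercept)
    coef: dict[str, float]  # includes "intercept"
    se: dict[str, float]
    random_intercept_sd: float
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int

    def wald_ci(self, term: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        crit = norm.ppf(0.5 + level / 2)
        return (
            self.coef[term] - crit * self.se[term],
            self.coef[term] + crit * self.se[term],
        )


def _sigmoid(x):
    return special.expit(x)


def _neg_loglik(theta, X, y, group_idx, n_groups, nodes, weights):
    """-log marginal likelihood; theta = (beta..., log sigma_b)."""
    beta = theta[:-1]
    sigma_b = np.exp(np.clip(theta[-1], -20.0, 20.0))
    lp = X @ beta
    # per node: sum_i log f(y_i | b = sqrt(2) sigma_b z_k), accumulated by group
    log_g = np.empty((n_groups, len(nodes)))
    for k, (z, _) in enumerate(zip(nodes, weights)):
        eta = lp + np.sqrt(2.0) * sigma_b * z
        ll_i = -np.logaddexp(0.0, np.where(y == 1, -eta, eta))
        log_g[:, k] = np.bincount(group_idx, weights=ll_i, minlength=n_groups)
    log_w = np.log(weights) - 0.5 * np.log(np.pi)
    return -float(special.logsumexp(log_g + log_w[None, :], axis=1).sum())


def _fd_hessian(f, x, eps=1e-4):
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


def fit_glmm(
    rows: pd.DataFrame,
    fixed_terms: tuple[str, ...] = ("txw_fail", "fgi_score"),
    outcome: str = "is_95pll",
    group: str = "mouse_id",
    n_quad: int = 25,
) -> GlmmFit:
    """Fit the random-intercept logistic model by ML with GH quadrature.

    ``rows`` must contain the fixed-term columns, a binary outcome column,
    and a grouping column.  Raises on a single-class outcome or fewer than
    two groups; non-convergence is flagged on the returned fit.
    """
    if len(fixed_terms) < 1:
        raise ValueError("need at least one fixed term")
    y = rows[outcome].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; model is not identifiable")
    groups, group_idx = np.unique(rows[group].to_numpy(), return_inverse=True)
    if len(groups) < 2:
        raise ValueError("need at least two groups (mice)")
    X = np.column_stack(
        [np.ones(len(rows))] + [rows[t].astype(float).to_numpy() for t in fixed_terms]
    )
    if np.isnan(X).any():
        raise ValueError("missing covariate values in GLMM input")
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)

    args = (X, y, group_idx, len(groups), nodes, weights)
    x0 = np.zeros(X.shape[1] + 1)  # beta = 0, log sigma_b = 0
    res = optimize.minimize(
        _neg_loglik, x0, args=args, method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-9},
    )
    # polish with BFGS from the simplex optimum
    res2 = optimize.minimize(_neg_loglik, res.x, args=args, method="BFGS",
                             options={"maxiter": 500})
    best = res2 if res2.fun <= res.fun else res
    theta = best.x
    converged = bool((best.success or res.success) and np.all(np.abs(theta[:-1]) < 30))

    H = _fd_hessian(lambda t: _neg_loglik(t, *args), theta)
    se = np.full(len(theta), np.nan)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if (d[:-1] <= 0).any():
            converged = False
        se = np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        converged = False

    names = ("intercept",) + tuple(fixed_terms)
    return GlmmFit(
        terms=tuple(fixed_terms),
        coef=dict(zip(names, theta[:-1])),
        se=dict(zip(names, se[:-1])),
        random_intercept_sd=float(np.exp(theta[-1])),
        loglik=-float(best.fun),
        converged=converged,
        n_obs=len(rows),
        n_groups=len(groups),
    )


def predict_fixed(fit: GlmmFit, rows: pd.DataFrame) -> np.ndarray:
    """Fixed-effects-only probabilities (random intercept set to zero)."""
    for t in fit.terms:
        if t not in rows.columns:
            raise KeyError(f"missing covariate {t!r}")
    eta = fit.coef["intercept"] + sum(
        fit.coef[t] * rows[t].astype(float).to_numpy() for t in fit.terms
    )
    return _sigmoid(eta)


def roc_auc(probabilities, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUC (Mann-Whitney concordance with tie averaging)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    fpr, tpr, thresh = roc_curve(labels, probabilities)
    auc = float(roc_auc_score(labels, probabilities))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresh}), auc
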