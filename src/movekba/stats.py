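"""Comparison models: mixed-effects beta regression and a log-area LMM.

Two questions drive the analysis.  First, does the proportion of each
behaviour's core area captured by the all-behaviour core area differ by
behaviour?  Answered with a beta regression on the transformed capture
proportions: logit-linked mean per behaviour subset, common precision φ,
and a colony random intercept integrated out by adaptive Gauss-Hermite
quadrature.  Second, do population-level key-area sizes differ by
behaviour?  Answered with a Gaussian linear mixed model on log10 area with
behaviour fixed effects (vs the all-behaviour baseline) and a colony random
intercept, fitted by maximum likelihood profiled over the variance ratio.

Both models are implemented directly (no mixed-model library); Wald 95%
intervals come from the observed information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import betaln, expit, logit, logsumexp
from scipy.stats import norm

logger = logging.getLogger(__name__)

Z95 = float(norm.ppf(0.975))


@dataclass
class BetaGLMMFit:
    subsets: list[str]
    beta: np.ndarray  # per-subset fixed effects, logit scale (cell means)
    beta_se: np.ndarray
    phi: float  # beta precision
    random_sd: float  # colony random-intercept sd (logit scale)
    means: pd.DataFrame  # subset, estimate, lo95, hi95 (response scale, u = 0)
    loglik: float
    converged: bool
    n_quad: int
    singular: bool = False  # random-effect variance collapsed to ~0

    def mean_for(self, subset: str) -> float:
        return float(self.means.set_index("subset").loc[subset, "estimate"])


@dataclass
class LMMFit:
    terms: list[str]  # intercept (baseline) then contrasts
    beta: np.ndarray
    beta_se: np.ndarray
    conf_int: np.ndarray  # (p, 2)
    random_var: float
    resid_var: float
    r2_marginal: float
    r2_conditional: float
    loglik: float
    baseline: str


def _beta_logpdf(y, mu, phi):
    a = mu * phi
    b = (1.0 - mu) * phi
    return (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y) - betaln(a, b)


def _agh_marginal_loglik(y, eta, starts, phi, sd, nodes, weights, u_modes):
    """Total log marginal likelihood, all groups at once, adaptive GH.

    *y*, *eta* are ordered by group; *starts* are the group start offsets
    (for ``np.add.reduceat``); *u_modes* (G,) is updated in place with the
    integrand modes (warm starts for the next evaluation).  The mode of
    each group's integrand is found by damped Newton on numeric
    derivatives; the quadrature is recentred and rescaled there.
    """

    def f(u):  # (G,) -> per-group log joint at random intercept u
        mu = expit(eta + np.repeat(u, np.diff(np.append(starts, len(y)))))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        per_obs = _beta_logpdf(y, mu, phi)
        return np.add.reduceat(per_obs, starts) + norm.logpdf(u, scale=sd)

    u = np.clip(u_modes, -8.0 * sd, 8.0 * sd)
    h = max(1e-6, 1e-4 * sd)
    for _ in range(50):
        fp, f0, fm = f(u + h), f(u), f(u - h)
        g = (fp - fm) / (2 * h)
        f2 = np.minimum((fp - 2 * f0 + fm) / h**2, -1e-8)
        step = np.clip(-g / f2, -4.0 * sd, 4.0 * sd)
        u = u + step
        if np.max(np.abs(step)) < 1e-9:
            break
    fp, f0, fm = f(u + h), f(u), f(u - h)
    f2 = np.minimum((fp - 2 * f0 + fm) / h**2, -1e-8)
    tau = 1.0 / np.sqrt(-f2)
    fu = np.stack([f(u + np.sqrt(2.0) * tau * z) for z in nodes])  # (Q, G)
    log_int = np.log(np.sqrt(2.0) * tau) + logsumexp(
        np.log(weights)[:, None] + nodes[:, None] ** 2 + fu, axis=0
    )
    u_modes[:] = u
    return float(np.sum(log_int))


def fit_beta_glmm(
    records: pd.DataFrame,
    response: str = "capture_transformed",
    subset_col: str = "subset",
    group_col: str = "colony_id",
    n_quad: int = 15,
) -> BetaGLMMFit:
    """ML fit of the mixed-effects beta regression on (0, 1) responses.

    Uses cell-means coding (one logit-scale mean per behaviour subset) so
    reported subset means need no baseline bookkeeping; contrasts are
    differences of coefficients.  Responses must already be transformed
    away from {0, 1}.
    """
    y_all = records[response].to_numpy(dtype=float)
    if np.any(y_all <= 0) or np.any(y_all >= 1):
        raise ValueError(
            "responses must lie strictly in (0, 1); apply transform_proportion first"
        )
    subsets = sorted(records[subset_col].unique())
    groups = sorted(records[group_col].unique())
    if len(groups) < 2:
        raise ValueError("random effect needs >= 2 groups")
    sub_idx = records[subset_col].map({s: i for i, s in enumerate(subsets)}).to_numpy()
    grp = records[group_col].to_numpy()
    # order observations by group so per-group sums are reduceat slices
    order = np.argsort(grp, kind="mergesort")
    y_ord = y_all[order]
    sub_ord = sub_idx[order]
    counts = np.array([(grp == g).sum() for g in groups])
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    modes = np.zeros(len(groups))  # warm starts for the inner mode search

    def nll(theta):
        beta = theta[: len(subsets)]
        phi = np.exp(theta[len(subsets)])
        sd = np.exp(theta[len(subsets) + 1])
        try:
            total = _agh_marginal_loglik(
                y_ord, beta[sub_ord], starts, phi, sd, nodes, weights, modes
            )
        except (ValueError, FloatingPointError):
            return 1e12
        return -total if np.isfinite(total) else 1e12

    # moment-based start: subset means on the logit scale
    beta0 = np.array(
        [logit(np.clip(y_all[sub_idx == i].mean(), 0.01, 0.99)) for i in range(len(subsets))]
    )
    theta0 = np.concatenate([beta0, [np.log(10.0), np.log(0.3)]])
    res = minimize(nll, theta0, method="Nelder-Mead",
                   options={"maxiter": 1000, "xatol": 1e-7, "fatol": 1e-9})
    res = minimize(nll, res.x, method="BFGS", options={"maxiter": 200})

    theta = res.x
    beta = theta[: len(subsets)]
    phi = float(np.exp(theta[len(subsets)]))
    sd = float(np.exp(theta[len(subsets) + 1]))
    singular = sd < 1e-4
    if singular:
        logger.info("fit_beta_glmm: random-intercept sd collapsed to ~0")

    cov = _numeric_cov(nll, theta)
    beta_se = np.sqrt(np.clip(np.diag(cov)[: len(subsets)], 0, None))
    means = pd.DataFrame(
        {
            "subset": subsets,
            "estimate": expit(beta),
            "lo95": expit(beta - Z95 * beta_se),
            "hi95": expit(beta + Z95 * beta_se),
        }
    )
    return BetaGLMMFit(
        subsets=subsets, beta=beta, beta_se=beta_se, phi=phi, random_sd=sd,
        means=means, loglik=-float(res.fun), converged=bool(res.success) or res.fun < 1e11,
        n_quad=n_quad, singular=singular,
    )


def _numeric_cov(nll, theta, h: float = 1e-4) -> np.ndarray:
    """Observed-information covariance by central-difference Hessian."""
    p = len(theta)
    H = np.zeros((p, p))
    f0 = nll(theta)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h
            ej = np.zeros(p); ej[j] = h
            if i == j:
                H[i, i] = (nll(theta + ei) - 2 * f0 + nll(theta - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    nll(theta + ei + ej) - nll(theta + ei - ej)
                    - nll(theta - ei + ej) + nll(theta - ei - ej)
                ) / (4 * h**2)
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


def fit_lmm(
    table: pd.DataFrame,
    response: str = "log10_area",
    fixed_col: str = "subset",
    group_col: str = "colony_id",
    baseline: str = "all",
) -> LMMFit:
    """ML fit of the random-intercept Gaussian LMM, profiled over the
    variance ratio λ = σ²_group / σ²_resid (1-D numeric optimisation).

    Fixed effects use treatment coding against *baseline*; Nakagawa R²:
    marginal = var_fixed / (var_fixed + var_group + var_resid),
    conditional adds var_group to the numerator.
    """
    df = table.dropna(subset=[response]).copy()
    groups = sorted(df[group_col].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups (colonies)")
    present = sorted(df[fixed_col].unique())
    if baseline not in present:
        logger.warning(
            "fit_lmm: baseline %r absent from the data; using %r", baseline, present[0]
        )
        baseline = present[0]
    levels = [baseline] + [s for s in present if s != baseline]
    y = df[response].to_numpy(dtype=float)
    n = len(y)
    X = np.zeros((n, len(levels)))
    X[:, 0] = 1.0
    for j, lev in enumerate(levels[1:], start=1):
        X[:, j] = (df[fixed_col] == lev).to_numpy()
    gidx = [np.flatnonzero((df[group_col] == g).to_numpy()) for g in groups]

    def profile_nll(log_lam):
        lam = np.exp(log_lam)
        # Woodbury per group: V_i^{-1} = I − λ/(1+λ n_i) J;  log|V_i| = log(1+λ n_i)
        XtVX = np.zeros((X.shape[1], X.shape[1]))
        XtVy = np.zeros(X.shape[1])
        logdet = 0.0
        for idx in gidx:
            ni = len(idx)
            w = lam / (1.0 + lam * ni)
            Xi, yi = X[idx], y[idx]
            XtVX += Xi.T @ Xi - w * np.outer(Xi.sum(axis=0), Xi.sum(axis=0))
            XtVy += Xi.T @ yi - w * Xi.sum(axis=0) * yi.sum()
            logdet += np.log1p(lam * ni)
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(XtVX, XtVy, rcond=None)[0]
        rss = 0.0
        for idx in gidx:
            ri = y[idx] - X[idx] @ beta
            w = lam / (1.0 + lam * len(idx))
            rss += ri @ ri - w * ri.sum() ** 2
        sig2 = rss / n
        nll = 0.5 * (n * np.log(2 * np.pi * sig2) + logdet + n)
        return nll, beta, sig2, XtVX

    res = minimize_scalar(
        lambda ll: profile_nll(ll)[0], bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-10},
    )
    log_lam = float(res.x)
    nll, beta, sig2, XtVX = profile_nll(log_lam)
    lam = np.exp(log_lam)
    resid_var = float(sig2)
    random_var = float(lam * sig2)
    cov_beta = np.linalg.inv(XtVX) * sig2
    se = np.sqrt(np.diag(cov_beta))
    ci = np.column_stack([beta - Z95 * se, beta + Z95 * se])

    var_fixed = float(np.var(X @ beta))
    denom = var_fixed + random_var + resid_var
    return LMMFit(
        terms=levels, beta=beta, beta_se=se, conf_int=ci,
        random_var=random_var, resid_var=resid_var,
        r2_marginal=var_fixed / denom,
        r2_conditional=(var_fixed + random_var) / denom,
        loglik=-float(nll), baseline=baseline,
    )
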