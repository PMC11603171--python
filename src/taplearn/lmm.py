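"""Random-intercept linear mixed model helpers.

The fitting itself is delegated to statsmodels' ``MixedLM`` (REML).  This
module adds what the inference around treatment contrasts needs and the
backend does not provide: closed-form marginal covariance algebra for the
random-intercept structure, the REML log-likelihood as a function of the
variance components, and Satterthwaite denominator degrees of freedom for
fixed-effect contrasts.

For a model y = X b + Z u + e with one random intercept per participant
(u ~ N(0, tau2), e ~ N(0, sigma2 I)) the marginal covariance of group i is
V_i = sigma2 I + tau2 J, whose inverse and determinant are closed-form:

    V_i^{-1} = (1/sigma2) (I - tau2 / (sigma2 + n_i tau2) J)
    log|V_i| = (n_i - 1) log sigma2 + log(sigma2 + n_i tau2)

Satterthwaite df for a contrast L b follow lmerTest's recipe:
nu = 2 f^2 / (g' A g) with f(theta) = L C(theta) L',
C = (X' V^{-1} X)^{-1}, g the gradient of f at the REML estimate and A
the asymptotic covariance of the variance components (inverse observed
information of the REML criterion), both obtained numerically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class RandomInterceptFit:
    """Marginal quantities of a fitted random-intercept model."""

    beta: np.ndarray
    tau2: float  # random-intercept variance
    sigma2: float  # residual variance
    cov_beta: np.ndarray  # (X' V^-1 X)^-1 at the REML estimate
    groups: list[tuple[np.ndarray, np.ndarray]]  # (X_i, y_i) per participant
    n_obs: int
    rank: int
    singular: bool  # tau2 collapsed to (near) zero


def _group_blocks(X: np.ndarray, y: np.ndarray, group_ids: np.ndarray):
    order = np.argsort(group_ids, kind="stable")
    X, y, g = X[order], y[order], group_ids[order]
    out = []
    for gid in np.unique(g):
        m = g == gid
        out.append((X[m], y[m]))
    return out


def _suff_stats(groups, tau2: float, sigma2: float):
    """Accumulate X'V^-1X, X'V^-1y, y'V^-1y and sum log|V_i|."""
    p = groups[0][0].shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    ytVy = 0.0
    logdet = 0.0
    for Xi, yi in groups:
        ni = len(yi)
        c = tau2 / (sigma2 + ni * tau2)
        x1 = Xi.sum(axis=0)
        y1 = yi.sum()
        XtVX += (Xi.T @ Xi - c * np.outer(x1, x1)) / sigma2
        XtVy += (Xi.T @ yi - c * x1 * y1) / sigma2
        ytVy += (yi @ yi - c * y1 * y1) / sigma2
        logdet += (ni - 1) * np.log(sigma2) + np.log(sigma2 + ni * tau2)
    return XtVX, XtVy, ytVy, logdet


def reml_loglik(theta: np.ndarray, groups) -> float:
    """Restricted log-likelihood (up to an additive constant) at
    theta = (tau2, sigma2)."""
    tau2, sigma2 = float(theta[0]), float(theta[1])
    if sigma2 <= 0 or tau2 < 0:
        return -np.inf
    XtVX, XtVy, ytVy, logdet = _suff_stats(groups, tau2, sigma2)
    sign, logdet_M = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtVX, XtVy)
    ypy = ytVy - XtVy @ beta
    return -0.5 * (logdet + logdet_M + ypy)


def beta_cov(theta: np.ndarray, groups) -> tuple[np.ndarray, np.ndarray]:
    """GLS estimate of the fixed effects and their covariance at theta."""
    tau2, sigma2 = float(theta[0]), float(theta[1])
    XtVX, XtVy, _, _ = _suff_stats(groups, tau2, sigma2)
    C = np.linalg.inv(XtVX)
    return C @ XtVy, C


def fit_random_intercept(
    X: np.ndarray, y: np.ndarray, group_ids: np.ndarray
) -> RandomInterceptFit:
    """REML fit via statsmodels MixedLM; falls back to OLS (flagged
    singular) when the intercept variance collapses or the fit fails."""
    import statsmodels.api as sm

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = _group_blocks(X, y, np.asarray(group_ids))
    n, p = X.shape

    tau2 = sigma2 = None
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, X, groups=np.asarray(group_ids)).fit(reml=True)
        sigma2 = float(res.scale)
        tau2 = float(np.asarray(res.cov_re)[0, 0])
    except Exception:
        pass

    singular = tau2 is None or not np.isfinite(tau2) or tau2 <= 1e-10 * y.var()
    if tau2 is None or not np.isfinite(tau2):
        tau2 = 0.0
    if sigma2 is None or not np.isfinite(sigma2) or sigma2 <= 0:
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        sigma2 = float(resid @ resid / max(n - p, 1))
    # keep the marginal covariance invertible even for degenerate data
    floor = 1e-10 * float(y.var()) if y.var() > 0 else 1e-12
    sigma2 = max(sigma2, floor, 1e-12)
    tau2 = max(tau2, 0.0)
    beta, C = beta_cov(np.array([tau2, sigma2]), groups)
    return RandomInterceptFit(
        beta=beta, tau2=tau2, sigma2=sigma2, cov_beta=C, groups=groups,
        n_obs=n, rank=p, singular=singular,
    )


def satterthwaite_df(fit: RandomInterceptFit, L: np.ndarray) -> tuple[float, str]:
    """Satterthwaite denominator df for the 1-df contrast L'beta.

    Returns (df, method); method is "satterthwaite" or "residual" when the
    fit is singular or the information matrix is not usable, in which case
    df = n_obs - rank.
    """
    L = np.asarray(L, dtype=float).ravel()
    fallback = float(fit.n_obs - fit.rank), "residual"
    if fit.singular:
        return fallback
    theta = np.array([fit.tau2, fit.sigma2])

    def f(th: np.ndarray) -> float:
        _, C = beta_cov(th, fit.groups)
        return float(L @ C @ L)

    # numeric gradient of f and Hessian of the REML criterion at theta
    h = np.maximum(1e-7, 1e-4 * theta)
    grad = np.zeros(2)
    for j in range(2):
        e = np.zeros(2)
        e[j] = h[j]
        grad[j] = (f(theta + e) - f(np.maximum(theta - e, [0.0, 1e-12]))) / (
            theta[j] + h[j] - max(theta[j] - h[j], 0.0 if j == 0 else 1e-12)
        )
    H = np.zeros((2, 2))
    ll0 = reml_loglik(theta, fit.groups)
    for j in range(2):
        for k in range(j, 2):
            ej = np.zeros(2); ej[j] = h[j]
            ek = np.zeros(2); ek[k] = h[k]
            if j == k:
                lp = reml_loglik(theta + ej, fit.groups)
                lm = reml_loglik(np.maximum(theta - ej, [0.0, 1e-12]), fit.groups)
                H[j, j] = (lp - 2 * ll0 + lm) / (h[j] ** 2)
            else:
                lpp = reml_loglik(theta + ej + ek, fit.groups)
                lpm = reml_loglik(np.maximum(theta + ej - ek, [0.0, 1e-12]), fit.groups)
                lmp = reml_loglik(np.maximum(theta - ej + ek, [0.0, 1e-12]), fit.groups)
                lmm_ = reml_loglik(np.maximum(theta - ej - ek, [0.0, 1e-12]), fit.groups)
                H[j, k] = H[k, j] = (lpp - lpm - lmp + lmm_) / (4 * h[j] * h[k])
    info = -H
    try:
        A = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return fallback
    denom = float(grad @ A @ grad)
    if denom <= 0 or not np.isfinite(denom):
        return fallback
    nu = 2.0 * f(theta) ** 2 / denom
    if not np.isfinite(nu) or nu <= 0:
        return fallback
    # df cannot sensibly exceed the residual df
    return min(nu, float(fit.n_obs - fit.rank)), "satterthwaite"


def contrast_test(
    fit: RandomInterceptFit, L: np.ndarray
) -> dict[str, float | str]:
    """t test of the contrast L'beta with Satterthwaite df."""
    L = np.asarray(L, dtype=float).ravel()
    est = float(L @ fit.beta)
    se = float(np.sqrt(L @ fit.cov_beta @ L))
    df, method = satterthwaite_df(fit, L)
    t = est / se if se > 0 else np.nan
    p = 2.0 * stats.t.sf(abs(t), df) if np.isfinite(t) else np.nan
    return {"estimate": est, "se": se, "t": t, "df": df, "p": p,
            "df_method": method}


def wald_f_test(fit: RandomInterceptFit, Lq: np.ndarray) -> dict[str, float | str]:
    """Omnibus Wald F test of the q-df hypothesis Lq beta = 0.

    The denominator df is the mean of the per-row Satterthwaite df — a
    pragmatic approximation, flagged in the output.
    """
    Lq = np.atleast_2d(np.asarray(Lq, dtype=float))
    q = Lq.shape[0]
    est = Lq @ fit.beta
    M = Lq @ fit.cov_beta @ Lq.T
    F = float(est @ np.linalg.solve(M, est)) / q
    dfs = [satterthwaite_df(fit, row)[0] for row in Lq]
    df_den = float(np.mean(dfs))
    p = stats.f.sf(F, q, df_den)
    eta2 = (q * F) / (q * F + df_den)
    return {"F": F, "df_num": float(q), "df_den": df_den, "p": float(p),
            "eta_squared": float(eta2), "df_method": "satterthwaite-mean"}
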