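"""Independently coded reference implementations used only as test oracles.

Everything here is written from textbook formulas — t CDF through the
regularized incomplete beta function, OLS through explicitly solved normal
equations, the inverse-variance weighted mean in plain arithmetic — so the
implementations under test are never checked against themselves.
"""

import math

import numpy as np
from scipy.special import betainc, ndtr


def t_sf_twosided(t: float, df: float) -> float:
    """Two-sided tail of the t distribution via the incomplete beta function."""
    if not math.isfinite(t):
        return 0.0
    x = df / (df + t * t)
    return float(betainc(df / 2.0, 0.5, x))


def one_sample_t(values) -> tuple:
    v = np.asarray(values, dtype=float)
    n = v.size
    m = v.mean()
    sd = math.sqrt(((v - m) ** 2).sum() / (n - 1))
    t = m / (sd / math.sqrt(n))
    return t, t_sf_twosided(t, n - 1)


def welch_t(a, b) -> tuple:
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    va = ((a - a.mean()) ** 2).sum() / (na - 1)
    vb = ((b - b.mean()) ** 2).sum() / (nb - 1)
    t = (a.mean() - b.mean()) / math.sqrt(va / na + vb / nb)
    df = (va / na + vb / nb) ** 2 / (
        (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    )
    return t, t_sf_twosided(t, df)


def pearson(x, y) -> tuple:
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    xc, yc = x - x.mean(), y - y.mean()
    r = (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())
    t = r * math.sqrt(n - 2) / math.sqrt(1 - r * r)
    return r, t_sf_twosided(t, n - 2)


def simple_ols(x, y) -> tuple:
    """Slope, se and two-sided P by explicitly solved 2x2 normal equations."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    X = np.column_stack([np.ones(n), x])
    xtx = X.T @ X
    coef = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ coef
    sigma2 = (resid**2).sum() / (n - 2)
    cov = sigma2 * np.linalg.inv(xtx)
    beta, se = coef[1], math.sqrt(cov[1, 1])
    t = beta / se
    return beta, se, t_sf_twosided(t, n - 2)


def multi_ols_residuals(y, covariates) -> np.ndarray:
    """OLS residuals of y on [1, covariates] via normal equations."""
    y = np.asarray(y, float)
    X = np.column_stack([np.ones(y.size)] + [np.asarray(c, float) for c in covariates])
    coef = np.linalg.solve(X.T @ X, X.T @ y)
    return y - X @ coef


def fixed_effects_meta(betas, ses) -> tuple:
    betas, ses = np.asarray(betas, float), np.asarray(ses, float)
    w = 1.0 / ses**2
    beta = (w * betas).sum() / w.sum()
    se = 1.0 / math.sqrt(w.sum())
    z = beta / se
    p = 2.0 * (1.0 - ndtr(abs(z)))
    return beta, se, z, p
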