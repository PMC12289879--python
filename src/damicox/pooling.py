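"""Rubin's rules for combining per-imputation estimates.

Pooling is done on the coefficient (log hazard ratio) scale: with m
imputations, point estimates Q_i and squared standard errors U_i,

    Qbar = mean(Q_i)
    W    = mean(U_i)                      (within-imputation variance)
    B    = var(Q_i)                       (between-imputation variance)
    T    = W + (1 + 1/m) B                (total variance)

Interval estimates use a t reference with Barnard-Rubin small-sample degrees
of freedom, which requires the complete-data degrees of freedom
(n_obs - k_params). Hazard ratios and their CI bounds are the exponentials
of the pooled log-scale quantities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def pool_rubin(estimates, variances, n_obs: int, k_params: int,
               terms: list[str] | None = None,
               alpha: float = 0.05) -> pd.DataFrame:
    """Pool m sets of coefficients with Rubin's rules.

    Parameters
    ----------
    estimates : array-like, shape (m, p)
        Per-imputation coefficient vectors, aligned across imputations.
    variances : array-like, shape (m, p)
        Per-imputation squared standard errors.
    n_obs, k_params : int
        Complete-data sample size and number of fitted parameters, for the
        Barnard-Rubin degrees of freedom.
    terms : list of str, optional
        Coefficient names (index of the returned table).

    Returns
    -------
    DataFrame indexed by term with columns: estimate, se, W, B, T, df,
    t, p, fmi, hr, hr_lo, hr_hi.
    """
    Q = np.atleast_2d(np.asarray(estimates, float))
    U = np.atleast_2d(np.asarray(variances, float))
    if Q.shape != U.shape:
        raise ValueError("estimates and variances must have the same shape")
    m, p = Q.shape
    if m < 2:
        raise ValueError("Rubin pooling needs m >= 2 imputations")
    if terms is not None and len(terms) != p:
        raise ValueError("terms length does not match coefficient count")

    qbar = Q.mean(axis=0)
    W = U.mean(axis=0)
    B = Q.var(axis=0, ddof=1)
    T = W + (1 + 1.0 / m) * B

    # Barnard-Rubin degrees of freedom
    nu_com = max(n_obs - k_params, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = (1 + 1.0 / m) * B / T            # fraction of variance due to B
        lam = np.where(T > 0, lam, 0.0)
        nu_old = np.where(B > 0,
                          (m - 1) / np.maximum(lam, 1e-300) ** 2,
                          np.inf)
        nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
        nu = 1.0 / (1.0 / nu_old + 1.0 / nu_obs)

    se = np.sqrt(T)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, qbar / se, 0.0)
    pval = 2 * stats.t.sf(np.abs(tval), df=nu)
    tq = stats.t.ppf(1 - alpha / 2, df=nu)
    lo = qbar - tq * se
    hi = qbar + tq * se

    r = np.where(W > 0, (1 + 1.0 / m) * B / W, np.inf)
    fmi = np.where(np.isfinite(r), (r + 2.0 / (nu + 3.0)) / (r + 1.0), 1.0)

    out = pd.DataFrame({
        "estimate": qbar, "se": se, "W": W, "B": B, "T": T,
        "df": nu, "t": tval, "p": pval, "fmi": fmi,
        "hr": np.exp(qbar), "hr_lo": np.exp(lo), "hr_hi": np.exp(hi),
    })
    if terms is not None:
        out.index = pd.Index(terms, name="term")
    return out
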