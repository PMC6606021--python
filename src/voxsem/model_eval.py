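"""Nested model comparison and global fit indices.

Likelihood-ratio (chi-square difference) tests compare nested growth
specifications.  Global indices (RMSEA, CFI, SRMR) are defined from a
model chi-square against a saturated model; for the two-part model a
natural saturated reference exists only for the continuous part, so the
chi-square-based indices here are computed from the continuous-part
normal likelihood against unstructured moments estimated by EM over the
missingness patterns.  The binary part enters model selection through
likelihood-ratio tests only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple
import warnings

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .growth import GrowthSpec, TwoPartData
from .likelihood import marginal_loglik, implied_moments

__all__ = [
    "LRTResult",
    "likelihood_ratio_test",
    "rmsea",
    "cfi",
    "srmr",
    "information_criteria",
    "FitIndices",
    "mvn_em",
    "compute_fit_indices",
]


class LRTResult(NamedTuple):
    delta_chi2: float
    df: int
    p: float
    delta_chi2_signed: float


def likelihood_ratio_test(loglik_restricted: float, loglik_full: float, df_diff: int) -> LRTResult:
    """Chi-square difference test for nested models.

    The signed difference is preserved as a diagnostic (numerical noise
    or boundary solutions can make it slightly negative); the test
    statistic is clipped at zero, yielding p = 1 in that case.
    """
    if df_diff <= 0:
        raise ValueError("df_diff must be positive")
    signed = 2.0 * (loglik_full - loglik_restricted)
    if signed < 0:
        warnings.warn(
            f"negative chi-square difference ({signed:.3g}); clipped to 0 for the test",
            stacklevel=2,
        )
    stat = max(signed, 0.0)
    p = float(chi2_dist.sf(stat, df_diff))
    return LRTResult(stat, int(df_diff), p, signed)


def rmsea(chi2: float, df: int, n: int) -> float:
    """Root mean square error of approximation.

    ``sqrt(max(chi2 - df, 0) / (df * n))``; values below 0.08 are
    conventionally read as acceptable fit.
    """
    if df <= 0:
        raise ValueError("df must be positive")
    if n <= 1:
        raise ValueError("n must exceed 1")
    return float(np.sqrt(max(chi2 - df, 0.0) / (df * n)))


def cfi(chi2_model: float, df_model: int, chi2_baseline: float, df_baseline: int) -> float:
    """Comparative fit index against the independence baseline.

    Clipped into [0, 1]; equals 1 when the model chi-square does not
    exceed its degrees of freedom.
    """
    num = max(chi2_model - df_model, 0.0)
    den = max(chi2_baseline - df_baseline, num, 0.0)
    if den == 0.0:
        return 1.0
    return float(np.clip(1.0 - num / den, 0.0, 1.0))


def srmr(observed, implied, include_means: bool = False) -> float:
    """Standardized root mean square residual.

    ``observed`` / ``implied`` are either covariance matrices or
    ``(mean, covariance)`` tuples.  Covariance residuals are standardized
    by ``sqrt(s_jj * s_kk)`` over the lower triangle including the
    diagonal; with ``include_means`` the mean residuals (standardized by
    ``sqrt(s_jj)``) are pooled in as well.
    """
    def _split(x):
        if isinstance(x, (tuple, list)):
            return np.asarray(x[0], float), np.asarray(x[1], float)
        return None, np.asarray(x, float)

    m_o, s_o = _split(observed)
    m_i, s_i = _split(implied)
    if s_o.shape != s_i.shape:
        raise ValueError("moment dimensions do not match")
    d = np.sqrt(np.diag(s_o))
    if np.any(d <= 0):
        raise ValueError("observed covariance must have a positive diagonal")
    idx = np.tril_indices_from(s_o)
    resid = (s_o - s_i)[idx] / np.outer(d, d)[idx]
    cells = list(resid**2)
    if include_means:
        if m_o is None or m_i is None:
            raise ValueError("means required when include_means=True")
        cells += list(((m_o - m_i) / d) ** 2)
    return float(np.sqrt(np.mean(cells)))


def information_criteria(loglik: float, n_free_params: int, n: int):
    """(AIC, BIC) from the maximized log-likelihood."""
    if n <= 0:
        raise ValueError("n must be positive")
    aic = -2.0 * loglik + 2.0 * n_free_params
    bic = -2.0 * loglik + n_free_params * np.log(n)
    return float(aic), float(bic)


@dataclass
class FitIndices:
    chi2: float
    df: int
    rmsea: float
    cfi: float
    srmr: float
    aic: float
    bic: float


def mvn_em(y: np.ndarray, max_iter: int = 200, tol: float = 1e-8):
    """ML mean/covariance of a multivariate normal with missing data.

    Standard EM over the missingness patterns; rows with no observed
    entries are ignored.  Returns ``(mean, cov, loglik)``.
    """
    y = np.asarray(y, float)
    obs = np.isfinite(y)
    keep = obs.any(axis=1)
    y, obs = y[keep], obs[keep]
    n, p = y.shape
    mu = np.array([np.nanmean(y[:, j]) if obs[:, j].any() else 0.0 for j in range(p)])
    resid = np.where(obs, y - mu, 0.0)
    sigma = resid.T @ resid / n + np.eye(p) * 1e-3

    patterns = {}
    for i, row in enumerate(obs):
        patterns.setdefault(tuple(row), []).append(i)

    ll_old = -np.inf
    for _ in range(max_iter):
        s1 = np.zeros(p)
        s2 = np.zeros((p, p))
        ll = 0.0
        for key, idx in patterns.items():
            o = np.asarray(key)
            m = ~o
            idx = np.asarray(idx)
            yo = y[np.ix_(idx, np.where(o)[0])]
            soo = sigma[np.ix_(o, o)]
            c = np.linalg.cholesky(soo)
            w = np.linalg.inv(soo)
            r = yo - mu[o]
            alpha = r @ w
            ll += float(
                -0.5 * idx.size * (o.sum() * np.log(2 * np.pi) + 2 * np.sum(np.log(np.diag(c))))
                - 0.5 * np.einsum("np,np->", r, alpha)
            )
            yhat = np.zeros((idx.size, p))
            yhat[:, o] = yo
            cond_cov = np.zeros((p, p))
            if m.any():
                smo = sigma[np.ix_(m, o)]
                yhat[:, m] = mu[m] + alpha @ smo.T
                cond = sigma[np.ix_(m, m)] - smo @ w @ smo.T
                cond_cov[np.ix_(m, m)] = cond
            s1 += yhat.sum(axis=0)
            d = yhat - mu
            s2 += d.T @ d + idx.size * cond_cov
        mu_new = s1 / n
        shift = mu_new - mu
        sigma = s2 / n - np.outer(shift, shift)
        sigma = 0.5 * (sigma + sigma.T)
        mu = mu_new
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            break
        ll_old = ll
    return mu, sigma, ll


def _continuous_loglik(fit, data: TwoPartData, spec: GrowthSpec) -> float:
    """Normal marginal log-likelihood of the continuous part at the fit."""
    blank = TwoPartData(
        np.full_like(data.binary, np.nan), data.continuous, data.covariates,
        data.occasion_times, data.subject_ids, data.voxel,
    )
    return float(marginal_loglik(fit.params, blank, spec))


def compute_fit_indices(fit, data: TwoPartData, spec: GrowthSpec) -> FitIndices:
    """Global fit of a fitted two-part model.

    chi2 compares the continuous-part normal likelihood against
    unstructured saturated moments (EM over missingness patterns); the
    CFI baseline is the independence model (free means, diagonal
    covariance).  Covariate effects enter the model likelihood but not
    the saturated reference, so the indices are a heuristic summary
    rather than an exact likelihood-ratio geometry; AIC/BIC use the full
    two-part likelihood.
    """
    T = spec.n_occasions
    y = data.continuous
    mu_s, sig_s, ll_sat = mvn_em(y)
    # independence baseline: with a diagonal covariance, observed cells are
    # independent, so per-occasion moments are the exact ML solution
    ll_base = 0.0
    for t in range(T):
        yt = y[:, t]
        yt = yt[np.isfinite(yt)]
        if yt.size == 0:
            continue
        v = yt.var()
        ll_base += float(-0.5 * yt.size * (np.log(2 * np.pi * v) + 1.0))
    ll_model = _continuous_loglik(fit, data, spec)

    qc = spec.q_c
    k_cont = qc + qc * (qc + 1) // 2 + spec.n_theta + len(data.covariate_names)
    k_sat = T + T * (T + 1) // 2
    df = max(k_sat - k_cont, 1)
    df_base = max(k_sat - 2 * T, 1)
    chi2 = max(2.0 * (ll_sat - ll_model), 0.0)
    chi2_base = max(2.0 * (ll_sat - ll_base), 0.0)

    n = fit.n_subjects_used
    mean_i, cov_i = implied_moments(
        fit.params, spec,
        covariate_means=np.nanmean(data.covariate_matrix(), axis=0) if data.covariate_names else None,
        data=data,
    )
    aic, bic = information_criteria(fit.loglik, fit.n_free_params, n)
    return FitIndices(
        chi2=float(chi2),
        df=int(df),
        rmsea=rmsea(chi2, df, n),
        cfi=cfi(chi2, df, chi2_base, df_base),
        srmr=srmr((mu_s, sig_s), (mean_i, cov_i)),
        aic=aic,
        bic=bic,
    )
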