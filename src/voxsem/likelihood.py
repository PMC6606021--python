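"""Marginal likelihood of the two-part latent growth curve model.

For subject :math:`i` with latent factors :math:`\\eta = (\\eta_d, \\eta_c)`
the likelihood is

.. math::

    L_i = \\int \\prod_t \\mathrm{Bern}\\big(y^d_{it} \\mid g(\\Lambda^d_t
    \\eta_d)\\big) \\prod_{t \\in O_i} N\\big(y^c_{it} \\mid \\Lambda^c_t
    \\eta_c, \\theta_t\\big)\\, \\varphi(\\eta; m_i, \\Psi)\\, d\\eta ,

with missing cells dropping their factor (full-information ML under MAR;
structural zeros of the continuous part are treated the same way).
Covariates and the voxel predictor shift the mean of their target latent
factor.

The implementation marginalizes the continuous factors analytically
(they are jointly normal with the observed continuous indicators) and
integrates only over the discrete-part factors with Gauss--Hermite
quadrature centred and scaled by the conditional distribution of
:math:`\\eta_d` given the observed continuous data -- an adaptive rule
that collapses the integral from q dimensions to at most three.  A
non-adaptive full-dimension tensor-product rule is retained as an
independent oracle (:func:`loglik_bruteforce`).

The analytic gradient with respect to the unconstrained parameter vector
is propagated through the quadrature, including the dependence of the
node locations on the conditional moments.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import log_expit, expit, log_ndtr, logsumexp
from numpy.polynomial.hermite import hermgauss

from .growth import GrowthSpec, TwoPartData, TwoPartParams, ParamPacker

__all__ = ["marginal_loglik", "loglik_bruteforce", "implied_moments", "build_groups"]

_LOG2PI = np.log(2.0 * np.pi)
_LOGPI = np.log(np.pi)
_SQRT2 = np.sqrt(2.0)


@lru_cache(maxsize=32)
def _gh_grid(n_nodes: int, dim: int):
    """Tensor-product Gauss-Hermite nodes/log-weights for ``dim`` axes."""
    z1, w1 = hermgauss(n_nodes)
    grids = np.meshgrid(*([z1] * dim), indexing="ij")
    z = np.column_stack([g.ravel() for g in grids])
    logw = np.zeros(z.shape[0])
    lw1 = np.log(w1)
    for g in np.meshgrid(*([lw1] * dim), indexing="ij"):
        logw += g.ravel()
    return z, logw


def build_groups(data: TwoPartData):
    """Group subjects by their continuous-missingness pattern.

    The conditional covariance of the discrete factors given the
    continuous data depends only on which occasions are observed, so all
    decompositions are shared within a group.
    """
    cobs = np.isfinite(data.continuous)
    keys = [tuple(row) for row in cobs]
    groups = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    out = []
    for key, idx in groups.items():
        idx = np.asarray(idx)
        oc = np.asarray(key, dtype=bool)
        yc = data.continuous[idx][:, oc]
        b = data.binary[idx]
        bmask = np.isfinite(b).astype(float)
        sgn = np.where(bmask > 0, 2.0 * np.nan_to_num(b) - 1.0, 0.0)
        out.append({"idx": idx, "oc": oc, "yc": yc, "bmask": bmask, "sgn": sgn})
    return out


def _log_link(x, link):
    if link == "logit":
        return log_expit(x)
    return log_ndtr(x)


def _dlog_link(x, link):
    """d/dx log g(x) for the symmetric links."""
    if link == "logit":
        return expit(-x)
    # phi(x) / Phi(x), computed stably in the log domain
    logpdf = -0.5 * (x**2 + _LOG2PI)
    return np.exp(logpdf - log_ndtr(x))


def _subject_means(params: TwoPartParams, data: TwoPartData, spec: GrowthSpec):
    n = data.n_subjects
    m = np.tile(params.mu, (n, 1))
    X = data.covariate_matrix()
    fidx = spec.resolve_covariate_paths(data.covariate_names) if X.shape[1] else np.zeros(0, int)
    for j in range(X.shape[1]):
        m[:, fidx[j]] += params.gamma[j] * X[:, j]
    if params.beta_voxel is not None and data.voxel is not None:
        m[:, spec.factor_index(spec.predictor_target)] += params.beta_voxel * data.voxel
    return m, X, fidx


def _logsumexp_rows(a):
    """Row-wise logsumexp without scipy's array-api dispatch overhead."""
    m = a.max(axis=-1)
    return m + np.log(np.exp(a - m[..., None]).sum(axis=-1))


def marginal_loglik(
    params: TwoPartParams,
    data: TwoPartData,
    spec: GrowthSpec,
    n_quad: int = 15,
    grad: bool = False,
    per_subject: bool = False,
    score: bool = False,
    packer: ParamPacker | None = None,
    x_packed: np.ndarray | None = None,
    groups=None,
):
    """Marginal log-likelihood (and optionally its gradient / scores).

    Returns the total log-likelihood; with ``grad=True`` additionally the
    gradient with respect to the unconstrained parameter vector, with
    ``score=True`` the per-subject gradient matrix instead.  A non-finite
    value (returned as ``-inf`` when the assembled latent covariance is
    not positive definite) flags an infeasible point to the caller.

    The conditional-moment algebra is organized per continuous
    missingness pattern, but all quadrature-node evaluations run in one
    batch over subjects so the cost stays linear with small constants.
    """
    qd, qc, T = spec.q_d, spec.q_c, spec.n_occasions
    Ld = spec.loadings_discrete
    Lc = spec.loadings_continuous
    th = params.theta_full(spec)
    psi = params.psi
    # infeasible covariance -> flag
    try:
        ev_min = np.min(np.linalg.eigvalsh(psi))
    except np.linalg.LinAlgError:
        ev_min = -np.inf
    want_any_grad = grad or score
    if ev_min < -1e-10:
        ll = -np.inf
        if want_any_grad:
            k = packer.n_params if packer is not None else 0
            z = np.zeros((data.n_subjects, k)) if score else np.zeros(k)
            return ll, z
        return ll

    if groups is None:
        groups = build_groups(data)
    psi_dd = psi[:qd, :qd]
    psi_dc = psi[:qd, qd:]
    psi_cc = psi[qd:, qd:]
    m_all, X, fidx = _subject_means(params, data, spec)

    n = data.n_subjects
    ll_i = np.zeros(n)
    z_nodes, logw = _gh_grid(n_quad, qd)
    K = z_nodes.shape[0]

    b = data.binary
    bfin = np.isfinite(b)
    any_binary = bool(bfin.any())
    bmask = bfin.astype(float)
    sgn = np.where(bfin, 2.0 * np.nan_to_num(b) - 1.0, 0.0)

    # per-group conditional moments; node shifts differ only by group
    mt_all = np.empty((n, qd))
    lps = np.empty((len(groups), K, T))
    feasible = True
    cache = []
    for gi, grp in enumerate(groups):
        idx = grp["idx"]
        oc = grp["oc"]
        p = int(oc.sum())
        m_d = m_all[idx, :qd]
        m_c = m_all[idx, qd:]
        if p > 0:
            Lo = Lc[oc]  # (p, qc)
            V = Lo @ psi_cc @ Lo.T + np.diag(th[oc])
            try:
                cf = cho_factor(V, lower=True)
            except np.linalg.LinAlgError:
                feasible = False
                break
            logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
            W = cho_solve(cf, np.eye(p))
            r = grp["yc"] - m_c @ Lo.T
            alpha = r @ W
            llm = -0.5 * (p * _LOG2PI + logdet + np.einsum("np,np->n", r, alpha))
            G = psi_dc @ Lo.T  # (qd, p)
            GW = G @ W
            mt = m_d + alpha @ G.T
            Pt = psi_dd - GW @ G.T
        else:
            Lo = W = alpha = GW = None
            llm = np.zeros(idx.size)
            mt = m_d
            Pt = psi_dd
        try:
            Lt = np.linalg.cholesky(Pt + 1e-12 * np.eye(qd))
        except np.linalg.LinAlgError:
            feasible = False
            break
        mt_all[idx] = mt
        lps[gi] = (_SQRT2 * (z_nodes @ Lt.T)) @ Ld.T
        ll_i[idx] = llm
        cache.append({"idx": idx, "oc": oc, "p": p, "Lo": Lo, "W": W,
                      "alpha": alpha, "GW": GW, "Lt": Lt})

    if feasible and any_binary:
        gid = np.empty(n, dtype=int)
        for gi, grp in enumerate(groups):
            gid[grp["idx"]] = gi
        lp = mt_all @ Ld.T  # (n, T)
        lp = lp[:, None, :] + lps[gid]  # (n, K, T)
        xlin = sgn[:, None, :] * lp
        logB = (_log_link(xlin, spec.link) * bmask[:, None, :]).sum(axis=2)
        wk = logw[None, :] + logB
        lse = _logsumexp_rows(wk)
        ll_i += lse - (qd / 2.0) * _LOGPI

    if feasible and want_any_grad:
        dmu_i = np.zeros((n, spec.q))
        dpsi_i = np.zeros((n, spec.q, spec.q))
        dth_i = np.zeros((n, T))
        if any_binary:
            pk = np.exp(wk - lse[:, None])  # (n, K)
            u = sgn[:, None, :] * _dlog_link(xlin, spec.link) * bmask[:, None, :]
            dk = u @ Ld  # (n, K, qd)
            g1_all = np.einsum("nk,nka->na", pk, dk)
            G2_all = _SQRT2 * np.einsum("nk,nka,kb->nab", pk, dk, z_nodes)
        else:
            g1_all = np.zeros((n, qd))
            G2_all = np.zeros((n, qd, qd))
        di = np.arange(qd)
        for c in cache:
            idx, oc, p = c["idx"], c["oc"], c["p"]
            Lt = c["Lt"]
            g1 = g1_all[idx]
            M = np.einsum("ba,nbc->nac", Lt, G2_all[idx])  # L^T G2
            Phi = np.tril(M)
            Phi[:, di, di] *= 0.5
            Linv = np.linalg.inv(Lt)
            # P = L^{-T} Phi^T L^{-1}  (trace convention for dPsi~)
            P = np.einsum("ba,ncb,cd->nad", Linv, Phi, Linv)
            dmu_i[idx, :qd] = g1
            dpsi_i[idx, :qd, :qd] += P
            if p > 0:
                Lo, W, alpha, GW = c["Lo"], c["W"], c["alpha"], c["GW"]
                b1 = g1 @ GW  # (ng, p) == (W G^T g1)^T
                dmu_i[idx, qd:] = (alpha - b1) @ Lo
                # dPsi_dc via dG = -(P + P^T) G W + g1 alpha^T, then (dG) Lo
                PT = P + np.transpose(P, (0, 2, 1))
                A1 = -np.einsum("nab,bp->nap", PT, GW) + np.einsum("na,np->nap", g1, alpha)
                dpsi_i[idx, :qd, qd:] += np.einsum("nap,pc->nac", A1, Lo)
                # dV accumulation (trace convention)
                Mv = (
                    0.5 * (np.einsum("np,nq->npq", alpha, alpha) - W[None, :, :])
                    - np.einsum("np,nq->npq", b1, alpha)
                    + np.einsum("ap,nba,bq->npq", GW, P, GW)
                )
                Ms = 0.5 * (Mv + np.transpose(Mv, (0, 2, 1)))
                dpsi_i[idx, qd:, qd:] += np.einsum("pa,npq,qb->nab", Lo, Ms, Lo)
                dth_i[np.ix_(idx, np.where(oc)[0])] += Ms[:, np.arange(p), np.arange(p)]

    if not feasible or not np.all(np.isfinite(ll_i)):
        ll = -np.inf
        if want_any_grad:
            k = packer.n_params if packer is not None else 0
            zret = np.zeros((n, k)) if score else np.zeros(k)
            return ll, zret
        return ll

    ll = ll_i.sum()
    if per_subject and not want_any_grad:
        return ll_i
    if not want_any_grad:
        return ll

    # chain covariate / voxel shifts from the per-subject mean gradient
    if X.shape[1]:
        dgamma_i = dmu_i[:, fidx] * X
    else:
        dgamma_i = np.zeros((n, 0))
    if params.beta_voxel is not None and data.voxel is not None:
        dbeta_i = dmu_i[:, spec.factor_index(spec.predictor_target)] * data.voxel
    else:
        dbeta_i = None

    if packer is None:
        packer = ParamPacker(spec, X.shape[1], params.beta_voxel is not None)
    if x_packed is None:
        x_packed = packer.pack(params)
    g = packer.pack_grad(x_packed, dmu_i, dpsi_i, dth_i, dgamma_i, dbeta_i)
    if score:
        return ll, g
    return ll, g.sum(axis=0)


def loglik_bruteforce(
    params: TwoPartParams,
    data: TwoPartData,
    spec: GrowthSpec,
    n_nodes: int = 40,
    max_subjects: int = 10,
    chunk: int = 400_000,
) -> float:
    """Reference log-likelihood by non-adaptive tensor-product quadrature.

    Evaluates the full integral over *all* latent factors jointly on a
    prior-standardized Gauss-Hermite grid with ``n_nodes`` points per
    dimension, with no analytic factorization.  Intended as a slow,
    independent oracle on toy problems only.
    """
    if data.n_subjects > max_subjects:
        raise ValueError(f"brute force limited to {max_subjects} subjects")
    if spec.q > 4:
        raise ValueError("brute force limited to 4 latent dimensions")
    if n_nodes < 40:
        raise ValueError("brute force requires at least 40 nodes per dimension")

    qd, T = spec.q_d, spec.n_occasions
    Ld = spec.loadings_discrete
    Lc = spec.loadings_continuous
    th = params.theta_full(spec)
    m_all, _, _ = _subject_means(params, data, spec)

    # eigen factor of Psi; zero-variance directions are dropped so the
    # degenerate (deterministic-latent) limit is covered exactly
    evals, evecs = np.linalg.eigh(params.psi)
    if np.min(evals) < -1e-10:
        raise ValueError("psi must be positive semidefinite")
    keep = evals > 1e-12
    A = evecs[:, keep] * np.sqrt(evals[keep])  # (q, q_eff)
    q_eff = A.shape[1]

    if q_eff == 0:
        zg = np.zeros((1, 0))
        logw = np.zeros(1)
    else:
        zg, logw = _gh_grid(n_nodes, q_eff)
    logw = logw - (q_eff / 2.0) * _LOGPI

    total = 0.0
    for i in range(data.n_subjects):
        b = data.binary[i]
        c = data.continuous[i]
        bobs = np.isfinite(b)
        cobs = np.isfinite(c)
        if not bobs.any() and not cobs.any():
            continue
        acc = []
        for s in range(0, zg.shape[0], chunk):
            z = zg[s : s + chunk]
            eta = m_all[i][None, :] + _SQRT2 * z @ A.T  # (m, q)
            logf = np.zeros(z.shape[0])
            if bobs.any():
                lp = eta[:, :qd] @ Ld[bobs].T
                sgn = 2.0 * b[bobs] - 1.0
                logf += _log_link(sgn[None, :] * lp, spec.link).sum(axis=1)
            if cobs.any():
                mu_c = eta[:, qd:] @ Lc[cobs].T
                resid = c[cobs][None, :] - mu_c
                logf += (
                    -0.5 * (_LOG2PI + np.log(th[cobs]))[None, :]
                    - 0.5 * resid**2 / th[cobs][None, :]
                ).sum(axis=1)
            acc.append(logsumexp(logw[s : s + chunk] + logf))
        total += logsumexp(np.asarray(acc))
    return float(total)


def implied_moments(
    params: TwoPartParams,
    spec: GrowthSpec,
    covariate_means: np.ndarray | None = None,
    data: TwoPartData | None = None,
):
    """Model-implied mean and covariance of the continuous indicators.

    mean = Lambda_c mu_c (plus the average covariate shift if covariate
    means are supplied), covariance = Lambda_c Psi_cc Lambda_c' +
    diag(theta).
    """
    qd = spec.q_d
    Lc = spec.loadings_continuous
    mu_c = params.mu[qd:].copy()
    if covariate_means is not None and data is not None:
        fidx = spec.resolve_covariate_paths(data.covariate_names)
        for j, mbar in enumerate(np.atleast_1d(covariate_means)):
            if fidx[j] >= qd:
                mu_c[fidx[j] - qd] += params.gamma[j] * mbar
    mean = Lc @ mu_c
    cov = Lc @ params.psi[qd:, qd:] @ Lc.T + np.diag(params.theta_full(spec))
    return mean, cov
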