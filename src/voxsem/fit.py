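"""Maximum-likelihood estimation of the two-part growth model.

Quasi-Newton optimization (L-BFGS-B with the analytic gradient) on the
unconstrained parameterization, with moment-based automatic starting
values and a small multi-start around them.  Standard errors come from
the inverse observed information (numerical Hessian of the negative
log-likelihood built from central differences of the analytic gradient),
delta-method-mapped to the structured scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logit, ndtri
from scipy.stats import norm

from .growth import GrowthSpec, TwoPartData, TwoPartParams, ParamPacker
from .likelihood import marginal_loglik, build_groups

__all__ = ["FitOptions", "FitResult", "fit_model", "standard_errors", "wald_test"]

log = logging.getLogger(__name__)


@dataclass
class FitOptions:
    n_starts: int = 3
    jitter: float = 0.1
    seed: int = 20190702
    n_quad: int = 15
    gtol: float = 1e-5
    ftol: float = 1e-11
    maxiter: int = 1000
    compute_se: bool = True
    se_method: str = "hessian"  # or "opg"


@dataclass
class FitResult:
    params: TwoPartParams
    loglik: float
    converged: bool
    n_subjects_used: int
    n_free_params: int
    se: dict | None
    gradient_norm: float
    spec: GrowthSpec
    x_packed: np.ndarray
    cov_packed: np.ndarray | None = None
    n_iter: int = 0
    messages: list = field(default_factory=list)
    covariate_names: tuple = ()

    def param_dict(self) -> dict:
        return self.params.as_dict(self.spec, self.covariate_names)

    def summary(self) -> dict:
        out = {
            "loglik": self.loglik,
            "converged": self.converged,
            "n_subjects": self.n_subjects_used,
            "n_free_params": self.n_free_params,
            "gradient_norm": self.gradient_norm,
            "estimates": self.param_dict(),
        }
        if self.se is not None:
            out["se"] = self.se
        if self.messages:
            out["messages"] = list(self.messages)
        return out


def _auto_init(data: TwoPartData, spec: GrowthSpec) -> TwoPartParams:
    """Moment-based starting values from occasion-wise margins."""
    qd, qc, T = spec.q_d, spec.q_c, spec.n_occasions
    Ld, Lc = spec.loadings_discrete, spec.loadings_continuous
    b, c = data.binary, data.continuous

    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        p_t = np.nanmean(np.where(np.isfinite(b), b, np.nan), axis=0)
        cm = np.nanmean(np.where(np.isfinite(c), c, np.nan), axis=0)
        cv = np.nanvar(np.where(np.isfinite(c), c, np.nan), axis=0)
    p_t = np.clip(np.nan_to_num(p_t, nan=0.5), 0.02, 0.98)
    inv = logit if spec.link == "logit" else ndtri
    mu_d, *_ = np.linalg.lstsq(Ld, inv(p_t), rcond=None)

    cm = np.nan_to_num(cm, nan=0.0)
    cv = np.nan_to_num(cv, nan=1.0)
    cv = np.clip(cv, 1e-3, None)
    mu_c, *_ = np.linalg.lstsq(Lc, cm, rcond=None)

    theta0 = float(np.clip(0.5 * np.mean(cv), 1e-3, None))
    var_d = np.array([0.3, 0.1, 0.05])[:qd]
    var_c = np.concatenate([[max(cv[0] - theta0, 0.1)], [0.05, 0.02][: qc - 1]])
    mu = np.concatenate([mu_d, mu_c])
    psi = np.diag(np.concatenate([var_d, var_c]))
    theta = np.full(spec.n_theta, theta0)
    gamma = np.zeros(len(data.covariate_names))
    beta = 0.0 if data.voxel is not None else None
    return TwoPartParams(mu, psi, theta, gamma, beta)


def fit_model(
    data: TwoPartData,
    spec: GrowthSpec,
    init: TwoPartParams | str = "auto",
    options: FitOptions | None = None,
) -> FitResult:
    """Fit the two-part growth model by maximum likelihood.

    ``init="auto"`` derives starting values from occasion-wise logit /
    linear moments; any :class:`TwoPartParams` may be passed instead
    (e.g. a warm start from a previous fit).  The best solution over the
    multi-start is returned; the fit is deterministic given the seed.
    """
    options = options or FitOptions()
    data.validate()
    spec.check_identification()
    groups = build_groups(data)
    n_used = int(
        np.sum(np.isfinite(data.binary).any(axis=1) | np.isfinite(data.continuous).any(axis=1))
    )

    packer = ParamPacker(spec, len(data.covariate_names), data.voxel is not None)
    if isinstance(init, str):
        if init != "auto":
            raise ValueError("init must be 'auto' or TwoPartParams")
        p0 = _auto_init(data, spec)
    else:
        p0 = init.copy()
        if data.voxel is not None and p0.beta_voxel is None:
            p0.beta_voxel = 0.0
        if p0.gamma.size != len(data.covariate_names):
            p0.gamma = np.zeros(len(data.covariate_names))
    x0 = packer.pack(p0)

    def objective(x):
        ll, g = marginal_loglik(
            packer.unpack(x), data, spec, n_quad=options.n_quad, grad=True,
            packer=packer, x_packed=x, groups=groups,
        )
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(x)
        return -ll, -g

    rng = np.random.default_rng(options.seed)
    starts = [x0]
    for _ in range(options.n_starts - 1):
        starts.append(x0 + rng.normal(0.0, options.jitter * (np.abs(x0) + 0.1)))

    best = None
    n_iter = 0
    for k, xs in enumerate(starts):
        res = minimize(
            objective, xs, jac=True, method="L-BFGS-B", bounds=packer.bounds(),
            options={"maxiter": options.maxiter, "gtol": options.gtol,
                     "ftol": options.ftol, "maxls": 60, "maxcor": 20},
        )
        n_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res
    res = best

    gnorm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success) and bool(np.isfinite(res.fun))
    params = packer.unpack(res.x)
    messages = []
    if not converged:
        messages.append(f"optimizer did not converge: {res.message}")
    lo = np.array([b[0] if b[0] is not None else -np.inf for b in packer.bounds()])
    hi = np.array([b[1] if b[1] is not None else np.inf for b in packer.bounds()])
    at_bound = (res.x - lo < 1e-6) | (hi - res.x < 1e-6)
    if at_bound.any():
        names = np.asarray(packer.names(data.covariate_names))[at_bound]
        messages.append(f"parameters at boundary: {', '.join(names)}")
    labels = spec.factor_labels
    tiny = [labels[i] for i in range(spec.q) if params.psi[i, i] < 1e-6]
    if tiny:
        messages.append(f"latent variance at zero boundary: {', '.join(tiny)}")
    extreme = [labels[i] for i in range(spec.q_d) if abs(params.mu[i]) > 8.0]
    if extreme:
        messages.append(
            "discrete part degenerate: link-scale mean extreme for "
            + ", ".join(extreme)
        )

    fit = FitResult(
        params=params,
        loglik=float(-res.fun),
        converged=converged,
        n_subjects_used=n_used,
        n_free_params=packer.n_params,
        se=None,
        gradient_norm=gnorm,
        spec=spec,
        x_packed=res.x.copy(),
        n_iter=n_iter,
        messages=messages,
        covariate_names=data.covariate_names,
    )
    if options.compute_se and converged:
        try:
            fit.se = standard_errors(fit, data, spec, method=options.se_method,
                                     n_quad=options.n_quad, groups=groups)
        except np.linalg.LinAlgError:
            fit.messages.append("observed information not positive definite; SEs absent")
    return fit


def _numerical_hessian(fun_grad, x, h=1e-5):
    """Hessian by central differences of an analytic gradient."""
    k = x.size
    H = np.zeros((k, k))
    for j in range(k):
        step = h * max(1.0, abs(x[j]))
        xp = x.copy(); xp[j] += step
        xm = x.copy(); xm[j] -= step
        H[:, j] = (fun_grad(xp) - fun_grad(xm)) / (2.0 * step)
    return 0.5 * (H + H.T)


def standard_errors(
    fit: FitResult,
    data: TwoPartData,
    spec: GrowthSpec,
    method: str = "hessian",
    n_quad: int = 15,
    groups=None,
) -> dict:
    """Delta-method standard errors on the structured scale.

    ``method="hessian"`` inverts the observed information; ``"opg"`` uses
    the outer product of per-subject scores (one likelihood pass, used in
    the voxel-wise batch driver).  Raises ``LinAlgError`` when the
    information matrix is not positive definite; callers record the SEs
    as absent in that case.
    """
    if groups is None:
        groups = build_groups(data)
    packer = ParamPacker(spec, len(data.covariate_names), fit.params.beta_voxel is not None)
    x = fit.x_packed

    if method == "opg":
        _, S = marginal_loglik(
            packer.unpack(x), data, spec, n_quad=n_quad, score=True,
            packer=packer, x_packed=x, groups=groups,
        )
        info = S.T @ S
    else:
        def grad_neg(xv):
            _, g = marginal_loglik(
                packer.unpack(xv), data, spec, n_quad=n_quad, grad=True,
                packer=packer, x_packed=xv, groups=groups,
            )
            return -g
        info = _numerical_hessian(grad_neg, x)

    # positive-definiteness gate: Cholesky raises LinAlgError otherwise
    np.linalg.cholesky(info)
    cov = np.linalg.inv(info)
    fit.cov_packed = cov

    # delta method: Jacobian of the structured parameter vector wrt x
    def structured(xv):
        p = packer.unpack(xv)
        vals = [p.mu, np.diag(p.psi)]
        vals.append(np.array([p.psi[i, j] for i, j in packer.pairs]))
        vals.append(p.theta)
        vals.append(p.gamma)
        if packer.has_voxel:
            vals.append(np.array([p.beta_voxel]))
        return np.concatenate(vals)

    k = x.size
    J = np.zeros((k, k))
    for j in range(k):
        step = 1e-6 * max(1.0, abs(x[j]))
        xp = x.copy(); xp[j] += step
        xm = x.copy(); xm[j] -= step
        J[:, j] = (structured(xp) - structured(xm)) / (2.0 * step)
    var = np.einsum("ij,jk,ik->i", J, cov, J)
    se = np.sqrt(np.clip(var, 0.0, None))
    return dict(zip(packer.names(data.covariate_names), se))


def wald_test(estimate: float, se: float):
    """Wald z and two-sided normal p-value for a single coefficient."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = estimate / se
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)
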