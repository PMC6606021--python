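"""Model structure for the two-part latent growth curve model.

The model decomposes a semicontinuous repeated outcome into a binary
"any use" process and a continuous "score given use" process.  Each part
carries latent growth factors (intercept, slope, optionally a quadratic
term) whose joint distribution is multivariate normal.  This module holds
the declarative model specification (:class:`GrowthSpec`), the structured
parameter container (:class:`TwoPartParams`) and the bijective mapping
between structured parameters and the unconstrained vector used by the
optimizer (:class:`ParamPacker`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GrowthSpec",
    "TwoPartParams",
    "TwoPartData",
    "ParamPacker",
    "GROWTH_ORDERS",
]

GROWTH_ORDERS = {"intercept_only": 1, "linear": 2, "quadratic": 3}
_FACTORS_D = ("Id", "Sd", "Qd")
_FACTORS_C = ("Ic", "Sc", "Qc")

# variances are bounded away from 0/inf on the log scale so the optimizer
# can approach a zero-variance boundary without numerical collapse
LOG_VAR_MIN = np.log(1e-8)
LOG_VAR_MAX = np.log(1e8)


@dataclass(frozen=True)
class GrowthSpec:
    """Declarative structure of a two-part growth model.

    Parameters
    ----------
    n_occasions:
        Number of measurement occasions T.
    time_scores:
        Slope loadings per occasion (strictly increasing).  The default
        ``(0, 1, 2)`` is the conventional equal-interval coding for three
        waves; supply e.g. ``(0, 2.6, 4.6)`` for per-year slopes.
    growth_order_discrete, growth_order_continuous:
        ``"intercept_only"``, ``"linear"`` or ``"quadratic"``.
    link:
        Link for the binary part: ``"logit"`` (default) or ``"probit"``.
    covariate_paths:
        Mapping from covariate name to the latent factor it predicts.
        Covariates present in the data but not listed here default to the
        continuous slope ``"Sc"`` (nuisance covariates regress onto the
        slope of the continuous part).
    predictor_target:
        Latent factor that receives the voxel regression path
        (one of ``Id``, ``Sd``, ``Ic``, ``Sc``).
    equal_residuals:
        Constrain the continuous residual variance to be equal across
        occasions.
    psi_cross:
        Cross-part covariance structure: ``"intercepts"`` (default; only
        Cov(Id, Ic) free), ``"none"`` or ``"full"``.
    """

    n_occasions: int = 3
    time_scores: tuple = (0.0, 1.0, 2.0)
    growth_order_discrete: str = "linear"
    growth_order_continuous: str = "linear"
    link: str = "logit"
    covariate_paths: tuple = ()
    predictor_target: str = "Sc"
    equal_residuals: bool = False
    psi_cross: str = "intercepts"

    def __post_init__(self):
        if self.growth_order_discrete not in GROWTH_ORDERS:
            raise ValueError(f"unknown growth order {self.growth_order_discrete!r}")
        if self.growth_order_continuous not in GROWTH_ORDERS:
            raise ValueError(f"unknown growth order {self.growth_order_continuous!r}")
        if self.link not in ("logit", "probit"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.psi_cross not in ("none", "intercepts", "full"):
            raise ValueError(f"unknown psi_cross {self.psi_cross!r}")
        ts = tuple(float(t) for t in self.time_scores)
        object.__setattr__(self, "time_scores", ts)
        object.__setattr__(self, "covariate_paths", tuple(tuple(p) for p in self.covariate_paths))
        if len(ts) != self.n_occasions:
            raise ValueError("time_scores length must equal n_occasions")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("time_scores must be strictly increasing")
        if "quadratic" in (self.growth_order_discrete, self.growth_order_continuous):
            if self.n_occasions < 3:
                raise ValueError("quadratic growth requires at least 3 occasions")
        if self.predictor_target not in self.factor_labels:
            raise ValueError(
                f"predictor_target {self.predictor_target!r} not among factors {self.factor_labels}"
            )
        for name, fac in self.covariate_paths:
            if fac not in self.factor_labels:
                raise ValueError(f"covariate path {name!r} -> unknown factor {fac!r}")

    # --- derived structure -------------------------------------------------
    @property
    def q_d(self) -> int:
        return GROWTH_ORDERS[self.growth_order_discrete]

    @property
    def q_c(self) -> int:
        return GROWTH_ORDERS[self.growth_order_continuous]

    @property
    def q(self) -> int:
        return self.q_d + self.q_c

    @property
    def factor_labels(self) -> tuple:
        return _FACTORS_D[: self.q_d] + _FACTORS_C[: self.q_c]

    def _loadings(self, order: int) -> np.ndarray:
        t = np.asarray(self.time_scores)
        cols = [np.ones_like(t), t, t**2][:order]
        return np.column_stack(cols)

    @property
    def loadings_discrete(self) -> np.ndarray:
        """T x q_d loading matrix of the binary part."""
        return self._loadings(self.q_d)

    @property
    def loadings_continuous(self) -> np.ndarray:
        """T x q_c loading matrix of the continuous part."""
        return self._loadings(self.q_c)

    @property
    def n_theta(self) -> int:
        return 1 if self.equal_residuals else self.n_occasions

    def factor_index(self, label: str) -> int:
        return self.factor_labels.index(label)

    def free_psi_pairs(self) -> list:
        """Index pairs (i, j), i > j, of free latent covariances.

        All within-part covariances are free.  Cross-part covariances
        follow ``psi_cross``: only the intercept-intercept covariance by
        default, matching the covariances commonly reported for this
        model.
        """
        qd = self.q_d
        pairs = []
        for i in range(self.q):
            for j in range(i):
                within = (i < qd) == (j < qd)
                if within:
                    pairs.append((i, j))
                elif self.psi_cross == "full":
                    pairs.append((i, j))
                elif self.psi_cross == "intercepts":
                    if {self.factor_labels[i], self.factor_labels[j]} == {"Id", "Ic"}:
                        pairs.append((i, j))
        return pairs

    def resolve_covariate_paths(self, names: Sequence[str]) -> np.ndarray:
        """Factor index targeted by each covariate column."""
        mapping = dict(self.covariate_paths)
        idx = []
        for name in names:
            fac = mapping.get(name, "Sc" if "Sc" in self.factor_labels else self.factor_labels[-1])
            idx.append(self.factor_index(fac))
        return np.asarray(idx, dtype=int)

    def check_identification(self):
        """Raise if the spec is structurally non-identified.

        The continuous part must not carry more free parameters than the
        observed first and second moments of the T indicators; the binary
        part must not exceed the 2^T - 1 degrees of freedom of the joint
        binary table.
        """
        T = self.n_occasions
        qc = self.q_c
        n_cont = qc + qc * (qc + 1) // 2 + self.n_theta
        moments = T + T * (T + 1) // 2
        if n_cont > moments:
            raise ValueError(
                f"continuous part not identified: {n_cont} free parameters for "
                f"{moments} observed moments (df < 0)"
            )
        qd = self.q_d
        n_disc = qd + qd * (qd + 1) // 2
        if n_disc > 2**T - 1:
            raise ValueError(
                f"discrete part not identified: {n_disc} free parameters for "
                f"{2**T - 1} binary-table degrees of freedom"
            )


@dataclass
class TwoPartParams:
    """Structured parameters of the two-part growth model.

    Attributes
    ----------
    mu:
        Latent means, discrete factors first then continuous
        (e.g. ``(mu_Id, mu_Sd, mu_Ic, mu_Sc)`` for the default spec).
    psi:
        Full q x q latent covariance matrix (entries not freed by the
        spec are structurally zero).
    theta:
        Residual variances of the continuous indicators, one per
        occasion (or a single value under an equality constraint).
    gamma:
        Regression coefficients of the covariates onto their target
        factors, aligned with the covariate columns of the data.
    beta_voxel:
        Coefficient of the voxel predictor on the target factor, or
        ``None`` when no voxel predictor is in the model.
    """

    mu: np.ndarray
    psi: np.ndarray
    theta: np.ndarray
    gamma: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_voxel: float | None = None

    def __post_init__(self):
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.psi = np.asarray(self.psi, dtype=float)
        self.theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float)) if np.size(self.gamma) else np.zeros(0)

    def copy(self) -> "TwoPartParams":
        return TwoPartParams(
            self.mu.copy(), self.psi.copy(), self.theta.copy(), self.gamma.copy(),
            self.beta_voxel,
        )

    def validate(self, spec: GrowthSpec):
        if self.mu.shape != (spec.q,):
            raise ValueError(f"mu must have shape ({spec.q},)")
        if self.psi.shape != (spec.q, spec.q):
            raise ValueError(f"psi must have shape ({spec.q}, {spec.q})")
        if not np.allclose(self.psi, self.psi.T):
            raise ValueError("psi must be symmetric")
        if np.min(np.linalg.eigvalsh(self.psi)) < -1e-10:
            raise ValueError("psi must be positive semidefinite")
        if self.theta.shape[0] not in (1, spec.n_occasions):
            raise ValueError("theta must have one entry per occasion or a single entry")
        if np.any(self.theta <= 0):
            raise ValueError("residual variances must be positive")

    def theta_full(self, spec: GrowthSpec) -> np.ndarray:
        if self.theta.shape[0] == 1:
            return np.repeat(self.theta, spec.n_occasions)
        return self.theta

    def as_dict(self, spec: GrowthSpec, covariate_names: Sequence[str] = ()) -> dict:
        """Flat name -> value mapping (``mean.Sc``, ``psi.Ic_Sc``, ...)."""
        labels = spec.factor_labels
        out = {}
        for i, lab in enumerate(labels):
            out[f"mean.{lab}"] = float(self.mu[i])
        for i, lab in enumerate(labels):
            out[f"psi.{lab}_{lab}"] = float(self.psi[i, i])
        for i, j in spec.free_psi_pairs():
            out[f"psi.{labels[j]}_{labels[i]}"] = float(self.psi[i, j])
        for t, th in enumerate(self.theta):
            out[f"theta.{t}" if self.theta.shape[0] > 1 else "theta"] = float(th)
        for name, g in zip(covariate_names, self.gamma):
            out[f"gamma.{name}"] = float(g)
        if self.beta_voxel is not None:
            out["beta_voxel"] = float(self.beta_voxel)
        return out


@dataclass
class TwoPartData:
    """Two-part representation of a semicontinuous repeated outcome.

    ``binary`` and ``continuous`` are N x T arrays with ``nan`` coding
    missingness.  Data produced by the two-part decomposition satisfies:
    an observed continuous value has ``binary == 1`` at the same cell,
    ``binary == 0`` has a missing continuous cell (a structural zero),
    and a missing binary cell has a missing continuous cell.  The
    container itself only enforces the incompatible combination
    (``binary == 0`` with an observed continuous value), so that
    continuous-only submodels — binary entirely missing — remain
    expressible.
    """

    binary: np.ndarray
    continuous: np.ndarray
    covariates: "object | None" = None  # pandas DataFrame, optional
    occasion_times: np.ndarray | None = None
    subject_ids: np.ndarray | None = None
    voxel: np.ndarray | None = None

    def __post_init__(self):
        self.binary = np.asarray(self.binary, dtype=float)
        self.continuous = np.asarray(self.continuous, dtype=float)
        if self.binary.shape != self.continuous.shape:
            raise ValueError("binary and continuous must have the same shape")
        if self.occasion_times is not None:
            self.occasion_times = np.asarray(self.occasion_times, dtype=float)
        if self.subject_ids is None:
            self.subject_ids = np.arange(self.binary.shape[0])
        else:
            self.subject_ids = np.asarray(self.subject_ids)

    @property
    def n_subjects(self) -> int:
        return self.binary.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.binary.shape[1]

    @property
    def covariate_names(self) -> tuple:
        if self.covariates is None:
            return ()
        return tuple(self.covariates.columns)

    def covariate_matrix(self) -> np.ndarray:
        if self.covariates is None:
            return np.zeros((self.n_subjects, 0))
        return np.asarray(self.covariates, dtype=float)

    def validate(self):
        b, c = self.binary, self.continuous
        bad = set(np.unique(b[np.isfinite(b)])) - {0.0, 1.0}
        if bad:
            raise ValueError(f"binary entries must be 0/1/missing, found {sorted(bad)}")
        if np.any((b == 0) & np.isfinite(c)):
            raise ValueError("binary == 0 requires missing continuous value")
        if self.covariates is not None and len(self.covariates) != self.n_subjects:
            raise ValueError("covariate rows must align with subjects")
        if self.voxel is not None and len(self.voxel) != self.n_subjects:
            raise ValueError("voxel predictor must align with subjects")

    def with_voxel(self, values: np.ndarray) -> "TwoPartData":
        return TwoPartData(
            self.binary, self.continuous, self.covariates,
            self.occasion_times, self.subject_ids, np.asarray(values, dtype=float),
        )


def _tril_indices(q):
    return [(i, j) for i in range(q) for j in range(i + 1)]


class ParamPacker:
    """Bijection between structured parameters and an unconstrained vector.

    Layout: latent means (raw), latent covariance parameters, log
    residual variances, covariate coefficients (raw), voxel coefficient
    (raw).  The latent covariance is parameterized without constraints:

    * ``psi_cross="full"``: log-Cholesky of the whole matrix;
    * otherwise: log-Cholesky of the within-part blocks, plus (for
      ``"intercepts"``) the intercept-intercept cross covariance mapped
      by ``tanh`` onto its exact positive-definiteness bound
      ``|c| < 1 / sqrt([Psi_dd^-1]_00 [Psi_cc^-1]_00)`` given the blocks.

    Every unconstrained vector therefore maps to a valid covariance
    matrix and the optimizer never meets an infeasibility wall, even
    when the likelihood pushes a correlation towards +-1 (common for
    weakly identified slope factors).
    """

    def __init__(self, spec: GrowthSpec, n_covariates: int = 0, has_voxel: bool = False):
        self.spec = spec
        self.n_covariates = int(n_covariates)
        self.has_voxel = bool(has_voxel)
        self.pairs = spec.free_psi_pairs()
        q, qd, qc = spec.q, spec.q_d, spec.q_c
        self.full_chol = spec.psi_cross == "full"
        self.has_cross = spec.psi_cross == "intercepts"
        if self.full_chol:
            self._chol_idx = [_tril_indices(q)]
        else:
            self._chol_idx = [_tril_indices(qd), _tril_indices(qc)]
        n_psi = sum(len(ix) for ix in self._chol_idx) + int(self.has_cross)
        self.n_params = q + n_psi + spec.n_theta + self.n_covariates + int(self.has_voxel)
        self._s_mu = slice(0, q)
        o = q
        self._s_chol = []
        for ix in self._chol_idx:
            self._s_chol.append(slice(o, o + len(ix)))
            o += len(ix)
        self._i_cross = o if self.has_cross else None
        o += int(self.has_cross)
        self._s_logth = slice(o, o + spec.n_theta)
        o += spec.n_theta
        self._s_gamma = slice(o, o + self.n_covariates)
        o += self.n_covariates
        self._i_beta = o if self.has_voxel else None

    # ------------------------------------------------------------------
    def names(self, covariate_names: Sequence[str] = ()) -> list:
        labels = self.spec.factor_labels
        names = [f"mean.{l}" for l in labels]
        names += [f"psi.{l}_{l}" for l in labels]
        names += [f"psi.{labels[j]}_{labels[i]}" for i, j in self.pairs]
        if self.spec.n_theta == 1:
            names += ["theta"]
        else:
            names += [f"theta.{t}" for t in range(self.spec.n_theta)]
        cn = list(covariate_names) or [f"x{j}" for j in range(self.n_covariates)]
        names += [f"gamma.{c}" for c in cn]
        if self.has_voxel:
            names += ["beta_voxel"]
        return names

    # ------------------------------------------------------------------
    def _block_slices(self):
        """(offset, size) of each Cholesky block in the latent ordering."""
        if self.full_chol:
            return [(0, self.spec.q)]
        return [(0, self.spec.q_d), (self.spec.q_d, self.spec.q_c)]

    def _chols_from_x(self, x):
        """Lower-triangular block factors encoded in ``x``."""
        Ls = []
        for s, (off, sz) in zip(self._s_chol, self._block_slices()):
            L = np.zeros((sz, sz))
            vals = x[s]
            for v, (i, j) in zip(vals, _tril_indices(sz)):
                L[i, j] = np.exp(v) if i == j else v
            Ls.append(L)
        return Ls

    @staticmethod
    def _cross_bound(psi_dd, psi_cc):
        p1 = np.linalg.inv(psi_dd)[0, 0]
        p2 = np.linalg.inv(psi_cc)[0, 0]
        return 1.0 / np.sqrt(p1 * p2)

    def pack(self, params: TwoPartParams) -> np.ndarray:
        x = np.empty(self.n_params)
        x[self._s_mu] = params.mu
        qd = self.spec.q_d
        if self.full_chol:
            blocks = [params.psi]
        else:
            blocks = [params.psi[:qd, :qd], params.psi[qd:, qd:]]
        for s, B in zip(self._s_chol, blocks):
            try:
                L = np.linalg.cholesky(B)
            except np.linalg.LinAlgError as e:
                raise ValueError("latent covariance block is not positive definite") from e
            vals = [np.log(L[i, j]) if i == j else L[i, j] for i, j in _tril_indices(B.shape[0])]
            x[s] = vals
        if self.has_cross:
            bound = self._cross_bound(blocks[0], blocks[1])
            r = params.psi[0, qd] / bound
            x[self._i_cross] = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
        th = params.theta
        if th.shape[0] != self.spec.n_theta:
            if self.spec.n_theta == 1:
                th = np.array([float(np.mean(th))])
            else:
                th = np.repeat(th, self.spec.n_theta)[: self.spec.n_theta]
        x[self._s_logth] = np.log(th)
        x[self._s_gamma] = params.gamma if params.gamma.size else []
        if self.has_voxel:
            x[self._i_beta] = 0.0 if params.beta_voxel is None else params.beta_voxel
        return x

    def unpack(self, x: np.ndarray) -> TwoPartParams:
        q, qd = self.spec.q, self.spec.q_d
        mu = np.asarray(x[self._s_mu], dtype=float).copy()
        Ls = self._chols_from_x(x)
        psi = np.zeros((q, q))
        if self.full_chol:
            psi = Ls[0] @ Ls[0].T
        else:
            psi[:qd, :qd] = Ls[0] @ Ls[0].T
            psi[qd:, qd:] = Ls[1] @ Ls[1].T
            if self.has_cross:
                bound = self._cross_bound(psi[:qd, :qd], psi[qd:, qd:])
                c = np.tanh(x[self._i_cross]) * bound
                psi[0, qd] = psi[qd, 0] = c
        theta = np.exp(x[self._s_logth])
        gamma = np.asarray(x[self._s_gamma], dtype=float).copy()
        beta = float(x[self._i_beta]) if self.has_voxel else None
        return TwoPartParams(mu, psi, theta, gamma, beta)

    def bounds(self) -> list:
        """Optimizer box bounds (scale parameters kept in a sane range)."""
        b = [(None, None)] * self.n_params
        for s, (off, sz) in zip(self._s_chol, self._block_slices()):
            for k, (i, j) in zip(range(s.start, s.stop), _tril_indices(sz)):
                if i == j:
                    b[k] = (LOG_VAR_MIN / 2.0, LOG_VAR_MAX / 2.0)
        for k in range(self._s_logth.start, self._s_logth.stop):
            b[k] = (LOG_VAR_MIN, LOG_VAR_MAX)
        if self.has_cross:
            b[self._i_cross] = (-12.0, 12.0)
        return b

    # ------------------------------------------------------------------
    def pack_grad(self, x: np.ndarray, dmu, dpsi, dtheta, dgamma, dbeta):
        """Chain structured gradients through the unconstrained transform.

        ``dpsi`` uses the trace convention d(loglik) = tr(dpsi dPsi)
        accumulated on the full matrix.  Inputs may carry a leading
        subject axis, in which case per-subject packed gradients (score
        rows) are returned.
        """
        dmu = np.asarray(dmu)
        dpsi = np.asarray(dpsi)
        dtheta = np.asarray(dtheta)
        stacked = dmu.ndim == 2
        n = dmu.shape[0] if stacked else 1
        g = np.zeros((n, self.n_params))
        if not stacked:
            dmu, dpsi, dtheta = dmu[None], dpsi[None], dtheta[None]
            dgamma = None if dgamma is None else np.asarray(dgamma)[None]
            dbeta = None if dbeta is None else np.atleast_1d(dbeta)
        g[:, self._s_mu] = dmu

        q, qd = self.spec.q, self.spec.q_d
        Ls = self._chols_from_x(x)
        if self.full_chol:
            A_blocks = [dpsi]
        else:
            A_blocks = [dpsi[:, :qd, :qd].copy(), dpsi[:, qd:, qd:].copy()]
            if self.has_cross:
                psi_dd = Ls[0] @ Ls[0].T
                psi_cc = Ls[1] @ Ls[1].T
                t = np.tanh(x[self._i_cross])
                inv_dd = np.linalg.inv(psi_dd)
                inv_cc = np.linalg.inv(psi_cc)
                p1, p2 = inv_dd[0, 0], inv_cc[0, 0]
                bound = 1.0 / np.sqrt(p1 * p2)
                dc = dpsi[:, 0, qd] + dpsi[:, qd, 0]  # (n,)
                g[:, self._i_cross] = dc * bound * (1.0 - t**2)
                # the bound itself depends on the blocks:
                # d(bound)/dPsi_dd = (bound / (2 p1)) w0 w0^T, w0 = Psi_dd^-1 e0
                w0 = inv_dd[:, 0]
                w1 = inv_cc[:, 0]
                A_blocks[0] += (dc * t * bound / (2.0 * p1))[:, None, None] * np.outer(w0, w0)[None]
                A_blocks[1] += (dc * t * bound / (2.0 * p2))[:, None, None] * np.outer(w1, w1)[None]
        for s, L, A in zip(self._s_chol, Ls, A_blocks):
            sz = L.shape[0]
            GL = np.einsum("nab,bc->nac", A + np.transpose(A, (0, 2, 1)), L)
            for k, (i, j) in zip(range(s.start, s.stop), _tril_indices(sz)):
                g[:, k] = GL[:, i, j] * (L[i, i] if i == j else 1.0)

        th = np.exp(x[self._s_logth])
        if self.spec.n_theta == 1:
            g[:, self._s_logth] = dtheta.sum(axis=1, keepdims=True) * th
        else:
            g[:, self._s_logth] = dtheta * th
        if self.n_covariates and dgamma is not None:
            g[:, self._s_gamma] = dgamma
        if self.has_voxel and dbeta is not None:
            g[:, self._i_beta] = np.asarray(dbeta).reshape(n)
        return g if stacked else g[0]
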