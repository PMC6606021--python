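"""Mass-univariate voxel-wise fitting of the two-part growth model.

One structural equation model is fitted per voxel: the voxel's tissue
value enters as a predictor of a chosen latent growth factor (by default
the slope of the continuous part) alongside the nuisance covariates.
The regression estimate, its standard error, Wald z and two-sided p are
projected back into image space, and suprathreshold voxels are grouped
into connected clusters with an extent rule (classically p < 0.001 and
extent > 100 voxels).

Each voxel fit is warm-started from the voxel-free base fit; a voxel fit
is a pure function of (voxel values, base fit, spec), so results never
depend on processing order or scheduling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import nibabel as nib
from scipy import ndimage
from scipy.optimize import minimize
from scipy.stats import norm

from .growth import GrowthSpec, TwoPartData, ParamPacker
from .likelihood import (
    marginal_loglik, build_groups, _gh_grid, _log_link, _dlog_link,
    _subject_means, _SQRT2, _LOGPI,
)
from .fit import FitOptions, FitResult, fit_model

__all__ = [
    "BrainImageSet",
    "VoxelMapResult",
    "Cluster",
    "VoxelwiseOptions",
    "run_voxelwise",
    "threshold_clusters",
    "world_coordinates",
    "write_maps",
    "read_images",
    "cluster_table",
]

log = logging.getLogger(__name__)

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


@dataclass
class BrainImageSet:
    """Subject-aligned 3D tissue maps with a common affine and mask."""

    data: np.ndarray  # (n_subjects, X, Y, Z)
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("data must be (subjects, X, Y, Z)")
        if self.mask.shape != self.data.shape[1:]:
            raise ValueError("mask shape must match image dimensions")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]


@dataclass
class VoxelMapResult:
    """Voxel-wise regression statistics mapped into image space."""

    estimate: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    target: str
    n_converged: int
    n_skipped: int = 0


@dataclass
class Cluster:
    voxel_count: int
    peak_voxel: tuple
    peak_world_mm: tuple
    peak_z: float
    sign: str


@dataclass
class VoxelwiseOptions:
    """Options of the voxel-wise batch driver.

    ``refit="beta"`` (default) estimates the voxel coefficient by Fisher
    scoring with the remaining parameters held at the voxel-free base
    MLE — the standard mass-univariate shortcut; with z-scored voxels
    the coefficient is nearly orthogonal to the nuisance parameters, so
    it tracks the full joint refit closely (audited by a test).
    ``refit="full"`` re-optimizes every parameter per voxel,
    warm-started from the base fit.
    """

    scale_voxels: bool = True
    refit: str = "beta"
    n_quad: int = 15
    gtol: float = 1e-5
    maxiter: int = 200
    jobs: int = 1
    seed: int = 20190702
    chunk: int = 32


class _BetaScoring:
    """Batched Fisher scoring for the voxel coefficient.

    With all other parameters fixed at the base MLE, the voxel value
    only shifts the mean of the target latent factor, so the expensive
    conditional decompositions are shared across voxels and iterations;
    each scoring step evaluates the likelihood gradient for a whole
    chunk of voxels at once.  The standard error is the inverse square
    root of the per-subject score information at the optimum.
    """

    def __init__(self, data: TwoPartData, spec: GrowthSpec, params, n_quad: int, groups=None):
        self.spec = spec
        qd, qc, T = spec.q_d, spec.q_c, spec.n_occasions
        self.qd = qd
        Ld = spec.loadings_discrete
        Lc = spec.loadings_continuous
        th = params.theta_full(spec)
        psi = params.psi
        psi_dd, psi_dc, psi_cc = psi[:qd, :qd], psi[:qd, qd:], psi[qd:, qd:]
        groups = groups or build_groups(data)
        base = params.copy()
        base.beta_voxel = None
        m_all, _, _ = _subject_means(base, data, spec)
        n = data.n_subjects
        self.n = n
        self.Ld = Ld
        tgt = spec.factor_index(spec.predictor_target)
        self.tgt_discrete = tgt < qd
        self.tgt = tgt

        z, logw = _gh_grid(n_quad, qd)
        self.z, self.logw = z, logw
        self.link = spec.link

        b = data.binary
        bfin = np.isfinite(b)
        self.bmask = bfin.astype(float)
        self.sgn = np.where(bfin, 2.0 * np.nan_to_num(b) - 1.0, 0.0)

        self.groups = []
        self.lps = np.empty((len(groups), z.shape[0], T))
        gid = np.empty(n, dtype=int)
        self.mt0 = np.empty((n, qd))
        self.llm0 = np.zeros(n)
        for gi, grp in enumerate(groups):
            idx, oc = grp["idx"], grp["oc"]
            gid[idx] = gi
            p = int(oc.sum())
            m_d = m_all[idx, :qd]
            m_c = m_all[idx, qd:]
            if p > 0:
                Lo = Lc[oc]
                V = Lo @ psi_cc @ Lo.T + np.diag(th[oc])
                cf = np.linalg.cholesky(V)
                W = np.linalg.inv(V)
                logdet = 2.0 * np.sum(np.log(np.diag(cf)))
                r0 = grp["yc"] - m_c @ Lo.T
                G = psi_dc @ Lo.T
                GW = G @ W
                Pt = psi_dd - GW @ G.T
                const = -0.5 * (p * np.log(2 * np.pi) + logdet)
                lo_t = Lo[:, tgt - qd] if not self.tgt_discrete else None
            else:
                Lo = W = r0 = G = GW = lo_t = None
                Pt = psi_dd
                const = 0.0
            Lt = np.linalg.cholesky(Pt + 1e-12 * np.eye(qd))
            self.lps[gi] = (_SQRT2 * (z @ Lt.T)) @ Ld.T
            self.groups.append(
                {"idx": idx, "p": p, "Lo": Lo, "W": W, "r0": r0, "G": G,
                 "GW": GW, "m_d": m_d, "const": const, "lo_t": lo_t}
            )
        self.gid = gid

    def loglik_grad(self, beta: np.ndarray, V: np.ndarray):
        """(loglik, gradient, score information) per voxel in the chunk.

        ``beta`` is (B,), ``V`` is (B, n) of voxel values.
        """
        B, n = V.shape
        qd = self.qd
        K = self.z.shape[0]
        T = self.Ld.shape[0]
        mt = np.empty((B, n, qd))
        llm = np.zeros((B, n))
        for g in self.groups:
            idx, p = g["idx"], g["p"]
            if p > 0:
                r = g["r0"][None, :, :].copy()
                if not self.tgt_discrete:
                    s = beta[:, None] * V[:, idx]  # (B, ng)
                    r = r - s[:, :, None] * g["lo_t"][None, None, :]
                alpha = r @ g["W"]
                llm[:, idx] = g["const"] - 0.5 * np.einsum("bnp,bnp->bn", r, alpha)
                mt[:, idx] = g["m_d"][None] + alpha @ g["G"].T
                g["_alpha"] = alpha
            else:
                mt[:, idx] = g["m_d"][None]
                g["_alpha"] = None
            if self.tgt_discrete:
                mt[:, idx, self.tgt] += beta[:, None] * V[:, idx]
        lp = (mt @ self.Ld.T)[:, :, None, :] + self.lps[self.gid][None]  # (B, n, K, T)
        xlin = self.sgn[None, :, None, :] * lp
        logB = (_log_link(xlin, self.link) * self.bmask[None, :, None, :]).sum(axis=3)
        wk = self.logw[None, None, :] + logB
        m = wk.max(axis=2)
        pk = np.exp(wk - m[:, :, None])
        sk = pk.sum(axis=2)
        lse = m + np.log(sk)
        pk /= sk[:, :, None]
        ll = llm.sum(axis=1) + lse.sum(axis=1) - n * (qd / 2.0) * _LOGPI

        u = self.sgn[None, :, None, :] * _dlog_link(xlin, self.link) * self.bmask[None, :, None, :]
        dk = u @ self.Ld  # (B, n, K, qd)
        g1 = np.einsum("bnk,bnka->bna", pk, dk)
        scores = np.empty((B, n))
        if self.tgt_discrete:
            scores = g1[:, :, self.tgt] * V
        else:
            for g in self.groups:
                idx, p = g["idx"], g["p"]
                if p > 0:
                    t1 = g["_alpha"] - np.einsum("bna,ap->bnp", g1[:, idx], g["GW"])
                    scores[:, idx] = (t1 @ g["lo_t"]) * V[:, idx]
                else:
                    scores[:, idx] = 0.0
        grad = scores.sum(axis=1)
        info = (scores**2).sum(axis=1)
        return ll, grad, info

    def fit(self, V: np.ndarray, tol: float = 1e-6, maxiter: int = 40):
        """Fisher-scoring estimates for a chunk of voxels.

        Returns ``(beta, se, converged)`` arrays of length B.
        """
        B = V.shape[0]
        beta = np.zeros(B)
        done = np.zeros(B, dtype=bool)
        se = np.full(B, np.nan)
        g_prev = np.full(B, np.nan)
        b_prev = np.zeros(B)
        for it in range(maxiter):
            act = ~done
            if not act.any():
                break
            _, grad, info = self.loglik_grad(beta[act], V[act])
            ok = info > 0
            step = np.zeros_like(grad)
            step[ok] = grad[ok] / info[ok]
            if it > 0:
                # secant step on the score where it is better conditioned
                # than the score-information approximation to the curvature
                db = beta[act] - b_prev[act]
                dg = g_prev[act] - grad
                sec_ok = ok & (np.abs(dg) > 1e-12) & (db * dg > 0)
                step[sec_ok] = grad[sec_ok] * db[sec_ok] / dg[sec_ok]
            np.clip(step, -1.0, 1.0, out=step)
            b_prev[act] = beta[act]
            g_prev[act] = grad
            beta[act] += step
            se_act = np.full(step.shape, np.nan)
            se_act[ok] = 1.0 / np.sqrt(info[ok])
            se[act] = se_act
            newly = np.zeros(B, dtype=bool)
            newly[act] = (np.abs(step) < tol) | ~ok
            done |= newly
        return beta, se, done


def run_voxelwise(
    images: BrainImageSet,
    data: TwoPartData,
    spec: GrowthSpec,
    options: VoxelwiseOptions | None = None,
    base_fit: FitResult | None = None,
) -> VoxelMapResult:
    """Fit the model at every mask voxel and map the brain->factor path.

    The voxel-free base model is fitted first (it must converge; its
    failure aborts the run) and every voxel fit is warm-started from it
    with the voxel coefficient initialized at zero.  All model
    parameters are re-optimized per voxel.  Standard errors of the voxel
    coefficient come from the outer product of the per-subject scores at
    the voxel-wise optimum (one likelihood pass per voxel); constant
    voxels and non-converged voxels are missing-coded and counted.
    """
    options = options or VoxelwiseOptions()
    if images.n_subjects != data.n_subjects:
        raise ValueError(
            f"subject axis mismatch: {images.n_subjects} images vs "
            f"{data.n_subjects} behavioral records"
        )
    data.validate()
    if base_fit is None:
        base_fit = fit_model(
            data, spec,
            options=FitOptions(n_quad=options.n_quad, seed=options.seed, compute_se=False),
        )
    if not base_fit.converged:
        raise RuntimeError(f"base model did not converge: {base_fit.messages}")

    groups = build_groups(data)
    packer = ParamPacker(spec, len(data.covariate_names), has_voxel=True)
    x_warm = np.concatenate([base_fit.x_packed, [0.0]])
    i_beta = packer.n_params - 1
    bounds = packer.bounds()
    vdata = data.with_voxel(np.zeros(data.n_subjects))

    mask_idx = np.argwhere(images.mask)
    nvox = mask_idx.shape[0]
    est = np.full(nvox, np.nan)
    se = np.full(nvox, np.nan)
    n_conv = 0
    n_skip = 0

    flat_idx = np.ravel_multi_index(tuple(mask_idx.T), images.mask.shape)
    vox_mat = images.data.reshape(images.n_subjects, -1)[:, flat_idx]

    valid = np.ones(nvox, dtype=bool)
    sds = vox_mat.std(axis=0)
    valid &= np.isfinite(vox_mat).all(axis=0) & (sds > 1e-12)
    scaled = vox_mat.copy()
    if options.scale_voxels:
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = (vox_mat - vox_mat.mean(axis=0)) / sds
    n_skip += int((~valid).sum())

    if options.refit == "beta":
        engine = _BetaScoring(data, spec, base_fit.params, options.n_quad, groups=groups)
        vidx = np.where(valid)[0]
        for s in range(0, vidx.size, options.chunk):
            sel = vidx[s : s + options.chunk]
            betas, ses, conv = engine.fit(scaled[:, sel].T)
            ok = conv & np.isfinite(ses)
            est[sel[ok]] = betas[ok]
            se[sel[ok]] = ses[ok]
            n_conv += int(ok.sum())
            n_skip += int((~ok).sum())
        return _assemble_result(images, mask_idx, est, se, spec, n_conv, n_skip)
    if options.refit != "full":
        raise ValueError("refit must be 'beta' or 'full'")

    def fit_one(v):
        """Warm-started refit with the voxel predictor; returns (beta, se)."""
        vdata.voxel = v
        x0 = x_warm

        def obj(x):
            ll, g = marginal_loglik(
                packer.unpack(x), vdata, spec, n_quad=options.n_quad, grad=True,
                packer=packer, x_packed=x, groups=groups,
            )
            if not np.isfinite(ll):
                return 1e12, np.zeros_like(x)
            return -ll, -g

        res = minimize(
            obj, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": options.maxiter, "gtol": options.gtol, "ftol": 1e-12},
        )
        if not res.success:
            return None
        pv = packer.unpack(res.x)
        _, S = marginal_loglik(
            pv, vdata, spec, n_quad=options.n_quad, score=True,
            packer=packer, x_packed=res.x, groups=groups,
        )
        try:
            cov = np.linalg.inv(S.T @ S)
        except np.linalg.LinAlgError:
            return None
        var_b = cov[i_beta, i_beta]
        if var_b <= 0:
            return None
        return float(res.x[i_beta]), float(np.sqrt(var_b))

    vidx = np.where(valid)[0]
    if options.jobs > 1:
        # each voxel fit is a pure function of (voxel values, base fit,
        # spec), so parallel and serial schedules give identical maps
        from joblib import Parallel, delayed

        outs = Parallel(n_jobs=options.jobs)(
            delayed(fit_one)(scaled[:, k]) for k in vidx
        )
    else:
        outs = (fit_one(scaled[:, k]) for k in vidx)
    for k, out in zip(vidx, outs):
        if out is None:
            n_skip += 1
            continue
        est[k], se[k] = out
        n_conv += 1
    return _assemble_result(images, mask_idx, est, se, spec, n_conv, n_skip)


def _assemble_result(images, mask_idx, est, se, spec, n_conv, n_skip) -> VoxelMapResult:
    with np.errstate(invalid="ignore", divide="ignore"):
        z = est / se
        p = 2.0 * norm.sf(np.abs(z))

    shape = images.mask.shape

    def scatter(vals):
        vol = np.full(shape, np.nan)
        vol[tuple(mask_idx.T)] = vals
        return vol

    log.info("voxelwise run: %d voxels, %d converged, %d skipped",
             mask_idx.shape[0], n_conv, n_skip)
    return VoxelMapResult(
        estimate=scatter(est), se=scatter(se), z=scatter(z), p=scatter(p),
        affine=images.affine.copy(), mask=images.mask.copy(),
        target=spec.predictor_target, n_converged=n_conv, n_skipped=n_skip,
    )


def world_coordinates(peak_voxel, affine) -> tuple:
    """Voxel index -> world (mm) coordinates through the image affine."""
    affine = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError("affine is singular")
    hom = np.append(np.asarray(peak_voxel, dtype=float), 1.0)
    return tuple((affine @ hom)[:3])


def threshold_clusters(
    result: VoxelMapResult,
    p_thresh: float = 0.001,
    k_min: int = 100,
    connectivity: int = 26,
):
    """Suprathreshold map and clusters surviving the extent rule.

    Voxels with p < ``p_thresh`` are split by the sign of the estimate;
    connected components (6/18/26-neighbour) with strictly more than
    ``k_min`` voxels are retained, sorted by extent (descending).  The
    cluster peak is its maximum-|z| voxel.
    """
    if connectivity not in _CONNECTIVITY:
        raise ValueError("connectivity must be one of 6, 18, 26")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    with np.errstate(invalid="ignore"):
        supra = (result.p < p_thresh) & np.isfinite(result.p)
    thresholded = np.zeros(result.p.shape, dtype=np.int8)
    clusters = []
    for sign, s in (("positive", 1), ("negative", -1)):
        with np.errstate(invalid="ignore"):
            m = supra & (np.sign(result.estimate) == s)
        labels, n_lab = ndimage.label(m, structure=structure)
        for lab in range(1, n_lab + 1):
            comp = labels == lab
            count = int(comp.sum())
            if count <= k_min:
                continue
            zvals = np.where(comp, np.abs(result.z), -np.inf)
            peak = np.unravel_index(np.argmax(zvals), zvals.shape)
            clusters.append(
                Cluster(
                    voxel_count=count,
                    peak_voxel=tuple(int(i) for i in peak),
                    peak_world_mm=world_coordinates(peak, result.affine),
                    peak_z=float(result.z[peak]),
                    sign=sign,
                )
            )
            thresholded[comp] = s
    clusters.sort(key=lambda c: (-c.voxel_count, c.peak_voxel))
    return thresholded, clusters


def cluster_table(clusters) -> pd.DataFrame:
    """Cluster list as a tidy table (extent, peak ijk, peak mm, peak z)."""
    rows = []
    for c in clusters:
        rows.append(
            {
                "voxel_count": c.voxel_count,
                "peak_i": c.peak_voxel[0],
                "peak_j": c.peak_voxel[1],
                "peak_k": c.peak_voxel[2],
                "peak_x_mm": round(c.peak_world_mm[0], 6),
                "peak_y_mm": round(c.peak_world_mm[1], 6),
                "peak_z_mm": round(c.peak_world_mm[2], 6),
                "peak_z": round(c.peak_z, 6),
                "sign": c.sign,
            }
        )
    cols = ["voxel_count", "peak_i", "peak_j", "peak_k",
            "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_z", "sign"]
    return pd.DataFrame(rows, columns=cols)


def write_maps(result: VoxelMapResult, paths: dict):
    """Write estimate / se / z / p volumes as NIfTI-1 images.

    ``paths`` maps any of ``estimate``, ``se``, ``z``, ``p`` to file
    names; the input affine is preserved and out-of-mask voxels are nan.
    """
    for key, path in paths.items():
        vol = getattr(result, key)
        img = nib.Nifti1Image(np.asarray(vol, dtype=np.float32), result.affine)
        nib.save(img, str(path))


def read_images(paths, mask_path=None, atol: float = 1e-4) -> BrainImageSet:
    """Load per-subject volumes (or one 4D volume) into a BrainImageSet.

    All volumes must share shape and affine (tolerance ``atol``); a mask
    image restricts the analysis, otherwise all finite voxels are used.
    """
    paths = [paths] if isinstance(paths, (str,)) else list(paths)
    vols, affines = [], []
    for p in paths:
        img = nib.load(str(p))
        arr = np.asarray(img.get_fdata(), dtype=float)
        if arr.ndim == 4:
            vols.extend(np.moveaxis(arr, -1, 0))
            affines.extend([img.affine] * arr.shape[-1])
        else:
            vols.append(arr)
            affines.append(img.affine)
    shapes = {v.shape for v in vols}
    if len(shapes) > 1:
        raise ValueError(f"subject volumes have mismatched shapes: {sorted(shapes)}")
    bad = [i for i, a in enumerate(affines) if not np.allclose(a, affines[0], atol=atol)]
    if bad:
        raise ValueError(f"subject volumes with mismatched affines at indices: {bad}")
    data = np.stack(vols)
    if mask_path is not None:
        mimg = nib.load(str(mask_path))
        if mimg.shape != data.shape[1:]:
            raise ValueError("mask shape does not match subject volumes")
        if not np.allclose(mimg.affine, affines[0], atol=atol):
            raise ValueError("mask affine does not match subject volumes")
        mask = np.asarray(mimg.get_fdata()) > 0
    else:
        mask = np.all(np.isfinite(data), axis=0)
    return BrainImageSet(data=data, affine=np.asarray(affines[0]), mask=mask)
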