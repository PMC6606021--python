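"""Synthetic study generator with known ground truth.

Emulates the structure of a three-wave adolescent alcohol-use cohort:
zero-inflated questionnaire sum scores driven by two correlated latent
growth processes (a logistic any-use process and a normal
score-given-use process), occasion-level attrition, demographic
covariates with a sex effect on the continuous slope, and per-subject
3D "tissue" volumes consisting of a spatially smooth Gaussian random
field plus spherical regions whose intensity tracks the subject's true
continuous slope.

Default parameter magnitudes follow the published estimates for this
model class (latent means/variances/covariances of the order reported
for a ~1800-subject cohort); the discrete-part values are interpreted on
the link (logit) scale, which makes them magnitude-realistic rather than
a reproduction of any particular cohort.  Retention across the three
occasions defaults to the 1794 -> 1439 -> 1284 pattern of that cohort,
applied as missing-at-random whole-occasion dropout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit
from scipy.stats import norm

from .growth import GrowthSpec, TwoPartData, TwoPartParams
from .voxelwise import BrainImageSet

__all__ = [
    "SyntheticConfig",
    "default_true_params",
    "generate_trajectories",
    "generate_brain",
    "generate_study",
]

_SITES = 9
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def default_true_params() -> TwoPartParams:
    """Ground-truth parameters at published magnitudes.

    Order of latent factors: (Id, Sd, Ic, Sc).  Cross-part slope
    covariances are fixed at zero; the intercept-intercept covariance is
    0.124.  The residual variance (0.5) is a free choice, of the order
    of the slope variance.
    """
    mu = np.array([0.568, 0.188, 0.693, 0.498])
    psi = np.array(
        [
            [0.090, -0.033, 0.124, 0.000],
            [-0.033, 0.024, 0.000, 0.000],
            [0.124, 0.000, 0.618, -0.078],
            [0.000, 0.000, -0.078, 0.218],
        ]
    )
    theta = np.array([0.5, 0.5, 0.5])
    return TwoPartParams(mu, psi, theta, np.array([-0.183]))


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic cohort.

    ``gamma_sex`` acts on the continuous slope; retention rates are the
    per-occasion probabilities of contributing data.  ``effect_regions``
    is a list of ``(center, radius, beta)`` spheres (voxel units) whose
    signal is proportional to the subject's standardized true continuous
    slope.
    """

    n_subjects: int = 1794
    occasion_times: tuple = (0.0, 1.0, 2.0)
    true_params: TwoPartParams = field(default_factory=default_true_params)
    gamma_sex: float = -0.183
    retention: tuple = (1.0, 1439.0 / 1794.0, 1284.0 / 1794.0)
    covariates: str = "sex_only"  # "none" | "sex_only" | "full"
    link: str = "logit"
    image_dims: tuple = (16, 16, 16)
    effect_regions: tuple = ()  # ((cx,cy,cz), radius, beta)
    smoothing_fwhm: float = 3.0
    noise_sd: float = 0.5
    seed: int = 20190702

    def validate(self):
        psi = np.asarray(self.true_params.psi)
        if np.min(np.linalg.eigvalsh(psi)) < -1e-10:
            raise ValueError("true latent covariance must be positive semidefinite")
        if not all(0.0 <= r <= 1.0 for r in self.retention):
            raise ValueError("retention rates must lie in [0, 1]")
        for center, radius, _beta in self.effect_regions:
            c = np.asarray(center, dtype=float)
            if np.any(c - radius < 0) or np.any(c + radius > np.asarray(self.image_dims)):
                raise ValueError(f"effect region at {tuple(center)} (r={radius}) exceeds image dims")

    def spec(self) -> GrowthSpec:
        return GrowthSpec(
            n_occasions=len(self.occasion_times),
            time_scores=tuple(self.occasion_times),
            link=self.link,
        )


def _make_covariates(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame | None:
    n = config.n_subjects
    if config.covariates == "none":
        return None
    cols = {"sex": rng.binomial(1, 0.54, n).astype(float)}
    if config.covariates == "full":
        cols["age"] = rng.normal(14.4, 0.45, n)
        cols["tbv"] = rng.normal(1200.0, 110.0, n)
        site = rng.integers(0, _SITES, n)
        for s in range(1, _SITES):
            cols[f"site_{s}"] = (site == s).astype(float)
    return pd.DataFrame(cols)


def generate_trajectories(config: SyntheticConfig, seed: int | None = None):
    """Draw latent trajectories and the observed two-part data.

    Returns ``(TwoPartData, ground_truth)`` where the ground truth holds
    the drawn latent factors, the pre-attrition responses and the
    covariates.  Attrition removes whole occasions at random,
    independently of the outcomes (MAR).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_subjects
    tp = config.true_params
    lam = np.asarray(config.occasion_times, dtype=float)
    T = lam.size

    cov = _make_covariates(config, rng)
    eta = rng.multivariate_normal(tp.mu, tp.psi, size=n)
    if cov is not None and "sex" in cov:
        eta[:, 3] += config.gamma_sex * cov["sex"].to_numpy()

    lin_d = eta[:, [0]] + np.outer(eta[:, 1], lam)
    p_use = expit(lin_d) if config.link == "logit" else norm.cdf(lin_d)
    binary = (rng.random((n, T)) < p_use).astype(float)
    theta = tp.theta if tp.theta.size == T else np.repeat(tp.theta, T)
    cont = eta[:, [2]] + np.outer(eta[:, 3], lam) + rng.normal(0.0, np.sqrt(theta), (n, T))
    continuous = np.where(binary == 1, cont, np.nan)

    present = rng.random((n, T)) < np.asarray(config.retention)
    binary = np.where(present, binary, np.nan)
    continuous = np.where(present, continuous, np.nan)

    data = TwoPartData(
        binary, continuous, covariates=cov,
        occasion_times=lam, subject_ids=np.arange(n),
    )
    data.validate()
    truth = {
        "eta": eta,
        "p_use": p_use,
        "present": present,
        "covariates": cov,
        "config_seed": config.seed if seed is None else seed,
    }
    return data, truth


def generate_brain(config: SyntheticConfig, truth: dict, seed: int | None = None):
    """Per-subject volumes: smooth noise field plus planted slope signal.

    Each volume is an independent Gaussian random field (normalized to
    unit variance after smoothing to ``smoothing_fwhm`` voxels FWHM)
    plus white noise of sd ``noise_sd``; inside every effect sphere the
    subject's standardized true continuous slope is added with weight
    ``beta``.  Returns ``(BrainImageSet, region_masks)``.
    """
    config.validate()
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    n = config.n_subjects
    dims = tuple(int(d) for d in config.image_dims)
    sc = truth["eta"][:, 3]
    zslope = (sc - sc.mean()) / sc.std()

    sigma = config.smoothing_fwhm * _FWHM_TO_SIGMA
    vols = np.empty((n,) + dims)
    for i in range(n):
        f = gaussian_filter(rng.normal(size=dims), sigma, mode="wrap")
        f /= f.std() + 1e-12
        vols[i] = f
    if config.noise_sd > 0:
        vols += rng.normal(0.0, config.noise_sd, vols.shape)

    grid = np.indices(dims)
    region_masks = []
    for center, radius, beta in config.effect_regions:
        c = np.asarray(center, dtype=float)
        dist2 = sum((grid[a] - c[a]) ** 2 for a in range(3))
        m = dist2 <= radius**2
        region_masks.append(m)
        vols += beta * zslope[:, None, None, None] * m[None]

    affine = np.eye(4)
    images = BrainImageSet(data=vols, affine=affine, mask=np.ones(dims, dtype=bool))
    return images, region_masks


def generate_study(config: SyntheticConfig, outdir, seed: int | None = None) -> dict:
    """Full synthetic bundle on disk, in the formats the pipeline reads.

    Writes ``behaviour.csv`` (long format, one row per subject and
    occasion with the reconstructed sum score and covariates),
    ``images.nii`` (4D), ``mask.nii`` and ``truth.json``; returns the
    paths plus the in-memory objects.
    """
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data, truth = generate_trajectories(config, seed=seed)
    images, region_masks = generate_brain(config, truth, seed=seed)

    n, T = data.binary.shape
    rows = []
    for i in range(n):
        for t in range(T):
            b = data.binary[i, t]
            score = 0.0 if b == 0 else data.continuous[i, t]
            rows.append(
                {
                    "subject_id": int(data.subject_ids[i]),
                    "occasion": t,
                    "sum_score": np.nan if not np.isfinite(b) else score,
                }
            )
    beh = pd.DataFrame(rows)
    if data.covariates is not None:
        covs = data.covariates.copy()
        covs.insert(0, "subject_id", data.subject_ids)
        beh = beh.merge(covs, on="subject_id")
    beh_path = outdir / "behaviour.csv"
    beh.to_csv(beh_path, index=False)

    img_path = outdir / "images.nii"
    mask_path = outdir / "mask.nii"
    nib.save(nib.Nifti1Image(np.moveaxis(images.data, 0, -1).astype(np.float32), images.affine), img_path)
    nib.save(nib.Nifti1Image(images.mask.astype(np.uint8), images.affine), mask_path)

    truth_path = outdir / "truth.json"
    payload = {
        "eta": truth["eta"].tolist(),
        "present": truth["present"].astype(int).tolist(),
        "region_voxels": [np.argwhere(m).tolist() for m in region_masks],
        "config": _config_dict(config),
    }
    truth_path.write_text(json.dumps(payload))
    return {
        "behaviour": beh_path,
        "images": img_path,
        "mask": mask_path,
        "truth": truth_path,
        "data": data,
        "image_set": images,
        "region_masks": region_masks,
    }


def _config_dict(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    tp = d.pop("true_params")
    d["true_params"] = {k: np.asarray(v).tolist() if not np.isscalar(v) and v is not None else v
                        for k, v in tp.items()}
    d["effect_regions"] = [
        [list(map(float, c)), float(r), float(b)] for c, r, b in config.effect_regions
    ]
    return d
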