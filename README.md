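# voxsem

Voxel-wise structural equation modelling of zero-inflated longitudinal
outcomes: a two-part latent growth curve model fitted by maximum
likelihood at every voxel of the brain, with the voxel's tissue volume
predicting a latent growth factor and the resulting statistics mapped
back into image space and cluster-thresholded.

## Who this is for

Researchers relating baseline brain structure (modulated VBM grey- or
white-matter maps) to the *trajectory* of a semicontinuous behavioural
score — the motivating case is the AUDIT alcohol-use score (ten items,
sum 0–40, strongly zero-inflated in adolescents) measured at three
occasions. Classical mass-univariate GLMs cannot express "probability
of any use" and "intensity of use given use" as separate but correlated
growth processes; this package fits exactly that model, whole-brain,
on one CPU, and ships a synthetic-data generator so the full pipeline
is testable without access to restricted cohort data.

## The model

The score at occasion *t* is split into a binary any-use indicator and
a continuous score-given-use (zeros of the continuous part are treated
as missing at random). With slope loadings `λ_t` and latent factors
`(I_d, S_d, I_c, S_c)` per subject:

    y_d[t] ~ Bernoulli( logit⁻¹( I_d + λ_t S_d ) )
    y_c[t] = I_c + λ_t S_c + ε_t,    ε_t ~ N(0, θ_t)
    (I_d, S_d, I_c, S_c) ~ MVN(μ + covariate shifts, Ψ)

Nuisance covariates (sex, age, TBV, site dummies) and the per-voxel
brain value shift the mean of a chosen factor (default: the continuous
slope `S_c`). The likelihood integrates the latents out — continuous
factors analytically, discrete factors by adaptive Gauss–Hermite
quadrature — with full-information handling of missing cells, and is
maximized by L-BFGS-B with an exact analytic gradient. A brute-force
full-dimensional quadrature oracle, global fit indices (RMSEA / CFI /
SRMR), chi-square difference tests, cluster-extent thresholding
(p < 0.001, extent > 100, 26-connectivity by default) and NIfTI I/O are
included. See `docs/methods.md` for the complete account.

## Worked example

```python
from voxsem import (GrowthSpec, SyntheticConfig, FitOptions, fit_model, wald_test,
                    generate_trajectories, generate_brain, run_voxelwise,
                    threshold_clusters, VoxelwiseOptions, cluster_table)

# behavioural cohort at study size
cohort = SyntheticConfig(n_subjects=1794, seed=20190702)
data, _ = generate_trajectories(cohort)
spec = GrowthSpec()                      # linear growth, logit link, target S_c
base = fit_model(data, spec, options=FitOptions(n_starts=1))
est, se = base.param_dict(), base.se
for key in ("mean.Sd", "mean.Sc", "psi.Sc_Sc", "gamma.sex"):
    z, p = wald_test(est[key], se[key])
    print(f"{key:10s} {est[key]:+.3f} (SE {se[key]:.3f}, z = {z:+.2f})")

# voxel-wise study with a planted 147-voxel sphere in a 16^3 volume
vol = SyntheticConfig(n_subjects=200, image_dims=(16, 16, 16),
                      effect_regions=(((8, 8, 8), 3.2, 2.5),), seed=20190702)
vdata, truth = generate_trajectories(vol)
images, regions = generate_brain(vol, truth)
vbase = fit_model(vdata, spec, options=FitOptions(n_starts=1, compute_se=False, n_quad=5))
res = run_voxelwise(images, vdata, spec, VoxelwiseOptions(n_quad=5), base_fit=vbase)
thr, clusters = threshold_clusters(res, p_thresh=0.001, k_min=100)
print(cluster_table(clusters).to_string(index=False))
```

printed (seed 20190702):

```
mean.Sd    +0.238 (SE 0.055, z = +4.37)
mean.Sc    +0.501 (SE 0.029, z = +17.51)
psi.Sc_Sc  +0.128 (SE 0.046, z = +2.75)
gamma.sex  -0.254 (SE 0.037, z = -6.88)
 voxel_count  peak_i  peak_j  peak_k  peak_x_mm  peak_y_mm  peak_z_mm  peak_z     sign
         147       8      11       7        8.0       11.0        7.0 6.75422 positive
```

The slope means of both parts are significantly positive (use and
use-intensity rise over the three waves), the continuous-slope variance
is significant (real heterogeneity in change), the sex path is
negative — all of the order of the generating values (0.188, 0.498,
0.218, −0.183) — and the single cluster surviving p < 0.001 with
extent > 100 is exactly the planted 147-voxel sphere: higher synthetic
"grey-matter" volume predicts a steeper rise in the use score.

The same pipeline is scriptable from the shell:

```bash
voxsem simulate --config config.yaml --out study/
voxsem fit       --data study/behaviour.csv --out fit/
voxsem voxelwise --data study/behaviour.csv --images study/images.nii \
                 --mask study/mask.nii --out maps/ --target Sc --seed 1
voxsem clusters  --pmap maps/p.nii --estmap maps/estimate.nii --out clusters.csv
```

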