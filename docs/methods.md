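# Methods

## The model

`voxsem` fits a two-part (semicontinuous) latent growth curve model to a
zero-inflated repeated outcome such as the AUDIT sum score measured at
T = 3 occasions. The observed score at occasion *t* is decomposed into

* a binary **any-use** indicator `y_d ∈ {0, 1}` (zero score vs. any
  positive score), and
* a continuous **score-given-use** value `y_c`, defined only where
  `y_d = 1`; structural zeros are treated as missing continuous cells
  under the usual MAR assumptions, so never-users contribute to the
  use/non-use process but carry almost no information about the
  intensity process.

Each part carries latent growth factors. With linear growth (the
default), subject *i* has latents `η = (I_d, S_d, I_c, S_c)`:

```
y_d[i,t] ~ Bernoulli( g( I_d[i] + λ_t · S_d[i] ) )          g = logit⁻¹ (probit optional)
y_c[i,t] = I_c[i] + λ_t · S_c[i] + ε[i,t],   ε ~ N(0, θ_t)
η[i]     ~ MVN( μ + shifts[i], Ψ )
```

`λ = (0, 1, 2)` by default (equal-interval coding for three waves;
configurable, e.g. `(0, 2.6, 4.6)` for per-year slopes given baseline /
follow-up ages of roughly 14, 16.6 and 19 years). Nuisance covariates
(sex, age, total brain volume, scanner-site dummies) shift the mean of
the continuous slope by default; the per-voxel brain value enters the
same way with coefficient `β_v` (target factor selectable among
`Id, Sd, Ic, Sc`).

`Ψ` is structured: all within-part covariances are free, and of the
cross-part block only Cov(I_d, I_c) is estimated by default (the three
covariances typically reported for this model class); `psi_cross` can be
set to `"none"` or `"full"`.

## Likelihood and quadrature

Missing cells simply drop their factor from the likelihood
(full-information ML; each subject contributes exactly their observed
cells). For each subject the continuous factors are jointly normal with
the observed continuous indicators, so they are marginalized
analytically: the likelihood factorizes into a closed-form multivariate
normal for `y_c` times an integral over the discrete factors only,

```
L_i = N(y_c; Λ_c m_c, Λ_c Ψ_cc Λ_c' + Θ) · ∫ Π_t Bern(y_d | g(Λ_d η_d)) · N(η_d; m̃_i, Ψ̃) dη_d
```

where `(m̃_i, Ψ̃)` is the conditional law of `η_d` given the observed
continuous data. The remaining 1–3-dimensional integral is evaluated by
Gauss–Hermite quadrature centred and scaled by that conditional — an
adaptive placement that is exact in the limit of no binary information
and, at the magnitudes relevant here (latent variances ≲ 1 on the link
scale), converged at the default 15 nodes/dimension to well below 1e-8.
The probit link has Gaussian rather than logistic tails and benefits
from ~25 nodes for the same accuracy. A deliberately naive
full-dimension tensor-product rule (`loglik_bruteforce`, prior-
standardized, no analytic factorization, ≥ 40 nodes/dimension) is kept
as an independent oracle; at 56 nodes it agrees with the adaptive rule
to ~1e-8 on realistic toys.

The analytic gradient is propagated through every step, including the
dependence of the quadrature nodes on the conditional moments (the
gradient is exact for the objective actually optimized). Per-subject
score vectors are available for outer-product-of-gradients (OPG)
information.

## Parameterization and optimization

The optimizer works on an unconstrained vector: raw latent means and
regression coefficients, log residual variances, and a log-Cholesky
factor per within-part block of `Ψ`. The free cross-part covariance
c = Cov(I_d, I_c) is mapped by `tanh` onto its exact positive-
definiteness bound given the blocks, `|c| < [Ψ_dd⁻¹]₀₀^(-1/2) ·
[Ψ_cc⁻¹]₀₀^(-1/2)`, so *every* unconstrained vector yields a valid
covariance matrix and the optimizer never meets an infeasibility wall.
This matters in practice: at the study magnitudes the discrete-part
covariance is weakly identified and the MLE frequently runs toward a
singular `Ψ` (corr → ±1); a hard feasibility boundary stalls
quasi-Newton methods there.

Estimation uses L-BFGS-B with the analytic gradient, moment-based
automatic starting values (occasion-wise logit/linear regressions),
a small jittered multi-start (3 starts, 10% jitter, default seed
20190702), and box bounds that keep scale parameters in
`[1e-8, 1e8]` — a zero-variance boundary is approached smoothly on the
log scale. Standard errors invert the observed information (central
differences of the analytic gradient) and are delta-method-mapped to
the structured scale; when the information matrix is not positive
definite, SEs are reported absent rather than NaN. Fits flag boundary
or degenerate solutions (zero latent variances, extreme link-scale
means) in `FitResult.messages` instead of failing.

## Model evaluation

Nested growth orders are compared by chi-square difference tests;
negative differences (possible at boundary solutions) are preserved as
signed diagnostics and clipped to zero for the p-value. Because a
two-part likelihood has no natural saturated reference, the
chi-square-based global indices (RMSEA with denominator `df·n`, CFI
against the independence baseline, SRMR over standardized covariance
residuals) are computed from the continuous part's normal likelihood
against unstructured moments estimated by EM over the missingness
patterns; covariate effects enter the model likelihood but not the
saturated reference, so these indices are a heuristic summary, which is
documented at the API. AIC/BIC use the full two-part likelihood.

Under an intercept-only truth, the linear-vs-intercept test places the
slope variance on the parameter boundary; the statistic then follows
the Stram–Lee `0.5·χ²(2) + 0.5·χ²(3)` mixture (rejection probability
0.035 at the χ²(3) 5% critical value, not 0.05). The test suite checks
the simulated statistic against that mixture.

## Voxel-wise driver

The mass-univariate stage fits the model once per mask voxel with the
(z-scored, by default) voxel value predicting the target factor, and
projects estimate / SE / Wald z / two-sided p back into image space.
Two refit policies exist:

* `refit="full"` — every parameter re-optimized per voxel, warm-started
  from the voxel-free base fit. This is the reference behaviour; a test
  verifies warm- and cold-started full refits agree in log-likelihood
  to 1e-6.
* `refit="beta"` (default) — the voxel coefficient alone is estimated
  by batched Fisher scoring (with secant acceleration) holding the
  nuisance parameters at the base MLE, with OPG standard errors. With
  centred voxel values the coefficient is nearly orthogonal to the
  nuisance parameters, and the audit test shows agreement with the full
  refit to |Δβ| < 0.05 (estimate correlation > 0.999). This is what
  makes whole-volume runs tractable on one CPU (a 16³ volume at
  N = 200 takes ~15 s rather than hours).

Cluster-extent thresholding splits suprathreshold voxels (`p <
p_thresh`, default 0.001, two-sided) by the sign of the estimate,
labels connected components (26-neighbour by default; 6 and 18
selectable), and retains components strictly larger than `k_min`
(default 100, honouring the strict "k > 100" reading). Peaks are
maximum-|z| voxels; world coordinates go through the NIfTI affine.
Constant voxels and non-converged voxels are missing-coded and counted
in the run manifest. No correction beyond the uncorrected-p + extent
rule is applied by default.

## Synthetic data

The generator emulates a three-wave adolescent cohort: latent draws at
the published magnitudes (`μ_Id = 0.568, μ_Sd = 0.188, Var_Id = 0.090,
Var_Sd = 0.024, Cov = −0.033; μ_Ic = 0.693, μ_Sc = 0.498, Var_Ic =
0.618, Var_Sc = 0.218, Cov = −0.078; Cov(I_d, I_c) = 0.124; γ_sex =
−0.183`), with the discrete-part values interpreted on the logit scale
(their published scale is ambiguous, so this is magnitude-realistic
rather than a reproduction — implied non-use rates are of the order of
35% declining to 25%, not the 48% → 7% of the cohort it mimics).
Residual variance defaults to 0.5 per occasion (unpublished; chosen of
the order of the slope variance). Attrition is whole-occasion MAR
dropout at retention 1.00 / 0.802 / 0.716 (1794 → 1439 → 1284).
Covariates: sex ~ Bernoulli(0.54), optionally age, total brain volume
and a uniform 9-level site factor. Model-scale continuous scores are
real-valued (occasionally ≤ 0); the CSV interface therefore codes
non-use as an exact zero score and use as any non-zero score, which
coincides with "score > 0" on genuine instrument data.

Brain volumes are one smooth Gaussian random field per subject
(configurable FWHM, unit variance, periodic boundary) plus white noise
(sd 0.5) plus spherical effect regions whose intensity is `β` times the
subject's standardized true continuous slope. The generator makes no
attempt at realistic neuroanatomy, tissue classes or preprocessing
artifacts — passing tests demonstrate statistical behaviour of the
estimator and thresholding rule, not robustness to real VBM data.

## Problem sizes used in the test and acceptance studies

Parameter recovery: 20 replicates at N = 2000. LRT calibration: 500
replicates at N = 500 (continuous part). Detection/specificity: 16³
volumes, a 147-voxel sphere (radius 3.2) with `β = 2.5`, N = 200, one
planted run and 20 null runs, scoring mode at 5 quadrature
nodes/dimension (indistinguishable from 15 nodes to ~5e-6 in z on an
audit chunk). The oracle comparisons use 10 random toy datasets of 3
subjects against the 56-node brute force.

## Known limitations

* At the default magnitudes the discrete-part covariance parameters are
  weakly identified with T = 3: their MLE is boundary-prone
  (corr(I_d, S_d) → −1 in a sizeable fraction of replicates) and the
  variance components carry upward finite-sample bias. This is a
  property of the estimator under these conditions (an independent
  random-effects implementation degenerates on the same data), not of
  the optimizer; the recovery study reports it rather than masking it.
  Continuous-part parameters and regression coefficients recover
  cleanly.
* Chi-square-based fit indices for the two-part model rest on the
  continuous part only (see above).
* The `refit="beta"` voxel mode ignores nuisance-parameter uncertainty;
  with centred voxel predictors the effect on β and its SE is small but
  not exactly zero.
* One latent structure per run: no latent classes, no multiple-group
  models, no robust/WLSMV estimation.
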