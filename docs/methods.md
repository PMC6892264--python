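# Methods

## Model

Per subject, multivariate responses follow the GLM **Y** = **ZU** + **XB** +
**e**, with **Y** (measurements × voxels), condition design **Z**, confounds
**X**, and errors that are IID over measurements but may be spatially
correlated over voxels, vec(**e**) ~ N(0, **V** ⊗ **I**).  Interest lies not
in the response patterns **U** but in the condition-by-condition second
moment **G** = **UU**ᵀ, modelled as a nonnegative mixture of hypothesis
covariance components **C**ᵢ with lognormal scales vᵢ = exp(λᵢ) and Gaussian
hyperpriors on the log scales.

### Second-order reduction

Condition estimates are Û = **R** **Z**⁻**Y**, where **Z**⁻ is the
pseudo-inverse (singular values truncated at 1e-10 of the largest) and
**R** = **I** − (**Z**⁻**X**)(**Z**⁻**X**)⁻ removes confounds in condition
space.  The engine consumes

- **S** = ÛÛᵀ and the error component **C**ₑ = **R** **Z**⁻**Z**⁻ᵀ **R**
  (the confound-projected form, keeping the generative expectation of **S**
  internally consistent);
- the effective spatial degrees of freedom υ (below);
- an orthonormal basis **E** of range(**R**).  With a constant confound,
  **R** is a centering projector, so **S**, the projected components and
  **C**ₑ share a null space; all traces and log-determinants are evaluated
  on **E**ᵀ·**E**-projected matrices, where they are full rank.  This is
  forced by the algebra, not a modelling choice.

Rows of **Y** may be mean-centred over voxels first (`centre_rows`), which
turns second moments into spatial covariances; the searchlight does this per
sphere.

### Spatial degrees of freedom

Spatial correlation does not bias the estimates but reduces the effective
number of independent voxels.  With ϒ = **r**ᵀ**r** the voxel Gram matrix of
the full-model residuals,

    υ = tr(ϒ)² / tr(ϒϒ),

which is 1 for perfectly correlated voxels and p for uncorrelated ones, and
is scale-invariant.  Estimated from finite residuals, the plug-in ratio is
biased low — for white noise it approaches p/(1 + p/m′), where m′ is the
residual degrees of freedom — which would inflate every scale estimate by
~1 + p/m′ and, more damagingly, mis-centre group-level credible intervals.
`spatial_dof` therefore accepts the residual degrees of freedom and replaces
the plug-in ratio with the ratio of Wishart-unbiased estimates of tr(**V**)²
and tr(**VV**):

    υ = ((m′+1)·t₁² − 2·t₂) / (m′·t₂ − t₁²),   t₁ = tr(ϒ), t₂ = tr(ϒϒ),

clipped to [1, p].  The raw functional (with its exact limiting cases)
remains the default when no residual dof is supplied.

### Likelihood and free energy

With S̄ = **S**/υ (entries on the scale of per-voxel variances) and
Ŝ(λ) = Σᵢ exp(λᵢ)·**C**ᵢ, the free energy is

    F = −(υ/2)·(tr(Ŝ⁻¹S̄) + ln|Ŝ|) − ½(μ−η)ᵀΣ⁻¹(μ−η) + ½ ln|Σ⁻¹Ω| + const,

i.e. a Wishart-type accuracy with υ acting as the degrees of freedom, a
prior penalty, and the Laplace complexity term evaluated at the optimal
posterior covariance.  Constants are dropped consistently; only differences
of F are meaningful.  (The penalty enters with a negative sign; a
positive-signed penalty would reward prior deviation and make the objective
unbounded.)

## Estimation

Fisher scoring on λ with

    ∂F/∂λᵢ = −(υ/2)[tr(Ŝ⁻¹vᵢCᵢ) − tr(Ŝ⁻¹S̄Ŝ⁻¹vᵢCᵢ)] − [Σ⁻¹(μ−η)]ᵢ
    Iᵢⱼ     = (υ/2)·tr(Ŝ⁻¹vᵢCᵢŜ⁻¹vⱼCⱼ) + Σ⁻¹ᵢⱼ

posterior covariance Ω = I(μ)⁻¹ at the mode.  Steps are capped at 8 log
units (∞-norm) and halved up to 8 times if the objective decreases, so the
recorded trajectory is non-decreasing; convergence requires |ΔF| < 1e-3 on
two consecutive iterations (at most 128).  λ is kept in [−32, 32] and a
jitter of 1e-10·tr(Ŝ)/dim is added once if Ŝ is numerically singular.

**Two deterministic starts.**  The objective can have two basins per
component: a shrunk state near the prior mean (a quasi-fixed point, since
the gradient scales with exp(λ)) and a data-supported state.  Starting only
at the prior mean can strand a truly expressed component in the shrunk
basin; starting only at a data-derived point can strand a weakly supported
scale on an interior plateau whose Laplace summary overstates the evidence.
The fit therefore ascends from both the prior mean and a least-squares
projection of S̄ onto the components (clipped to exp(±8); components under a
precise prior start at the prior mean) and keeps the optimum with the higher
free energy — the complexity term correctly arbitrates between the basins.
Fits remain bit-for-bit reproducible.

### Hyperpriors

Default shrinkage hyperprior N(−16, 128) per log scale: a prior scale
expectation of exp(−16) ≈ 1.1e-7 (the component is absent unless the data
argue otherwise) with essentially uninformative spread.  A component is
"switched off" by the precise prior N(−16, 1/128).  Posterior point
estimates of scales are reported as exp(μ) (the mode-consistent summary used
in the worked example); the full lognormal summary, including the mean
exp(μ + Ω/2) and 90% intervals, is available from `scale_summary`.

## Bayesian model reduction

For Gaussian prior/posterior pairs, replacing prior (η, Π⁻¹) by (η_r, Π_r⁻¹)
gives reduced posterior precision P_r = P − Π + Π_r, mean
μ_r = P_r⁻¹(Pμ − Πη + Π_rη_r), and evidence change (full minus reduced)

    ΔF = ½ ln(|Π||P_r| / (|Π_r||P|))
       + ½ (μᵀPμ − ηᵀΠη + η_rᵀΠ_rη_r − μ_rᵀP_rμ_r).

The identity is exact for log-likelihoods quadratic in λ; it was verified
against direct numerical integration of the Gaussian marginal likelihood,
and against refits under moderately perturbed priors (agreement < 0.001
nats).  For drastic reductions (e.g. the precise null, ~14 log units from a
data-supported mode) the quadratic expansion is an extrapolation; this is
the standard practice for scoring components, but a direct refit can then
differ by more than the nominal 0.1-nat agreement seen in the quadratic
regime.  Reductions whose P_r is not positive definite raise an error rather
than being silently regularised; log-determinants use Cholesky
factorisations.

Component probabilities are two-model softmaxes over {full, reduced};
exclusive selection reduces all-but-one effect component and softmaxes the
single-component evidences (the noise component is never reduced).

## Group level (PEB)

Subject log scales follow λ_s = **D**_s λ⁽²⁾ + r_s, r_s ~ N(0, Γ), with a
subjects × regressors design whose first column of ones carries the group
average (covariate columns are mean-centred by default so that reading is
preserved).  Swapping subject s's prior for the empirical prior
N(**D**_sλ⁽²⁾, Γ) changes its evidence by an amount exactly quadratic in
λ⁽²⁾ (by the BMR identity), so given Γ the level-2 posterior is closed form;
no subject data are re-inverted.  The between-subject covariance is diagonal,
Γⱼⱼ = exp(γⱼ)·bⱼ with bⱼ the mean first-level posterior variance of
component j, and γⱼ ~ N(0, 1): wide enough that the subjects, not the
hyperprior, determine the random-effect variance (a tight hyperprior pins Γ
at bⱼ and demonstrably undercovers the group mean).  γ is optimised by
Newton ascent with numeric derivatives and step halving (same tolerances as
the first level), bounded to [−8, 8]; the group free energy trajectory is
non-decreasing.  Level-2 priors default to N(−16, 128) for group means and
N(0, 128) for covariate effects.  Updated subject posteriors are the BMR
posteriors under the empirical prior at the estimated group mean and Γ.

## Synthetic data

The generator reproduces the study conditions used throughout the tests: 16
stimuli = 8 equally spaced parametric levels × 2 categories; contrasts are
the unit-norm mean-centred parametric ramp, the unit-norm ±1 category
pattern, and their interaction (the parametric contrast multiplied
elementwise by the ±1 sign pattern, which keeps it unit-norm and orthogonal
to both main effects).  Per subject: 24 seeded random permutations of the 16
conditions stacked into a one-hot design (384 rows), 64 voxels, a constant
confound with per-voxel baseline, voxel patterns drawn IID per active
contrast with the configured per-voxel variance (defaults 1, 1, 0), and
Gaussian noise smoothed along a 1-D voxel line (Gaussian kernel, reflecting
boundaries, default sd ⅛ voxel) then rescaled so the marginal per-voxel sd
equals `noise_sd`.  The default `noise_sd` is 0.5 — half the main-effect
sd — while the noise-manipulation analyses use sd 1 doubling to 2 (variance
1 → 4), matching the two conventions in which the design is described.
Effect scales default to 1 per active main effect; this is a documented
choice, as only the noise variance has externally stated truth values.

What the generator does *not* emulate: haemodynamic convolution, temporal
autocorrelation, drifts, motion artefacts, or 3-D anatomical structure
(except in the searchlight tests, which embed signal blobs in 3-D noise
volumes).  Passing tests therefore certify the estimation machinery under
the stated statistical structure, not robustness to real fMRI preprocessing
residue — timeseries are assumed high-pass filtered and whitened upstream.

## Searchlight

Sphere membership is computed in world space via the affine (inclusive
boundary, centres restricted to in-mask voxels, KD-tree radius queries);
spheres below `min_voxels` (default 10) are skipped and recorded as NaN.
Whole-volume quantities (condition estimates **Z**⁻**Y**, model residuals)
are computed once; per sphere the rows are re-centred over the sphere's
voxels, υ is estimated from the sphere's residual block, and the two-
component model {seed hypothesis, noise} is fitted and scored against the
precise null by BMR.  The posterior-probability map is the logistic of the
logBF map, conventionally thresholded at 0.95; no multiple-comparison
correction is applied.  Spheres are independent, so results are identical
under any processing order or parallel partition.  Default radius 8 mm —
these defaults are package choices, not externally fixed values.

## Problem sizes

Tests and the acceptance script run at the generator's native scale
(8 subjects × 384 × 64), with 20 replicates for stochastic claims,
100 random problems for the ascent-monotonicity property, and 5 seeded
20³-voxel volumes (16 conditions × 8 presentations) for searchlight
localisation.

## Known limitations

- Single IID noise component only; condition-specific or serially
  correlated error components are representable in `ComponentSet` but no
  estimation presets are provided.
- Laplace (Gaussian) posteriors on log scales: plateau-shaped posteriors of
  weakly identified scales are summarised by a local mode and curvature.
- One hierarchical level; diagonal between-subject covariance.
- The spatial-DOF estimator treats residuals as an IID sample over
  measurements; strong temporal structure would bias υ.
- No random-field correction of searchlight maps; thresholding is per-voxel.
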