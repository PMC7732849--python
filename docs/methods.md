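# Methods

This document specifies the statistical models, the synthetic generator, and
the numerical choices in `vhlifespan`, including the reasoning behind
parameter defaults and the known limitations of each step.

## 1. Trajectory model and thinning profiles

Per region, thickness is modelled as

```
thickness_ij = s(age_ij) + sex_i·β_sex + scanner_ij·β_scan + u_i + ε_ij
u_i ~ N(0, σ²_u),   ε_ij ~ N(0, σ²)
```

where `s` is a penalized cubic spline and `u_i` a subject random intercept.

**Basis.** A cubic B-spline on `knots_k = 6` distinct knots placed at the
empirical age quantiles (boundary knots at the observed min/max age), giving
a basis of dimension 8. No natural boundary constraint is imposed: forcing
`s'' = 0` at the boundary knot would bias the derivative exactly where
childhood curvature is largest. The curvature penalty `∫ s''(x)² dx` is
computed exactly by two-point Gauss–Legendre quadrature per inter-knot
segment (the integrand is piecewise quadratic there, which the rule
integrates exactly).

**Mixed-model representation.** The penalty matrix is eigendecomposed; its
null space (constant + linear) enters as fixed effects, and the positive
eigenvectors, scaled by the inverse square-root eigenvalues, become i.i.d.
random wiggly coefficients with variance ratio γ₁ = τ²/σ². The subject
intercepts have ratio γ₂ = σ²_u/σ². Profiled REML over (log γ₁, log γ₂) is
minimized with Nelder–Mead; each evaluation uses precomputed cross-products
and a Cholesky factor of `I + Z'Z·γ` (Woodbury form), so cost is independent
of n after the one-time cross-product pass. Coefficient uncertainty is the
Bayesian covariance from the full penalized normal matrix.

**Outlier pass.** One pass: observations with |residual| strictly greater
than `outlier_sd = 7` working-residual SDs (residuals include the subject
intercept) are removed and the model refitted once. Ties at the threshold
are retained.

**Thinning profiles.** The derivative of the fitted smooth on the grid
5–89 step 2 (43 ages), computed by a forward finite difference with
`fd_eps = 0.01` years; pointwise 95% half-widths come from the delta method
on the smooth's coefficient covariance. Covariates are additive, so the
derivative does not depend on the sex/scanner level used for prediction (the
test suite checks this to 1e-10).

**Known limitation — boundary bias.** Under observation noise, REML-optimal
smoothing of a k = 6 spline carries extra bias at the edge of the age
support. Characterized on synthetic data at n = 800 (noise defaults), the
derivative error at the first grid age (5 y) is ≈ 0.011 mm/yr across seeds
while all interior ages stay below ≈ 0.007; noise-free recovery is below
0.005 mm/yr everywhere. Conclusions about the youngest grid age should be
read with this in mind.

## 2. Expression aggregation and the consistent pool

Probe values are mean-aggregated per (donor, sample, region, gene); samples
are median-summarized within (donor, region); the cross-donor median of the
donor medians is the gene's regional profile (midpoint convention for even
counts). A gene is *consistent* if its mean pairwise inter-donor profile
correlation is ≥ `consistency_threshold = 0.45`; when a second dataset is
supplied, the cross-dataset profile correlation must also reach the
threshold. Consistent genes form both the panel universe and the resampling
pool. Mouse marker panels are mapped to human symbols through an explicit
homolog table (many-to-many allowed), deduplicated in order, and intersected
with the pool.

## 3. Virtual-histology inference

For each consistent gene and grid age, the Pearson correlation between the
gene's 34-region expression profile and the age's thinning profile is
computed; a panel's statistic is the unweighted mean over its genes. The
null resamples genes: each of B = 10,000 iterations draws a panel-sized
subset of the pool without replacement, averages its correlations at every
age, and records the signed value with the largest absolute value across
ages. Two-sided p per age: `(1 + #{|null| ≥ |observed|}) / (B + 1)`; this
max-over-ages construction controls the family-wise rate over the 43 ages
within a panel. Across panels, Benjamini–Hochberg at each age; in
replication mode (`restrict_panels`) only the stated panels are tested and
adjusted. Per-panel RNG streams are derived from the master seed plus a
stable hash of the panel name, so adding or removing panels never perturbs
other panels' draws, and the pool is sorted by gene symbol before drawing,
so results do not depend on input row order. Variance explained at an age is
the OLS R² of the thinning profile on the significant panels' mean
expression profiles.

**Known limitation — conditioning of gene-resampling nulls.** Gene
resampling is exactly calibrated only when panel genes are exchangeable with
the pool. Averaged over data-generating randomness the test is nominal
(random pseudo-panels achieve a 5% family-wise rate in our calibration
studies), but conditional on one expression matrix a *fixed* panel's rate
varies with the norm of its mean profile (observed per-panel range ≈ 0.5–10%
at the nominal 5%). Coherent panels whose members share a strong latent
profile make the null anticonservative; this is intrinsic to the method, not
to the implementation.

## 4. Diagnosis contrasts

Per region, an elderly HC/MCI/AD cohort is fitted with
`thickness ~ C(diagnosis, HC reference) + age + sex + site + (1 | subject)`
by REML (statsmodels MixedLM; an OLS fallback with a logged warning is used
when no subject has multiple visits). Contrasts are coefficient differences
from the single fit, so `AD_vs_HC = AD_vs_MCI + MCI_vs_HC` holds to machine
precision. Each contrast profile is pushed through the same resampling
machinery with a single "age", where the max-over-ages step degenerates to
the identity. Designs are checked for rank; at least 10 subjects per
diagnosis are required per region.

## 5. Enrichment

Seed sets are panel genes whose profile tracks a target profile at
|r| ≥ 0.5 (fidelity screen); partners are background genes with r ≥ 0.5 to
the seed-set mean profile; over-representation of a disease gene set among
the partners uses the one-sided hypergeometric tail, BH-adjusted across the
seed sets of one run. Co-expression is computed on the single supplied
regional matrix; the statistical shape (seed → partners → enrichment) is the
point, not a multi-resource compendium.

## 6. Synthetic generator

All generators are pure functions of (spec, seed). The base curve is
`T(age) = 3.7 − 0.35·ln(1 + age/5) − 0.0002·max(0, age−60)²` (steep
childhood decline, mild adult thinning, late-life acceleration). Regional
structure enters on the *derivative*: `T'_r(age) = T'(age) + g(age)·z_r`
with `g` a difference of Gaussian bumps centred at 8 y (+) and 70 y (−),
amplitude `g0 = 0.01` mm/yr per expression SD, and `z_r` the standardized
mean expression profile of one chosen panel. Thickness integrates this
exactly (`erf` closed form), so ground truth is exact. Observation model:
subject intercept SD 0.10 mm, scan noise SD 0.05 mm, four scanners with
fixed offsets, same-day duplicate scans for 15% of subjects, bimodal age
sampling, 1–6 visits within an 11-year window. The clinical generator
subtracts regionally varying deficits `δ_MCI = 0.05 + 0.02·z_r`,
`δ_AD = 0.12 + 0.05·z_r` (mm) from the healthy model.

The expression generator draws, per panel, a shared latent regional profile
(SD `panel_latent_sd = 1`) plus per-gene noise (SD `within_panel_sd = 12`),
background genes as independent N(0, 1) profiles, then adds donor/sample
(SD 0.3) and probe (SD 0.2) noise with 1–4 probes per gene and a Poisson
number of samples per donor-region. `within_panel_sd` is deliberately large
relative to the shared latent: it keeps panel members close to exchangeable
with the pool, which is the regime in which the gene-resampling null is
calibrated (§3) while the panel-mean coupling signal remains recoverable.
Calibration studies set `panel_latent_sd = 0` (exact exchangeability) and
`g0 = 0`; because a strictly uncoupled world has a region-constant true
derivative (inter-regional correlation undefined), calibration uses
estimation-noise-emulating profiles: the base derivative plus smooth
region-independent Gaussian-bump perturbations (coefficient SD 0.002 mm/yr).

## 7. Numerical and reproducibility choices

- Problem sizes (34 regions, 43 ages, nine panels of 25–103 genes, ~2100
  consistent genes, 800-subject cohorts, 200 subjects per clinical group)
  were chosen so every check runs in minutes on one CPU.
- All randomness flows from a single master seed; derived stream seeds are
  masked to below 2³¹. Reruns at a fixed seed are bit-identical (hashed
  output digests in the run manifest).
- Cohort TSVs are written with 17 significant digits and re-parsed with a
  correctly-rounded parser, so write→read round-trips are exact.
- Zero-variance guards treat numerically-zero variance (≤ 1e-12 relative)
  as zero: a constant profile row can acquire an O(1e-18) standard deviation
  purely from floating-point mean subtraction.
- Permutation p-values use the add-one convention and are therefore never
  zero; with B iterations the smallest attainable p is 1/(B+1).
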