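# Methods notes

This note records the modelling assumptions, numerical choices and known
limitations behind `growthmicro`, in the order the pipeline runs. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Conditional weight gain

CWG z-scores are standardized residuals of one cohort-level OLS regression
of six-month WAZ on birth WAZ plus length and age covariates. Choices:

- **Design matrix.** The LAZ covariate is ambiguous between the birth and
  six-month occasions; we include **both** by default
  (`intercept + waz_birth + laz_birth + laz_6m + age_6m`) and expose
  `laz_occasions={"both","birth","six_month"}`. The design columns used are
  recorded in `CWGResult.design_columns`.
- **Standardization.** Residual divided by the sample standard deviation of
  residuals (n−1 denominator), *not* internally studentized residuals —
  this makes mean 0 / sd 1 exact by construction.
- The "six-month" visit is the visit nearest 182 days within ±60 days;
  children without one are excluded from CWG scoring (not from curve
  reconstruction).
- Degenerate fits (zero residual sd) and rank-deficient designs raise
  typed errors; the singular-design error names the collinear columns.

## LMS z-scores and the growth reference

`z = ((X/M)^L − 1)/(L·S)` with the log form used when |L| < 1e-12; L, M, S
are linearly interpolated in age. The synthetic reference stores LMS
triplets per **sex × measure (weight, length)** on a daily grid 0–730; its
median curves are monotone power laws anchored at realistic birth and
two-year sizes (WHO-like magnitudes), S ∈ (0, 0.3), L ∈ [−2, 2]. Real
reference tables can be supplied in the same CSV layout
(`sex, measure, age_days, L, M, S`).

## Sparse functional PCA

- **Smoothers.** Mean and covariance are local-linear (Gaussian kernel)
  fits of binned pooled data. Bins sit at the *within-bin mean* coordinate,
  which keeps the binned smoother exact for linear trends; the smoother is
  computed in centred form (slope about the local weighted mean abscissa)
  because the textbook uncentred normal equations cancel catastrophically
  at evaluation points far from the visit clusters.
- **Bandwidths** are chosen by GCV over a geometric candidate grid. The
  covariance smoother's bandwidth floor is half the largest gap between
  occupied design points: a 7-visit schedule leaves a 365-day unobserved
  stretch, and a bandwidth below that gap cannot generalize across it
  (GCV, evaluated only at observed bins, cannot see this). Selected
  bandwidths are reported in `FPCAModel.meta`.
- **Noise variance** σ² is the average of (smoothed raw diagonal − surface
  diagonal) over the central half of the domain, floored at 0.
- **Components.** Eigenpairs come from the quadrature-weighted discretized
  operator on a 51-point working grid, interpolated to the daily grid and
  re-orthonormalized (Cholesky); K is the smallest number of components
  with fraction of variance explained ≥ 0.99 (configurable). Eigenvalues
  below max(1e-12, 1e-10·trace) are treated as zero, so a cohort with one
  common curve yields K = 0 and all-zero scores.
- **Scores** are conditional expectations
  `ξ̂_i = Λ Φ_iᵀ (Φ_i Λ Φ_iᵀ + σ̂² I)⁻¹ (y_i − μ_i)`. When σ̂² ≈ 0 the
  inner matrix is rank-deficient; a ridge of max(σ̂², 1e-4 × mean prior
  variance at the child's ages) keeps the solve conditioned while changing
  well-posed scores negligibly.
- **Grid.** 731 daily points, so visit ages index the grid exactly.

## Curve representation and registration

Curves are projected by least squares onto 102 cubic B-splines with evenly
spaced knots on [0, 730]; the basis is rich enough that projection residuals
are ~1e-4 of the curve range. Registration warps each curve toward the
cross-sectional mean: `h_i(t)` is the normalized integral of the
exponential of a 9-parameter cubic spline (strictly increasing,
endpoint-fixed by construction), fitted by L-BFGS with a small ridge on the
warp coefficients so the identity warp is the exact optimum for
already-aligned curves; mean and warps alternate for ≤ `max_iter` rounds.
The warp target and family are our own operationalization — "alignment to
the dominant shape" admits many; ours is the common continuous-registration
choice.

## Diversity

Defaults follow standard practice: rarefaction is uniform subsampling
without replacement (multivariate hypergeometric), samples below depth are
dropped with an audited warning rather than erroring; α-diversity is
computed on phylum-aggregated counts; F:B with zero Bacteroidetes is
*undefined* (NaN, logged) rather than infinite so downstream rank tests
stay well-defined. The phylum proportion test rounds mean-proportion
"successes" to the nearest integer (the construction otherwise yields
non-integers), applies Pearson χ² with Yates correction only for 2-group
comparisons, and multiplies p by the number of tests (capped at 1).
One-tailed Mann–Whitney uses the exact U distribution for small tie-free
samples and the tie-corrected normal approximation (no continuity
correction) otherwise.

## Two-stage taxon merging

- "Neighbor" = the nearest sibling **group** under the same parent, tie-broken
  by tree distance, branch order, then name. If a unit has no remaining
  sibling (its parent collapsed to a unary node), the nearest sibling of an
  ancestor is used and the audit entry is flagged `+ancestor-sibling`.
- The rarity rule (< `min_count` in strictly more than `prevalence` of
  samples) is **re-checked after every merge** (fixpoint), making the result
  order-invariant: merged sums can exit rarity.
- Stage-2 correlation is Pearson on the stage-1 outputs; constant columns
  have undefined correlation and are logged as unmergeable. Chained merges
  average pairwise (mean of the two current vectors), matching a
  sum-then-average-per-merger semantics.
- Stage 1 conserves the grand count total exactly; group membership always
  partitions the input genera; group ids are the lowest common rank name of
  the members plus a stable integer (singletons keep the genus name).

## Function-on-scalar regression

- Solved in closed form **on the observation grid** with time rescaled to
  [0, 1] and a squared-second-difference penalty; the rescaling makes the
  default smoothing parameter λ_s = 10⁴ scale-free. With λ_s = 0 the
  estimator coincides with pointwise OLS exactly (acceptance criterion).
- The **intercept is unpenalized by default** (`penalize_intercept=True`
  restores the uniform penalty). A heavily penalized intercept cannot track
  a curved mean function; the unexplained curvature leaks into the residual
  covariance, inflating coefficient variances ~10% and making all three
  significance measures conservative (PCA fell below the calibration band
  in our null simulations). This deliberately inverts the originally
  planned default; the flag preserves the variant.
- Coefficient covariance surfaces are the sandwich of the penalized hat
  operator with the **empirical residual-curve covariance** (no working
  independence) divided by n − p.
- Significance measures from `V_j = Σ ν_m ψ_m ψ_mᵀ`, scores
  `z_m = ⟨β̂_j, ψ_m⟩`: **L2** uses T = ∫β̂², null Σν_m χ²₁ by Monte Carlo
  (10⁵ draws, fixed internal seed 715001, overridable); **PCA** uses the
  Wald statistic on components covering 95% of the trace, χ²_M reference;
  **Choi** weights by 1/√ν over components covering 99.9% of the trace with
  a Σ√ν_m χ²₁ Monte-Carlo null — our concretization of a weighting "between
  PCA and L2" (the geometric midpoint √ν between weights ν and 1), flagged
  as such since the original weighting is defined in its own reference.

## FLAME-style selection

- Coefficients live in the truncated Mercer eigenbasis (M = 50 by default)
  of the first-order Sobolev kernel, whose RKHS norm is ∫f² + ∫(f′)²; the
  elliptical group-threshold block update is solved exactly via a monotone
  scalar fixed-point for the RKHS norm, giving *exact* zeros for unselected
  predictors. Block minimization is exact, so the objective decreases
  monotonically (asserted in tests).
- Pilot = unweighted fit at 1e-3·λ_max (ridge-like); adaptive weights
  ω_j = 1/max(‖β̃_j‖_L2, 1e-8)^γ with γ = 1.
- λ path: 10 log-spaced values below the weighted λ_max; K-fold CV (folds
  stratified on curve mean level, seeded) minimizes held-out integrated
  squared error; warm starts descend the path; active-set sweeps with a
  full sweep every fifth iteration.
- Curves are mean-centred before fitting (the intercept is handled
  implicitly); X is standardized column-wise, so reported coefficient
  curves are per-sd-of-predictor.

## Covariate models

Greedy correlation pruning scans diet columns in declared order and drops a
column correlated > 0.7 with an already-retained one; base categories
(dairy, vegetables) are declared before their near-duplicate derived
categories (milk, vegetables-excluding-potatoes) so the derived ones are
eliminated. Best-subset enumerates all 2^p subsets (refused for p > 20) on
precomputed Gram matrices; the criterion defaults to **BIC**
(`n·ln(RSS/n) + k·ln n`, k counting the intercept) — the original
selection tool's criterion is unstated, and BIC's sparsity suits a
confounder screen; AIC is available. Categorical covariates use
reference-level dummy coding (first declared level). `joint_fosr` drops
all-zero covariate columns (they would make the normal equations singular
while carrying no information) and errors on id mismatches, listing
orphans.

## Synthetic cohort: what it emulates, what it does not

The generator states a world: 200 children, 75 genera, 7 visits with ±7-day
scheduling jitter and 10% missingness (birth never missing), multinomial
counts at depth 100,000 with 40% planted-rare genera (≈1 expected read) and
log-normal overdispersion (sd 0.3), one correlated sibling pair per site
sharing a latent log-normal factor (sd 1.0; members floored at 1.5%
abundance so the correlation survives counting noise), one abundant anchor
genus per phylum (keeping phylum summaries defined), growth-index curves
with two principal components (level and tilt; typical deviations 0.008 and
0.004 kg/cm), visit noise sd 0.004 kg/cm, length measurement error 0.4%,
and microbiota effects of ±0.003·sin(πt/T) on the oral summaries. Lengths
follow the reference median with child-level variation and weights are
back-solved as index × length, so the weight-for-length signal *is* the
simulated curve by construction.

Not emulated: realistic phylogenetic branch lengths, compositional
covariance beyond the planted blocks, age-dependent microbiota, informative
missingness, demography, or the intervention design. A green test therefore
establishes correctness of the estimators under the stated generative
model, not robustness to real-data pathologies.

The distributional form of growth-curve variation (Gaussian low-rank FPCA)
is our modelling choice; the FPCA eigen-scale convention is that
`pc_sds` are typical curve deviations in index units, with eigenvalues
carrying the 730-day domain factor since eigenfunctions are orthonormal
over days.

## Known limitations

- FPCA bandwidth selection is GCV over a small candidate grid with the
  gap-keyed floor; pathological designs (one cluster of visits) will fall
  back to heavy smoothing.
- The Choi weighting and truncation are a documented concretization, not a
  reproduction of the original reference's operator.
- Registration optimizes a nonconvex objective per child; it is
  deterministic but only locally optimal.
- Group-count outcomes of the merge (e.g. 46 groups from 75 genera in the
  README example) are data-dependent observations, not contracts.
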