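# growthmicro

Statistical machinery for linking **early-childhood growth trajectories** to
**oral and gut microbiota composition**, packaged as a tested, reusable
pipeline with a synthetic-cohort generator so every stage can be exercised
and validated without any protected data.

The scientific setting: children are weighed and measured at a handful of
clinic visits over their first two years (birth, 3–4 weeks, 16, 28, 40
weeks, 1 year, 2 years), and 16S rRNA genus-level count tables are obtained
from oral/stool samples at age two. The package implements the analysis
chain that connects the two:

1. **Anthropometrics** (`growthmicro.anthro`) — the growth index
   (weight kg / length cm), WAZ/LAZ via the LMS transform
   `z = ((X/M)^L − 1)/(L·S)` against a sex- and age-specific reference, and
   the **conditional weight gain (CWG) z-score**: the standardized residual
   of a cohort regression of six-month WAZ on birth WAZ with LAZ and precise
   age as covariates. `CWG ≥ 0` defines *rapid infant weight gain*.
2. **Growth curves** (`growthmicro.curves`) — sparse functional PCA: the
   mean `μ(t)` and covariance surface `G(s,t)` are estimated by pooled
   local-linear smoothing, per-child scores `ξ_ik` are best linear unbiased
   predictors given the child's own sparse visits, and each smooth curve
   `μ + Σ_k ξ_ik φ_k` is represented in a 102-function cubic B-spline basis
   and optionally aligned by monotone time warping.
3. **Diversity** (`growthmicro.diversity`) — rarefaction without
   replacement, inverse Simpson / Shannon / Simpson α-diversity at the
   phylum level, the Firmicutes:Bacteroidetes (F:B) ratio, Bray–Curtis
   dissimilarity, phylum proportion χ² tests with Bonferroni correction,
   and one-tailed Mann–Whitney group comparisons.
4. **Taxon merging** (`growthmicro.merge`) — a two-stage phylogeny-guided
   aggregation: merge a genus into its tree sibling when it has <5 counts
   in >90% of samples (counts summed), then merge sibling groups whose
   abundances correlate above 0.7 (counts averaged), both to fixpoint, with
   a full audit log.
5. **Function-on-scalar regression** (`growthmicro.fosr`) — coefficient
   *curves* `β_j(t)` from penalized least squares with a second-derivative
   roughness penalty, pointwise confidence bands, and three quadratic-form
   significance measures (**L2**, **PCA**, **Choi**) built from the
   eigendecomposition of the coefficient covariance surface.
6. **FLAME-style selection** (`growthmicro.flame`) — high-dimensional
   functional variable selection minimizing
   `(1/2n) Σ_i ‖Y_i − Σ_j x_ij β_j‖² + λ Σ_j ω_j ‖β_j‖_K`
   with the first-order Sobolev kernel
   `K(s,t) = cosh(min(s,t))·cosh(1−max(s,t))/sinh(1)`, adaptive weights from
   a pilot fit, block coordinate descent with exact group thresholding, and
   cross-validated λ. Unselected coefficient curves are *exactly* zero.
7. **Covariate models** (`growthmicro.covariates`) — greedy correlation
   pruning of diet variables at |r| > 0.7, OLS regressions with t/F
   statistics and adjusted R², exhaustive best-subset selection (BIC/AIC),
   and joint functional regressions of curves on microbiota summaries plus
   diet.
8. **Synthetic cohort** (`growthmicro.synthetic`) — a generative model with
   known ground truth: random taxonomy trees with labelled phyla,
   multinomial counts with planted rarity and sibling correlation, an LMS
   reference, covariates with planted collinearity, and growth curves
   `μ(t) + Σ_k ξ_ik φ_k(t) + Σ_j x_ij β_j(t)` with configurable
   microbiota→growth effects.

## Worked example

```python
import numpy as np
import growthmicro as gm
from growthmicro.anthro import cohort_zscores
from growthmicro.curves import fit_fpca, predict_curves
from growthmicro.fosr import fit_fosr
from growthmicro.merge import merge_taxa
from growthmicro.synthetic import SyntheticConfig, simulate_cohort

cohort = simulate_cohort(SyntheticConfig(n_children=200, n_genera=75, seed=7))

zs = cohort_zscores(cohort.records, cohort.reference)
cwg = gm.cwg_zscores(zs["waz_birth"], zs["waz_6m"], zs["laz_birth"],
                     zs["laz_6m"], zs["age_6m"])
rapid, non_rapid = gm.classify_rapid(cwg)
print(len(rapid), len(non_rapid))          # 95 84

model = fit_fpca(cohort.records)
print(model.n_components, model.sigma2)    # 2  2.69e-05
curves = predict_curves(model)             # 102-spline representation

result = merge_taxa(cohort.tables["oral"], cohort.tree)
print(result.n_groups)                     # 46 groups from 75 genera

grid = np.linspace(0, 730, 147)
fit = fit_fosr((grid, curves.evaluate(grid)),
               cohort.features[["oral_inverse_simpson"]])
print(fit.pvalues["oral_inverse_simpson"])
# {'L2': 0.1046, 'PCA': 0.0418, 'Choi': 0.0723}
```

What the numbers mean: 95 of 179 scoreable children are classified as rapid
gainers (CWG ≥ 0; the CWG scores have mean 0 and sd 1 by construction). The
functional PCA recovers the two planted components (σ̂² is the visit-level
measurement noise). The two-stage merge collapses 75 genera into 46
taxonomic groups by absorbing rare and collinear siblings. The functional
regression of growth curves on oral α-diversity yields a **negative**
coefficient curve (range −0.0056 to −0.0015 index units per diversity sd) —
lower oral diversity goes with higher growth index, the planted effect —
with the three significance measures shown (Choi is the preferred,
intermediate weighting).

## Command line

```sh
growthmicro simulate --seed 1 --outdir data/        # write a synthetic cohort
growthmicro run --config cfg.yaml [--seed N] [--outdir D] [--skip-flame]
```

`run` executes the full chain (data → CWG → curves → diversity → merge →
functional regressions → FLAME → covariate models), writing per-stage
artifacts (TSV/CSV/JSON/newick), a manifest with parameters and input
hashes per stage, and `report.json`.

## Acceptance script

`scripts/acceptance.py` re-runs the entire pipeline from scratch on the
default synthetic cohort (no external inputs):

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/growthmicro/   anthro, curves, diversity, merge, fosr, flame,
                   covariates, synthetic, pipeline, cli, trees, errors
tests/             unit, property (hypothesis) and acceptance suites
docs/methods.md    modelling choices, assumptions, limitations
```
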