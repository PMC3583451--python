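# Methods

This note records the models implemented in `markerimpute`, their
assumptions, the defaults that matter, and the design decisions taken where
more than one reasonable construction exists.

## Data model

Genotypes are an `m x n` matrix of allele-dosage codes, individuals in rows,
markers in columns, missing calls as NaN. Three codings are supported:
`-1/1` and `0/1` for fully inbred or dominant-scored two-state data (one
allele observation per individual) and `-1/0/1` for diploid dosage data
(heterozygote = 0, two observations per individual; the heterozygote
contributes half a count to each allele in MAF calculations). All algorithms
treat codes as continuous values; imputed matrices are real-valued and
flagged as such. Markers are unordered throughout — no map, no phasing.

## Imputation methods

All five methods return observed cells bit-exactly unchanged and leave no
missing cells.

**MNI.** Column means of the observed calls. Deterministic; the baseline
every other method is compared against. By construction its per-marker
accuracy `Rm²` is ≈ 0 (slightly negative, because the observed-cell mean is
not exactly the hidden-cell mean).

**kNNI** (`k` default 5). Distances are Euclidean between marker columns of
the mean-prefilled matrix, computed once (no iterative refresh) against the
doubled matrix `[M, flip(M)]`, where flipping reflects codes about the
coding midpoint; a marker in perfect negative LD therefore appears at
distance 0 through its flipped copy. A marker and its own flip are excluded
from its candidate list. Each missing cell is the `1/d²`-weighted average of
the values at the k nearest candidates *originally observed* in that row;
if fewer than k are observed the available ones are used, and if none are,
the mean prefill stands (counted in `n_fallback_cells_`). Zero-distance
candidates would make `1/d²` infinite, so the fill is then the unweighted
mean of all zero-distance candidates — the limit of the weighting scheme.
Ties at the k-th distance break by ascending marker index (stable sort) for
determinism. kNNI assumes nothing about the distribution of the data, but
its accuracy depends directly on tight LD partners existing.

**SVDI** (`k` default `min(m, n) // 10`, at least 1; `max_iter` 10, `tol`
0.02). Mean prefill; each iteration takes the top-k left singular vectors
`U_k` of the current completed matrix and regresses each marker's
*originally observed* entries on `U_k` by least squares (minimum-norm
solution if rank-deficient), predicting the missing entries. RSS sums the
squared model residuals over all originally observed cells of all markers
jointly; iteration stops when `|RSS₀ − RSS₁| / RSS₁ < 0.02` or at 10
iterations. Assumes an approximately low-rank (multivariate-normal) matrix.

**EMI** (`tol` 0.02, `max_iter` 50). Marker columns are modelled as i.i.d.
draws of an m-vector with mean `mu` (one entry per individual) and
covariance `Sigma` across individuals. E-step: fill each marker's missing
entries with the conditional expectation given that marker's observed
entries (a linear regression with Schur-complement coefficients); M-step:
re-estimate `mu` and `Sigma` (maximum-likelihood, divisor n) from the
completed matrix. Convergence is declared when the largest absolute change
over the concatenation of `mu` and the entries of `Sigma Sigmaᵀ` is at most
0.02. A tiny ridge (1e-9 on the diagonal) keeps `Sigma` invertible when
individuals are duplicated; a larger fallback ridge is applied only if a
solve fails. Assumes multivariate normality of the genotype codes.

**RFI** (`n_trees` 100, `max_iter` 10 sweeps, `min_samples_leaf` 5,
bootstrap bagging). Markers are processed from lowest to highest missing
fraction after a mean prefill. For each marker with holes, 100 regression
trees are grown on bootstrap samples of the originally observed rows with
all other markers (their current completed values) as candidate predictors
at every split (`mtry = n−1`; a `sqrt` option exists), and the ensemble mean
fills the holes, updating the matrix in place. After each full sweep the
relative change `ΔN = Σ(M₁−M₀)² / ΣM₁²` (over the columns that had holes)
is computed; the first time ΔN increases, the previous matrix `M₀` is
returned, otherwise iteration stops after 10 sweeps. Trees are seeded
deterministically from the imputer's `random_state`. Model-free, and by a
wide margin the most expensive method.

**Choosing k.** `select_k_cv` masks a random 5% of the observed cells per
fold (default 10 folds), imputes with each k on a grid, scores mean squared
error against the held-out truth, and picks the smallest k among the
minimisers. The 5% masking fraction and the MSE criterion are this
package's choices.

## Accuracy statistics

`R² = 1 − SSE/SST` between true and imputed values, computed **only over the
simulated-missing cells**, per marker (`Rm²`) and per individual (`Ri²`);
SST uses the mean of the same hidden-truth subset, so a mean-style predictor
scores ≈ 0 and values can be negative. Markers/individuals whose hidden
truth is constant have an undefined R²; they are excluded from aggregates
and counted in a diagnostics field. Aggregation follows the study design:
element-wise mean across missing-data replicates (`Rm²`-bar), median across
markers for a scalar summary, and a further mean across the three
missingness levels (`Rm²`-double-bar) for the factor analyses.

**Percent-correct equivalence.** Continuous imputations have no natural
"percent correct", so for a marker with minor-allele frequency `maf` and
accuracy `r²` we simulate two-state truths at that MAF and generate
imputations from the shrink-to-mean model
`imputed = mean + r²·(truth − mean) + e`, `var(e) = r²(1−r²)·var(truth)`,
which realises exactly `R² = r²` under the formula above; rounding to the
nearest legal code and comparing with the truth gives the percent correct.
At `r² = 0` this collapses to the marker mean and the percent correct tends
to `100·(1 − maf)` — low-MAF markers are "easy" in percent-correct terms
even when `Rm²` is 0, which is why the two scales disagree and why percent
correct cannot be compared across panels with different MAF spectra.
Negative accuracies are treated as 0 (the mean predictor).

## Factors affecting accuracy

**LD.** Pairwise `r² = D²/(p₁q₁p₂q₂)` with `D = x₁₁ − p₁p₂`; the two-locus
haplotype frequency `x₁₁` is the maximum-likelihood estimate from the
standard EM over unphased genotype pairs (only double heterozygotes carry
phase ambiguity; for inbred two-state data the EM reduces to direct
haplotype counting and coincides with the squared Pearson correlation of
dosages, which is used as a fast path). Individuals are used
pairwise-complete. A marker whose maximum `r²` against any other marker
reaches 0.5 is classified as being in at least moderate LD; the ratio of
low-LD to moderate-LD median accuracy quantifies how strongly a method
depends on LD.

**Relatedness.** Per individual: Euclidean distance to the closest other
individual (on a complete matrix — truth by default for synthetic runs),
and overall prediction error variance (PEV). For each marker j, the model
`y = 1μ + g + e` with `cov(g) = σ²g K₋ⱼ` is fitted, where `K₋ⱼ` is the
VanRaden-style centred cross-product relationship matrix built from all
markers except j, scaled to mean diagonal 1. The marker's PEV vector is the
diagonal of the genetic block of the inverted mixed-model coefficient
matrix, and the overall PEV is the sum across markers (renormalised if any
marker model fails). Variance components come from spectral REML per marker
(`mode='exact'`, default up to 500 markers) or are estimated once and
reused (`mode='fast'`); they can also be fixed, which is how the algebra is
unit-tested against direct dense MME inversion. Low PEV means a
well-connected individual whose missing calls are easy to predict.

**Fst screening.** Per-marker Weir–Cockerham-style variance-components Fst
over groups (families, or any labels), treating each inbred call as one
allele observation; used to exclude the top-quartile markers when checking
how much of the accuracy is driven by population subdivision.

**Binning rules** for the factor curves: MAF to the nearest tenth,
per-marker nonmissing count to the nearest multiple of 5, closest-relative
distance to the nearest whole number, PEV (which has no natural grain) to
decile bins; bin summaries are medians, empty bins are omitted.

## Genomic selection

**RR-BLUP.** `y = 1μ + Xu + e` with `u ~ N(0, σ²u I)` on column-centred
markers. The variance ratio `δ = σ²e/σ²u` is found by restricted maximum
likelihood on the spectral decomposition of `K = XcXcᵀ` (a bounded
one-dimensional search over `log δ`); effects are the ridge solution at the
REML ratio, `û = Xcᵀ(K + δI)⁻¹(y − μ̂)`, identical to the GBLUP form (tested
to 1e-6). A fixed ratio can be supplied, in which case the fit equals the
closed-form ridge estimator.

**Bayesian LASSO.** Park–Casella Gibbs sampler with the
scale-mixture-of-normals representation of the double-exponential prior:
block draw of effects from `N(A⁻¹Xcᵀ(y−μ), σ²A⁻¹)` with
`A = XcᵀXc + D⁻¹_τ`, scaled-inverse-χ² for `σ²`, inverse-Gaussian for
`1/τ²ⱼ`, and `λ² ~ Gamma(shape p + 0.1, rate Στ²/2 + 0.1)`. Defaults are
10 000 iterations with 2 000 burn-in; the study pipeline uses shorter,
seeded chains (2 000 / 500) because GS accuracy, not posterior tails, is
the quantity of interest. Chains are bit-reproducible under a seed.

**Cross-validation.** A single random k-fold partition (default 10) per
replicate, no stratification; each fold's GEBVs come from a model trained
without it, accuracy is the per-fold Pearson correlation between GEBV and
the phenotype (breeding-value estimates), averaged across folds. Reported
standard errors are `std/√n_replicates` across missing-data replicates.

## Synthetic panels

The generator emulates an elite inbred breeding panel rather than any
coalescent-exact population:

* **Founders and historic LD.** Founder lines carry one haplotype each;
  allele frequencies are U-shaped Beta(0.5, 0.5) truncated below a MAF
  floor (default 0.05). With probability `founder_ld` (default 0.9) a
  marker copies the previous marker's founder alleles along the hidden
  chromosome order, with a 5% per-founder flip. This Markov structure is
  what creates marker pairs in population-wide near-perfect LD — the
  redundancy that real DArT/GBS panels show and that neighbour-based
  imputation exploits; with `founder_ld = 0` all LD is pedigree-derived and
  much weaker.
* **Pedigree.** Each family is a biparental cross of two random founders
  advanced by `selfing_generations` (default 8) of single-seed descent,
  with Poisson(`recomb_rate`, default 0.1 per chromosome per meiosis)
  crossovers at hidden uniform positions. Residual heterozygosity is
  ~`0.5^g`. Defaults: 20 families x 10 lines from 20 founders, 500 markers
  on 10 chromosomes; with these settings ~90% of markers have a partner at
  `r² ≥ 0.5`, comparable to the denser of the empirical panels this kind
  of study uses. Monomorphic markers get their founder alleles re-drawn.
* **Phenotypes.** Standard-normal additive effects at `n_qtl` (default 40)
  random markers; noise scaled so the realised heritability matches the
  request (default `h² = 0.5`).
* **Missingness.** Per marker, a target fraction is drawn from a
  right-skewed Beta rescaled to the level's cap — shapes (2.0, 1.3),
  (2.33, 1.0), (3.2, 0.5) for caps 0.20/0.50/0.70, i.e. mode near the cap
  with a long left tail, mean total missingness ≈ 12/35/60% — and
  `round(fraction · n_observed)` observed cells are hidden uniformly
  without replacement (never below one remaining observation). An empirical
  list of fractions can replace the parametric stand-in. Ten replicates per
  level is the study default.

What the generator does **not** emulate: genotyping error (truth is
error-free), multi-allelic or dominance-coded loci beyond the two-state
codings, selection or migration structure beyond family membership, and
ascertainment of markers. Passing tests on these panels therefore
demonstrate the algorithms' behaviour under high LD and close relatedness
with random missingness — the regime where map-free imputation is
advertised to work — not performance on, say, low-LD diversity panels,
where neighbour-based methods degrade sharply (visible by setting
`founder_ld = 0`).

## Study pipeline and problem sizes

`run_experiment` executes replicates x levels x methods x GS models from one
config; every cell's seed derives from the base seed via SHA-256 (kept below
2³¹), so cells are independently reproducible and a deleted output
regenerates identically. Failures are recorded per cell without aborting
siblings. The reference desk-scale study (`ExperimentConfig.desk_scale`)
uses a 100 x 200 panel (10 families x 10 lines, 16 founders, 5 chromosomes)
with 2 replicates per level and RR-BLUP only — the same design as the full
defaults, sized so the complete factorial including RFI at its full 100
trees finishes in minutes on a single CPU; the test suite and
`scripts/acceptance.py` both run exactly this study.

## Numerical choices and degenerate inputs

* All-missing markers are rejected before any imputation; masking always
  leaves at least one observed call per marker.
* Undefined accuracies (constant hidden truth), monomorphic LD pairs and
  monomorphic Fst markers are NaN-flagged and excluded from medians rather
  than silently zeroed.
* kNNI zero-distance rule and stable tie-breaks as above; SVDI uses
  minimum-norm least squares under rank deficiency; EMI and the GRM/PEV
  algebra use small explicit ridges (1e-9 / 1e-8) rather than
  pseudo-inverses; REML searches `log δ` on [−12, 12].
* `ΔN` and RSS denominators guard against exact zero with a 1e-300 floor.

## Known limitations

* EMI's per-marker conditional fill refits a dense `Sigma_OO` solve per
  marker and iteration; on panels much larger than ~1 000 individuals a
  low-rank or pattern-grouped implementation would be needed.
* RFI's `mtry = n−1` follows the original recipe and dominates runtime;
  the `sqrt` option trades fidelity for speed.
* Exact-mode PEV fits n REML models; above 500 markers the shared-variance
  fast mode is used by default.
* The Bayesian LASSO uses a dense p x p Cholesky per iteration — adequate
  for marker counts in the low thousands, not for genome-scale p.
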