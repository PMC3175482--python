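# Methods

## Overview

`stpls` mines multivariate genotype–phenotype associations in a panel of
genomes (the motivating system is a panel of 36 *Saccharomyces cerevisiae*
strains measured for 20 growth phenotypes against the S288C reference gene
set). The method has three stages:

1. **Genotype features.** Each genome is summarised against a reference
   gene set by best-hit alignment scores, converted to approximate
   evolutionary distances.
2. **Sparse regression.** One Soft-Thresholding PLS (ST-PLS) model per
   phenotype relates the n × p distance matrix **X** to the phenotype
   vector **y** under the linear model E(**y**) = **Xβ**, selecting genes
   while fitting.
3. **Association statistics.** Selected gene sets are post-processed:
   permutation nulls, pleiotropy, Fisher enrichment of gene categories,
   evolutionary-rate contrasts, and coordinate exports for biplots and
   chromosome maps.

## Genotype features

For reference gene *r<sub>j</sub>* the self-alignment score
S(r<sub>j</sub>; r<sub>j</sub>) under unit match scoring equals its length
in residues. The best hit of genome *g<sub>i</sub>* against *r<sub>j</sub>*
gives a maximum bit-score S(g<sub>i</sub>; r<sub>j</sub>), normalized as

    s_ij = clamp( S(g_i; r_j) / S(r_j; r_j),  1/20,  1 )

A (genome, gene) pair with no alignment hit scores 0 and therefore floors
at 1/20: absence of detectable homology is treated as maximal divergence.
Genes whose normalized score is below 0.5 in *every* genome are discarded
as uninformative. The retained scores are mapped to distances with the
20-state (amino-acid) Jukes-Cantor form

    d = -(19/20) · ln( (20 s - 1) / 19 )

whose saturation point is exactly s = 1/20 — the reason for that floor.

Numerical choices:

- **Saturation floor.** At s = 1/20 the transform diverges; the log
  argument is floored at ε = 1e−8 (configurable), giving a finite cap
  D_max = −0.95 ln ε ≈ 17.5. Finite features are required downstream.
- **Upper clamp.** Translated-nucleotide bit-scores live on a different
  scale from the unit-match self-score, so the ratio can exceed 1; values
  above 1 are clamped to 1 (distance 0), since s > 1 is undefined under
  the substitution model.
- Distances of 0 occur iff the clamped normalized score is exactly 1.

What this feature scheme does *not* model: paralogous hits within a genome
(only the best hit counts), alignment coverage, and nucleotide-level
(4-state) distances.

## Phenotype preparation

Missing phenotype cells are imputed by K nearest neighbours (default
K = 5, suitable for a few dozen strains): neighbours are the other strains
with the target column observed, ranked by Euclidean distance over the
columns observed in both rows, computed on per-column standardized values;
the imputed value is the unweighted mean of the K neighbours' values on
the original scale. Imputed values therefore always lie within the
observed range of their column.

All model fitting standardizes columns of **X** and **y** to mean 0,
sd 1 with the sample (n−1) convention. Held-out rows in cross-validation
are standardized with training-fold parameters only, so no information
leaks from the held-out strains. Inside a model fit, a genotype column
that is constant across the training rows carries no information and is
mapped to zeros rather than aborting the fit; the strict `standardize`
function (used for phenotypes) still rejects zero-variance columns.

## ST-PLS

The orthogonal-scores NIPALS PLS1 recursion with X- and y-deflation is
used. At component a, the raw loading weight w = X<sub>a</sub>ᵀy<sub>a</sub>
is (i) scaled by its largest absolute entry, (ii) soft-thresholded
w<sub>j</sub> ← sign(w<sub>j</sub>)(|w<sub>j</sub>| − δ)₊, (iii)
Gram-Schmidt orthogonalized against previously accepted weight vectors
(a no-op for the first component), and (iv) normalized. Scores
t = X<sub>a</sub>w, loadings p = X<sub>a</sub>ᵀt/tᵀt and
q = y<sub>a</sub>ᵀt/tᵀt, and deflation then proceed as in standard PLS1.
Coefficients for a k-component model are

    beta = W (Pᵀ W)⁻¹ q

on the standardized scale; the selected gene set is {j : beta_j ≠ 0}.
With δ = 0 the procedure reduces exactly to PLS1 (verified against an
independent NIPALS implementation and scikit-learn to ~1e−16).

Edge cases:

- Because the weight vector is scaled by its maximum before thresholding,
  the largest coordinate always survives step (ii); the over-shrunk state
  arises when orthogonalization annihilates the surviving direction or
  the residual covariance is exhausted. If that happens after component
  a ≥ 1, the model is truncated at the last successful component and
  flagged; if no first component exists, `OverShrunkError` is raised.
- Ties in the scaled maximum need no tie-break (scaling only); in the
  extreme-δ regime ties can yield multiple survivors, accepted as-is.
- `beta` is kept on the standardized scale; back-transformation happens
  only in `predict`, so selection and biplots operate on standardized
  quantities.

## Model selection

A random leave-3-out cross-validation partitions the strains into
⌊n/3⌋ disjoint segments (the last segment absorbs any remainder, so
segments have 3–5 members). For every segment and shrinkage level one
path fit to the maximum component count yields predictions at every
(k, δ) cell of the grid (components 1–10 by default; shrinkage 0.70,
0.73, …, 0.97). Pooled squared errors give the CVRMSE per cell; its
standard error is the sd of segment-level RMSEs divided by √(#segments)
(standard one/two-SE-rule practice — the estimator is not otherwise
pinned down). A cell is invalid if any fold could not reach its k.

The minimum CVRMSE is itself noisy, so a **slack** of `slack_se` (default
2) standard errors is allowed: candidate cells satisfy CVRMSE ≤ min +
2·SE(min cell) and mean selected-gene count ≥ `min_genes` (default 25,
keeping gene lists comparable across phenotypes for enrichment). Among
candidates the largest δ wins, ties broken by smallest k — sparsity is
the study's goal; the opposite ordering is available via `prefer="k"`.
If no candidate reaches `min_genes` the constraint is dropped with a
warning. The chosen cell is refit on all strains.

Model quality is the Willmott index of agreement

    d = 1 − Σ(p_i − o_i)² / Σ(|p_i − ō| + |o_i − ō|)²

computed on the pooled cross-validated predictions of the chosen cell;
d ∈ [0, 1] analytically and the return value is clamped to that interval
to absorb ulp-level cancellation error.

**Permutation null.** Row-shuffling **X** preserves the gene-gene
correlation structure while severing the genotype–phenotype link. Each
replicate reruns the full CV + selection + refit pipeline and records the
cross-validated d-index and the selected-gene count. Randomness flows
from a single seed through named substreams (one for the permutations,
one CV stream per replicate), so nulls are reproducible and replicates
are independent.

## Association statistics

- **Enrichment** of a category within a selected set uses the one-sided
  Fisher exact test (hypergeometric upper tail) in the enrichment
  direction, with the complementary one-sided tail reported for
  depletion; fold ratio is observed/expected, (x/n_sel)/(K/N). Families
  of categories are Benjamini-Hochberg adjusted; significance marks are
  `*`/`**`/`***` at raw p < 10/5/1% and bullet marks at the same levels
  for adjusted p.
- **Pleiotropy**: genes selected in at least a fraction (default 25%,
  ceiling convention: 5 of 20) of the phenotypes.
- **Rate contrast**: Welch (unequal-variance) one-sided t-test of
  mean evolutionary rate, selected vs other genes. Welch and one-sided
  were design choices; rates are consumed as precomputed per-gene
  numbers.
- **Paralogs**: a gene is flagged iff it has a non-self blastp hit with
  E < 1e−10 covering ≥ 50% of its length.
- **Biplots**: strain scores are the latent component scores T; gene
  coordinates are *correlation* loadings (Pearson correlation of each
  standardized gene column with each score column), bounded in [−1, 1],
  matching the correlation-biplot convention. Rendering is out of scope;
  only coordinates are exported.

## Synthetic data

The generators emulate the statistical shape of the study, not its
biology:

- **Genotype matrix**: latent Gaussians with block equicorrelation ρ
  (blocks of 20 genes, ρ = 0.3 by default), squashed monotonically into
  the valid normalized-score range and mapped through the Jukes-Cantor
  transform. This captures correlated functional neighbourhoods; it does
  not model phylogenetic (strain-tree) covariance, alignment noise, or
  gene-length effects.
- **Phenotypes**: y = Z_support β + ε with Z the standardized genotype
  columns, |β| = `effect_size` with random signs, ε ~ N(0, σ²); the
  support is spread across distinct blocks when possible, so signal
  variance ≈ s·effect². Defaults: n = 36, p = 1000, s = 10, |β| = 1,
  σ = 0.5.
- **Score tables**: normalized scores are planted directly (with columns
  planted entirely below 0.5 and pairs planted as absent), and raw scores
  are emitted as planted-score × integer self-score; the expected matrix
  is computed with the same division the pipeline performs, making the
  end-to-end feature test exact to floating-point.
- **Annotations**: a category whose membership odds are boosted inside
  the true support (odds = 1 ⇒ independence); Gamma-distributed
  evolutionary rates with group means 0.100 (support) vs 0.078 (other),
  matching the influential/non-influential contrast the method is meant
  to expose.

Passing tests on these fixtures show the machinery is correct and that
the selector behaves as designed under a known sparse linear truth; they
do not demonstrate recovery of real trait-influencing genes, where
effects are weaker, phenotypes non-linear, and strains phylogenetically
dependent.

### A note on support recovery at the default conditions

At n = 36, p = 1000, s = 10 equal independent effects and σ = 0.5, each
true gene's population correlation with y is capped at
1/√(s + σ²) ≈ 0.31, while the largest of ~990 null sample correlations
(sd 1/√35 ≈ 0.17) is typically ≈ 0.6. Sparse selections of ~25–60 genes
therefore recover only a minority of the support (an oracle keeping the
top 25 genes by |correlation| achieves recall ≈ 0.4); near-complete
recovery appears only for very loose models that keep hundreds of genes.
This is an intrinsic property of the signal-to-dimension regime, not of
the selector: the two-SE slack rule intentionally trades a little
prediction error for much sparser gene lists. The permutation-null
contrast (selected sets under row-shuffled X share essentially no genes
with the truth) is unaffected.

## Problem sizes used in the test suite

Unit and property tests run at desk scale (n ≤ 40, p ≤ 250); the
whole-pipeline studies use the generator defaults above (n = 36,
p = 1000, 20 seeds), and the exhaustive Fisher check covers every 2×2
table with universe size ≤ 200. These sizes were chosen to exercise the
p ≫ n regime the method targets while keeping runs reproducible on a
single CPU.

## Known limitations

- The normalized-score upper clamp at 1.0 is a modelling choice forced by
  the scale mismatch between translated-alignment bit-scores and
  unit-match self-scores.
- KNN imputation's K and distance convention are package choices
  (standardized distances; plain Euclidean over jointly observed
  columns).
- Only univariate-response (PLS1-style) models are fitted — one model per
  phenotype; no multi-response mode.
- The alignment searches themselves (tblastx/blastp) are not run by this
  package; it consumes their tabular output.
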