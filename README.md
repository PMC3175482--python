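# stpls

Genotype–phenotype mining for strain panels with BLAST-derived
evolutionary-distance features and **Soft-Thresholding Partial Least
Squares (ST-PLS)** regression.

Given (i) pairwise-alignment best-hit scores of a set of genomes against a
reference gene set, (ii) a strain × phenotype table, and (iii) optional
gene annotations, the package:

1. builds an n × p genotype matrix **X** of approximate Jukes-Cantor
   evolutionary distances — normalized best-hit score
   s = clamp(S(gᵢ; rⱼ)/S(rⱼ; rⱼ), 1/20, 1), genes with s < 0.5 everywhere
   discarded, then d = −(19/20)·ln((20s − 1)/19);
2. fits one sparse regression per phenotype under E(**y**) = **Xβ**, where
   each PLS loading weight w = Xᵀy is max-scaled, soft-thresholded
   (|wⱼ| − δ)₊, orthogonalized and normalized, so that
   **β** = W(PᵀW)⁻¹q is sparse and the nonzero coefficients name the
   associated genes; the component count k and shrinkage δ are chosen by
   random leave-3-out cross-validation with a two-standard-error slack
   rule favouring sparse models, subject to a minimum selected-gene count;
3. evaluates each model with Willmott's index of agreement
   d = 1 − Σ(pᵢ−oᵢ)²/Σ(|pᵢ−ō|+|oᵢ−ō|)² on pooled cross-validated
   predictions, against permutation nulls obtained by row-shuffling **X**;
4. summarises the selected gene sets: pleiotropy (genes influencing ≥25%
   of phenotypes), one-sided Fisher exact enrichment of annotation
   categories with Benjamini-Hochberg correction, Welch t-contrast of
   evolutionary rates, correlation-biplot and chromosome-map coordinate
   exports.

It is aimed at the "large p, small n" regime (e.g. 36 yeast strains ×
thousands of reference genes), where ordinary least squares is hopeless
and univariate scans ignore the multivariate structure. A seeded
synthetic-data module generates score tables, block-correlated genotype
matrices, sparse-truth phenotypes and planted-enrichment annotations, so
the whole pipeline is testable without any downloads.

See `docs/methods.md` for the model, its assumptions and numerical
choices.

## Worked example

```python
import numpy as np
from stpls import (SimulationConfig, simulate_genotype_matrix,
                   simulate_phenotypes, run_selection, permutation_null)

cfg = SimulationConfig(n=36, p=500, support_size=5,
                       effect_size=1.5, noise_sd=0.4, seed=11)
X = simulate_genotype_matrix(cfg)          # 36 strains x 500 genes
y, truth = simulate_phenotypes(X, cfg)     # sparse linear truth, 5 genes

choice = run_selection(X.frame, y, seed=1)           # CV + slack rule + refit
null = permutation_null(X.frame, y, n_perm=19, seed=2)

print(f"chosen model: k={choice.k} components, delta={choice.delta:.2f}")
print(f"cross-validated d-index {choice.cv_d_index:.3f}")
print(f"selected genes: {choice.model.n_selected}, true support recovered: "
      f"{len(choice.model.selected & set(truth.support))}/{len(truth.support)}")
print(f"null d-index 95th percentile: {np.quantile(null['d_index'], 0.95):.3f}")
```

prints

```
chosen model: k=10 components, delta=0.91
cross-validated d-index 0.750
selected genes: 12, true support recovered: 5/5
null d-index 95th percentile: 0.608
```

The fitted model keeps 12 of 500 genes, including all 5 planted ones, and
its cross-validated agreement (0.750) clearly exceeds what row-shuffled
genotypes achieve (null 95th percentile 0.608) — the model found signal,
not noise.

The same pipeline is available from the shell:

```bash
stpls simulate --n 36 --p 500 --phenotypes 20 --seed 7 --out fixture/
stpls build-matrix --scores fixture/scores.tsv --refs fixture/refs.tsv --out X.tsv
stpls impute --phenotypes fixture/phenotypes.tsv --k 5 --out imputed.tsv
stpls fit --matrix X.tsv --phenotypes imputed.tsv --phenotype pheno_01 \
      --seed 1 --out model.json
stpls run --config run.yaml        # full pipeline from a config file
```

`stpls run` writes a self-describing run directory: the genotype matrix,
imputed phenotypes, one JSON summary per phenotype (chosen k, δ, d-index,
selected genes), permutation-null draws, the pleiotropy table and
per-phenotype enrichment tables with significance marks.

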