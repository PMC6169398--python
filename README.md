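# clinalscan

Landscape-genomics analysis of clinal adaptation: from a genome-wide SNP
panel plus georeferenced climate and common-garden phenotype tables to
population structure, variance partitioning, association scans and
candidate-gene enrichment.

The package is aimed at crop population genomicists working with
georeferenced landrace collections — the motivating setting is a highly
selfing cereal panel sampled along a steep precipitation gradient, where the
question is how much genome-wide nucleotide variation reflects clinal
adaptation rather than neutral structure and isolation by distance.

## What it computes

* **Population-genetic summaries** — MAF spectrum, observed heterozygosity
  and inbreeding F, windowed nucleotide diversity π, Weir–Cockerham F_ST
  (per site and ratio-of-sums per window), Tajima's D in windows, LD decay
  (binned r² with a smoothing spline and threshold crossings).
* **Population structure** — LD pruning, PCA (center 2p̂, scale √(2p̂q̂)),
  DAPC (k-means on PC scores with BIC model selection, then discriminant
  axes), IBS distances and neighbor-joining trees.
* **Variance partitioning (RDA)** — adjusted-R² decomposition of the SNP
  matrix on climate and space predictor sets,

  R² = tr(SS_fit)/tr(SS_tot),  adjR² = 1 − (1 − R²)(n − 1)/(n − p − 1),

  into [a] climate-unique, [b] climate∩space collinear, [c] space-unique and
  residual ([a]+[b]+[c]+res = 1 exactly), with a permutation test for [b]
  that randomizes individuals (p = (1 + #{perm ≥ obs})/(n_perm + 1)).
* **Association** — common-garden BLUPs (y = μ + garden + accession + ε by
  REML), VanRaden kinship, EMMA-style mixed-model GWAS (Q + K), multi-locus
  MLMM with stepwise cofactors, structure-naive GLM scans for climate
  variables, top-quantile outlier selection.
* **Enrichment** — colocalization of outlier SNPs or high-D windows with
  genes within 100 kb, 2×2 chi-square candidate enrichment, and
  whole-genome gene-set permutation tests.
* **Synthetic landscapes** — a generator that plants known structure
  (Balding–Nichols groups at a target F_ST), inbreeding, a climate gradient
  collinear with latitude, logistic allele-frequency clines, phenotypes and
  candidate genes, with truth files, so the whole pipeline is testable
  without any external data.

## Worked example

```python
import numpy as np
from clinalscan import (LandscapeConfig, simulate_landscape, prepare_response,
                        permute_collinear_test, dapc_find_clusters, sample_qc,
                        weir_cockerham_fst)

gm, samples, truth = simulate_landscape(LandscapeConfig(seed=1))
Y = prepare_response(gm.dosages)
vp = permute_collinear_test(Y, samples.climate_matrix(),
                            samples.space_matrix(), n_perm=999, seed=1)
print(f"climate|space unique: {100*vp.frac_climate_unique:.1f}% / "
      f"{100*vp.frac_space_unique:.1f}%")
print(f"climate-space collinear: {100*vp.frac_collinear:.1f}% "
      f"(permutation p = {vp.perm_p_collinear:.3f})")

dapc = dapc_find_clusters(gm, k_max=6, seed=1)
_, fst = weir_cockerham_fst(gm, dapc.assignments)
f = np.mean([q.inbreeding_f for q in sample_qc(gm)])
print(f"DAPC groups: k = {dapc.k_selected}, weighted F_ST = {fst:.2f}")
print(f"mean inbreeding coefficient: {f:.2f}")
```

prints

```
climate|space unique: 1.2% / -0.0%
climate-space collinear: 3.2% (permutation p = 0.001)
DAPC groups: k = 3, weighted F_ST = 0.16
mean inbreeding coefficient: 0.83
```

Reading: on this 300-accession, 5000-SNP synthetic landscape about 3% of the
SNP variance is explained by climate collinear with space — the signature of
clinal adaptation along a gradient that itself runs with latitude — while
climate and space alone each explain ≈1% or less; the permutation test puts
the collinear fraction far outside the null (p = 0.001 is the resolution of
999 permutations). DAPC recovers the three planted genetic groups, and the
inbreeding coefficient reflects the selfing regime (F ≈ 0.8). A negative
adjusted-R² fraction is ordinary small-sample behavior and is reported as
computed.

The same analyses run from the shell: `clinalscan simulate`, `clinalscan
stats pi|fst|tajima|ld|qc`, `clinalscan structure pca|dapc|nj`, `clinalscan
varpart`, `clinalscan assoc blup|mlm|mlmm|glm`, `clinalscan enrich
chisq|permute`, and `clinalscan run --config run.yaml --out results/run1`
for the full checkpointed pipeline (QC → diversity → structure → RDA →
scans → enrichment, with a merged `summary.json`).

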