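# Methods

`clinalscan` implements a landscape-genomics workflow for detecting clinal
adaptation in a selfing crop panel: population-genetic summaries, population
structure, variance partitioning of SNP variation into climate and space
components, phenotype and environmental association scans, and
candidate-gene enrichment. This note records the models, the numerical
choices, and what the bundled synthetic landscape does and does not emulate.

## Data model

Genotypes are diploid ALT-dosages (0/1/2) with an explicit missing sentinel
(−1); every statistic masks missing calls rather than imputing silently
(mean- or mode-imputation happens only where a method requires complete data
and is stated below). Variants are biallelic SNPs sorted by natural
chromosome order and position. All internal interval arithmetic is 0-based
half-open; GFF3 and VCF coordinates are converted at the boundary.

## Population-genetic statistics

* **Allele statistics and filters.** Frequencies use non-missing calls only.
  The filter defaults mirror a GBS pipeline: site missingness < 0.2,
  monomorphic sites dropped, minor-allele count ≥ 3 (removes singletons and
  doubletons), MAF ≥ 0.03 for GWAS. The filter report attributes each removed
  site to the first failing rule in the order missingness, monomorphic, MAF,
  MAC.
* **π.** Per site, the unbiased estimator 2p̂q̂·2n/(2n−1) (equal to the mean
  pairwise difference among the 2n observed alleles); summed per window and
  divided by the window span in bp. Windows tile each chromosome from 0,
  half-open, last partial window kept.
* **F_ST.** Weir & Cockerham (1984) variance components a, b, c per site for
  r populations with unequal sample sizes, using observed heterozygote
  frequencies; windowed and global estimates are ratio-of-sums Σa/Σ(a+b+c)
  (the "weighted" estimator). Negative per-site values are retained —
  clamping would bias the components.
* **Tajima's D.** Computed per window from S and the summed mean pairwise
  difference with the 1989 constants. The chromosome count is the rounded
  mean number of observed alleles over the window's segregating sites; on
  complete (imputed) data this is exactly 2n. A `ploidy=1` mode treats rows
  as haplotypes, used for coalescent calibration. Windows with S = 0 or a
  non-positive variance term report a missing value.
* **LD decay.** r² is the squared Pearson correlation of dosage vectors on
  pairwise-complete samples, restricted to within-chromosome pairs up to a
  maximum distance, binned by distance; a cubic smoothing spline (smoothing
  factor scaled to a configurable effective df, default 8) runs through bin
  means, and threshold crossings (e.g. r² = 0.1) and the half-initial-value
  distance are read off the smoothed curve by linear interpolation.
* **Per-sample QC.** Observed heterozygosity over non-missing polymorphic
  sites; F = 1 − O(het)/E(het) with the expectation from panel-wide 2p̂q̂
  averaged over the sample's own non-missing sites.

## Population structure

PCA centers dosages by 2p̂ and by default scales by √(2p̂q̂); missing dosages
are mean-imputed (zero after centering). Scores come from SVD with a
deterministic sign convention (largest-|loading| element positive). DAPC
follows the find-clusters recipe: k-means (k-means++, 10 starts, seeded) on
retained PC scores for k = 1..k_max, model selection by
BIC(k) = n·log(WSS/n) + k·log(n) (ties to the smallest k), then linear
discriminant axes on the selected partition. The number of retained PCs
defaults to the smallest set reaching 80% of variance — on genotype data this
keeps most PCs, which is deliberate: it leaves the null (panmictic) BIC curve
minimized at k = 1 while strong structure still dominates the retained space.
LD pruning is greedy and windowed (drop the later member of any pair with
r² > 0.5, default 50-kb windows, half-window step). Distances are
1 − mean IBS share; neighbor joining is delegated to scikit-bio with negative
branch lengths clamped at zero.

## Variance partitioning (RDA)

The genotype matrix (mean-imputed, column-centered) is regressed on
standardized predictor blocks; explained variance is
R² = tr(SS_fit)/tr(SS_total) and is adjusted with Ezekiel's formula using the
predictor block's rank (rank-deficient blocks lose collinear directions via
QR with a warning). The two-set partition is the classical identity:
climate-unique [a], space-unique [c], collinear [b] = adjR²(C) + adjR²(S) −
adjR²(C+S), residual = 1 − adjR²(C+S); the four fractions sum to one exactly.
The implementation works entirely through n×n projection matrices and the
cross-product S = YYᵀ, so the SNP count only enters once and the permutation
test (shuffle sample rows of Y, recompute [b], upper-tail add-one p-value) is
cheap at thousands of permutations. Genotype columns are centered but not
variance-scaled by default (a scaling flag exists); fractions are reported as
computed, including small negative values. An alternative mode permutes the
climate block only (climate conditional on space); the default randomizes
individuals.

This partition was verified against R `vegan::varpart` on a small fixture
(agreement to 1e-8; note vegan's `indfract` rows are [a] = X1|X2,
[b] = X2|X1, [c] = joint, [d] = residual).

## Phenotypes and association

* **BLUPs.** y = μ + garden (random) + accession (random) + residual, fit by
  REML (Nelder–Mead on the two log variance ratios with the residual
  profiled out); accession predictions are shrinkage estimates
  μ + σ̂²_a Z_aᵀ V̂⁻¹(y − μ̂). A single-garden design fixes the garden
  variance at zero with a warning. In balanced single-garden designs the fit
  reproduces the closed-form shrunken accession mean to 1e-8.
* **Kinship.** Centered (VanRaden) K = ZZᵀ/(2Σp̂q̂) after mean-imputation.
* **Mixed-model scan.** One spectral decomposition of K; REML for
  δ = σ²_e/σ²_g under the null model via a 100-point log-δ grid plus bounded
  refinement; then per-SNP generalized least squares with fixed effects
  (intercept + first 3 PCs + SNP) on the rotated data, Wald t-tests.
  Non-PSD kinship gets an eigenvalue floor at zero with a warning. With
  K = I and δ̂ → ∞ the scan reduces to ordinary least squares (verified to
  1e-6).
* **Multi-locus scan (MLMM).** Forward stepwise: add the most significant
  SNP as a fixed cofactor when it passes the threshold (default Bonferroni
  0.05/m — the marker count used for the threshold is configurable, since a
  printed threshold need not equal α/m exactly), re-estimate variance
  components, repeat up to `max_cofactors`; a backward pass reports which
  cofactors remain significant in the final model. The reported scan is the
  last forward step.
* **Environmental scan.** A deliberately structure-naive per-SNP simple
  regression of the climate variable on dosage (the regression direction
  does not affect the t-test p-value). Correcting for structure would
  remove exactly the clinal signal of interest, at the cost of false
  positives — the calibration tests quantify the trade. Outliers are the
  top empirical p-value quantile (default 1%), ties at the cutoff all
  included.

## Colocalization and enrichment

A gene is hit when the gap between its interval and the nearest outlier SNP
(or high-D window) is at most 100 kb; the gap is measured between 0-based
half-open intervals, so a SNP at 1-based 150,001 is 45,000 bp from a gene
ending at 105,000. Enrichment of the a-priori candidate set over all
annotated genes is tested by a 2×2 Pearson chi-square without continuity
correction, and by a whole-genome permutation that redraws candidate-sized
gene sets uniformly without replacement (n_perm default 1000, add-one
p-value). "High-D" defaults to D > 0; a percentile threshold is recommended
when the genome-wide D distribution is shifted (structured or bottlenecked
panels shift D globally, leaving D > 0 uninformative). Permuted gene sets
are not matched for length or chromosome by default.

## The synthetic landscape

The generator emulates the statistical regime this analysis expects from a
selfing landrace panel on one climatic gradient:

* **Structure**: k groups (default 3) with Balding–Nichols Beta frequencies
  around the ancestral frequency at Wright's F = 0.2. Balding–Nichols was
  chosen over a demographic coalescent because differentiation is specified
  directly by F_ST, which is how the target regime is described; the
  Weir–Cockerham estimate on generated panels lands at 0.201 ± 0.003.
* **Site-frequency spectrum**: rare-dominated — ancestral minor-allele
  frequencies log-uniform on [0.005, 0.5] (ALT/REF symmetric), giving ~30–40%
  of SNPs below MAF 0.01, as in reduced-representation SNP panels.
* **Inbreeding**: each genotype is drawn selfed (g ∈ {0, 2}) with
  probability F_self (default 0.8) or Hardy–Weinberg otherwise, producing
  genotype frequencies p² + pqF, 2pq(1 − F), q² + pqF. Estimated sample F
  comes out ≈ 0.83 (slightly above the input because panel-wide expected
  heterozygosity includes the Wahlund effect of group structure).
* **Geography and climate**: samples sit on a latitude line; the leading
  climate axis (an annual-precipitation proxy, mm) is built to correlate
  with latitude at r = −0.86; nine companion variables (four precipitation,
  five temperature) are noisy copies at fixed correlations.
* **Clinal loci**: a configurable subset of SNPs whose allele frequency
  follows a logistic cline on the standardized climate axis, independent of
  group membership, from intermediate base frequencies U(0.2, 0.8) — the
  frequency regime of stable clines maintained by a gradient. The default
  (500 of 5000 loci, slope 0.9 logit per climate SD) was calibrated once so
  the realized climate-collinear adjusted-R² fraction is 0.030, the regime
  the package targets. A `clinal_cluster_size` option places clinal loci in
  runs of consecutive SNPs, emulating adaptive regions wide enough to
  dominate a 100-kb window (used by the enrichment tests).
* **Phenotypes**: per-garden records y = μ + garden + genetic + residual
  with the residual scaled to a requested within-garden heritability.
* **Genes**: uniform gene placement with a configurable fraction of
  candidates placed within a window of true clinal loci.
* **Coalescent sites**: neutral haplotypes for Tajima's-D calibration are
  simulated with msprime (ploidy 1, population size 1, mutation rate θ/2 on
  a unit sequence, infinite sites), so E[S] = θ·a₁ exactly; ancestry and
  mutation seeds are decorrelated through a SeedSequence.

What it does **not** emulate: linkage disequilibrium from shared ancestry
(sites are exchangeable given the group and cline structure, so LD-decay
curves on generated panels are flat at the 1/n baseline; LD behavior is
tested on purpose-built block designs instead), genotyping error and
missingness mechanisms, realistic recombination or demographic history, and
selection as a forward process. Passing tests therefore demonstrate
correctness and calibration of the estimators under the stated statistical
regime, not performance on any particular empirical panel.

## Problem sizes and determinism

Test and acceptance runs use desk-scale panels (120–400 samples,
2000–5000 SNPs, 10 chromosomes × 2 Mb, 99–999 permutations), chosen so the
whole suite exercises every stage end to end on one CPU; the genome layout
keeps ~10–25 SNPs per 100-kb window so window statistics behave like their
full-scale counterparts. Every stochastic component takes an explicit seed
and draws from a single numpy Generator; pipeline reruns with the same
config produce byte-identical summaries, and each stage checkpoints its
outputs so deleting one stage file recomputes only that stage.

## Known limitations

* The BLUP model treats gardens and accessions as uncorrelated random
  effects; genotype-by-garden interaction is not modeled.
* Tajima's D with residual missingness uses a per-window mean chromosome
  count; with highly variable missingness a per-site treatment would be
  preferable.
* The MLMM reports the last forward-step model rather than applying an
  extended-BIC model-selection criterion over the path.
* Permutation p-values are bounded below by 1/(n_perm + 1); headline runs
  use 999 permutations.
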