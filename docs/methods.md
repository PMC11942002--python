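# Methods

This note documents the models, estimators, defaults and numerical choices
behind `dermsig`, and what the synthetic-data validation does and does not
demonstrate about real data.

## Synthetic study model

The generator emulates a four-arm topical-treatment experiment on a
reconstructed skin equivalent: control (CTL) plus three compounds (LYS, CDL,
ZDL), `n_replicates = 3` samples per arm, over `n_genes = 14,600` detectable
genes by default.

**Counts.** Gene *g* in sample *j* (group *G*) is negative-binomial,

    x_gj ~ NB(mean = L_j · p_g(G),  variance = mean + φ · mean²)

with baseline relative abundances μ_g drawn log-uniform over mean counts
[2, 2000] (`baseline_logmean_range`, natural-log bounds), dispersion
φ = 0.1 (constant by default; per-gene arrays accepted), library sizes L_j
drawn uniform over (0.8, 1.6) × Σμ (so normalization is non-trivial), and
p_g(G) ∝ μ_g · 2^{lfc(g,G)} normalized within each sample — i.e. planted
effects shift group means by 2^log2FC while total depth stays at its drawn
value in expectation. Gene lengths are log-uniform in [500, 10 000] bp so
FPKM computation is exercised. One run-level seed is split per sub-generator
by SHA-256 (`dermsig.seeding`), so adding a generator never perturbs
another's stream, and identical configs are byte-reproducible.

**Planted effects.** Each `PlantedEffect` names a gene set, its size, the
affected arms, and a normal log2FC draw (mean, sd). The defaults encode the
study-like conditions: a 50-gene late-differentiation program up-regulated
by the zinc arm (log2FC ~ N(+1.0, 0.5²)), a 50-gene early-differentiation
program down-regulated (N(−0.43, 0.3²), i.e. ≈ −26% on average), melanoma-up
and melanoma-down signatures of 200 genes shifted N(−0.19, 0.2²) (≈ −12%)
and N(+0.07, 0.2²) (≈ +5%), a moderate CDL response (2 × 150 genes, ±0.7),
a minimal LYS response (20 genes), and membership-only senescence and marker
panels. The differentiation programs carry `min_baseline_mean = 50`: marker
programs of the cornified envelope are abundant transcripts, and restricting
them to well-measured baselines is also the regime in which fold-change
recovery at n = 3 is meaningful (the fold change of a mean-2-counts gene is
mostly counting noise).

**Reference time course.** The 7-day epidermal-regeneration reference is
emitted directly as per-day DE tables (the analysis consumes processed
signatures, not raw reference counts). Late-program genes follow a
deterministic ramp log2FC = slope·day with slopes uniform in [0.3, 1.0];
early-program genes peak on day 1 and decay linearly to zero; background
genes draw z ~ N(0, 1) per day with log2FC = 0.25·z and p = 2Φ(−|z|), which
makes the null p-values exactly uniform by construction. Planted slopes are
recorded in the truth object.

**Signature library.** Directional disease signatures and senescence sets
are the planted memberships; five annotation source lists of 100 genes share
a common core of `round(source_overlap × size)` genes (overlap 0 ⇒ pairwise
disjoint), so a ≥3-of-5 evidence filter recovers exactly the core; four
marker panels (mitosis / basal / early / late) are 10-gene subsets.

**What the generator does not emulate.** Gene–gene correlation, length
biases, batch structure, isoform-level effects, the microarray noise of a
disease reference, and any relationship between annotation lists and true
function. Passing tests therefore demonstrate statistical correctness of the
machinery under a clean NB world — not robustness to those real-data
features.

## Differential-expression proxy

Counts are normalized by median-of-ratios factors (pseudo-reference =
geometric mean over genes positive in all samples; factors scaled to
geometric mean 1; library-size-only fallback with a warning when no gene is
positive everywhere). These factors are full per-sample normalization
constants: normalized counts are counts/factor.

The test conditions on the total of the two groups' summed normalized
counts: with S_A ~ NB(n_A μ, φ_A/n_A) and S_B ~ NB(n_B μ, φ_B/n_B), the
p-value is the conditional probability of all outcomes less likely than
observed plus half the observed likelihood class (mid-p). The mid-p variant
is what keeps the null distribution of p close to uniform — the plain rule
leaves a point mass at p = 1 from the modal outcome. Only a window of ±12
unconditional standard deviations around the conditional center is
evaluated; outside mass is ≤ ~1e-20.

**Dispersion.** Per gene, a moment estimate from the pooled within-group
variance of normalized counts, de-biased for the normalization scale (the
Poisson part of Var(c·X) scales with c): φ̂ = (s² − μ·c̄)/μ². The common
dispersion is the *mean* of the raw (possibly negative) per-gene estimates
over genes with μ ≥ 1 — the median of these skewed 4-d.f. estimates is
biased ≈ 16% low, enough to visibly inflate the false-positive rate. The
working dispersion is 0.9·common + 0.1·gene-wise: with n_A + n_B − 2 = 4
degrees of freedom the gene-wise estimate is so noisy that heavier weights
on it make the test anti-conservative (the asymmetry between under- and
over-estimated φ does not cancel in the tail). Each group's summed-count
distribution additionally gets φ_group = φ + (c̄_group − 1)/μ to absorb the
scale factors. Calibration under the fully null generator: rejection at
p < 0.05 within [0.045, 0.06] and KS-uniformity across seeds (see the
acceptance tests).

**Fold change.** FC = (mean_trt + 0.5)/(mean_ctl + 0.5) on normalized
counts; the 0.5 pseudo-count bounds log2FC for zero-count groups and
compresses fold changes of very low-abundance genes toward 1 (negligible at
mean counts ≥ 50). The median-of-ratios assumption that most genes are
unchanged means planting effects on ~half the transcriptome would be
partially absorbed into the factors — planted fractions in tests are kept
below ~10%.

**Tiers.** Permissive: p < 0.05 and FC > 1.50 or FC < 0.67. Stringent:
additionally FDR < 0.10. Intersecting the stringent tier with the
raw-p criterion guarantees stringent ⊆ permissive (an FDR below 0.10 does
not by itself imply p < 0.05); this is the package's tier definition.

## Area enrichment statistic

The discrete sum A = (1/N)Σ(C(k) − k/N) is used (not a trapezoid), because
it satisfies the exact identity A = ((N+1)/2 − r̄)/N, which (i) makes the
permutation null cheap — only the mean rank of a random size-m subset is
needed, (ii) yields the normal approximation through the Wilcoxon rank-sum
variance Var(A) = (N−m)(N+1)/(12 m N²), and (iii) gives exact antisymmetry
under ranking reversal. The permutation p uses the add-one rule
(1 + #{|A_null| ≥ |A_obs|})/(n_perm + 1), two-sided by default, n_perm =
10,000 by default; every result records n_perm and seed. Random subsets are
drawn by arg-partitioning uniform keys in memory-bounded chunks. Ranking
ties (equal FC) break by ascending p then gene id, so rankings are
deterministic.

## Resampling mean-FC null

"Mean FC" is the arithmetic mean of linear fold changes (the quantity lives
on a linear FC axis); a geometric mode is available behind a flag. The null
resamples size-m gene sets without replacement from the comparison's tested
universe; the two-sided p compares distances from the null mean with the
add-one correction, so p = 0 is impossible. Percent shift = (mean FC − 1)·100
— a set "decreased by 12%" has mean FC ≈ 0.88.

## Rank overlap and hypergeometric tails

Two rankings are restricted to their shared universe (N = intersection
size, configurable in principle because the appropriate universe for
cross-platform overlaps is study-specific); overlap(k) is computed by
cumulative counting of max(rank_A, rank_B). The Fisher test at cutoff K is
the hypergeometric upper tail P(X ≥ k) summed in log space (gammaln +
logsumexp), accurate for tails far below float underflow of individual
terms; k at the minimum possible overlap returns exactly 1.

## Other components

* **Detectability**: Garwood exact Poisson lower bound on the raw count,
  rescaled to FPKM — count ≥ 1 ⟺ positive lower bound, matching the intent
  of an abundance-uncertainty filter without re-deriving any assembler's CI.
  "2 of the 6 samples" generalizes to 2 of the comparison's samples.
* **BH**: textbook step-up with cumulative-minimum monotonicity, cap at 1.
* **ORA**: terms intersected with an explicit universe (default: the
  comparison's tested universe); no ontology propagation — term content is
  taken as given.
* **ΔΔCt**: per-sample ΔCt, per-gene centering on the control-group mean
  ΔCt, relative quantity 2^(−ΔΔCt) rescaled so the control mean is exactly
  1; invariant to any per-sample constant Ct shift. Replicate ΔCt values are
  kept per sample so group summaries carry replicate variance.
* **Fisher's LSD**: one-way ANOVA pooled variance, pairwise t at α = 0.05,
  df = N − k. The letter display is a greedy anchor scan over groups sorted
  by decreasing mean: each letter extends until the first group differing
  significantly from its anchor, which anchors the next letter. With two
  groups the pairwise p equals the pooled two-sample t-test. Zero pooled
  variance with unequal means flags all pairs significant with a warning.
* **PCA**: log2(FPKM + 1), gene-centered, SVD with a deterministic sign
  convention (largest-magnitude loading positive). Displacement vectors are
  group mean scores minus the control mean. The transform choice is a
  documented default, not derivable from any single convention.
* **Strong-gene selection**: evidence score = min raw p across comparisons;
  smallest `target_n` kept, ties by gene id. A transparent surrogate for
  "strongest evidence in any one comparison" selection rules.
* **Clustering / trends**: average-linkage Euclidean clustering on log2FC
  profiles with rows pre-sorted by gene id (permutation-invariant heights
  and leaf order); loess = statsmodels lowess (local linear, tricube),
  which reproduces linear inputs exactly; window must cover ≥ 3 points.

## Pipeline determinism

The run-level seed is split per stage and comparison by SHA-256, every
stochastic output records its seed and replicate count in `#` metadata
lines, floats are written with 17 significant digits (exact float64 round
trip), and the integrated run writes the synthetic dataset to disk and
re-reads it before analysis — so running `simulate` and the analysis stages
separately reproduces the integrated run's outputs checksum for checksum.
The manifest lists inputs, seeds, universe sizes and SHA-256 checksums of
all outputs.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run the generator at 2,000–6,000
genes (full four-arm design) rather than the 14,600-gene default, with
permutation/resampling depths of 999–20,000 — sizes chosen so the complete
validation runs comfortably on a single CPU while leaving every statistical
property (calibration bands, oracle comparisons, recovery rates) unchanged,
since all of them are per-gene or per-set properties independent of universe
scale. The null-calibration dataset is 5,000 genes, 3 vs 3, dispersion 0.1.

## Known limitations

* The DE proxy targets calibration and recovery, not numerical equality
  with any specific external DE tool; genuinely heterogeneous per-gene
  dispersions are only partially captured at shrink weight 0.9.
* At n = 3 and dispersion 0.1 the measurement noise of a single gene's
  log2FC is ≈ 0.39 (floor √(2φ/n)/ln2 even at high abundance); per-gene
  fold-change *direction* calls are correspondingly noisy, and set-level
  statistics (area, mean-FC shift) are the reliable readouts.
* The mean-FC null resamples genes independently; correlated gene sets in
  real data would widen the true null relative to the resampled one.
* Universe choice for cross-ranking overlaps is exposed as a parameter but
  defaults to the intersection; there is no attempt to reconstruct
  platform-specific universes.
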