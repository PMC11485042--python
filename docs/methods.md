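# Methods

`omicsmeta` integrates three lines of gene-level evidence for a
quantitative trait — common-variant association aggregated over a gene
window, association of measured whole-blood expression with the trait, and
rare-variant set tests — into a single correlated meta-analysis per gene,
followed by protein-interaction-module enrichment and GO
over-representation. This note records the models, the numerical choices,
and what the synthetic cohort does and does not emulate.

## Trait preparation

Traits are residualized on a covariate design (age, age², sex, and one-hot
field-center style factors; trait-specific covariates are configuration,
not code), then adjusted stepwise for the top 10 genotype principal
components, then inverse-normal transformed.

- **Stepwise rule.** Forward, in PC index order, single pass: a PC is
  retained iff its marginal association with the current residual has
  p < 0.05, and the residual is re-fit on the retained set. "Stepwise" is
  underdetermined in common usage; this is the simplest reproducible
  reading and the retained set is reported in the run manifest.
- **Inverse normal transform.** Blom offset: z_i = Φ⁻¹((r_i − 3/8)/(n + ¼))
  with average ranks for ties — the common genetics default.
- **Genotype PCs.** Computed from a seeded subsample of up to 2,000 common
  variants (standardized dosages, sample-space Gram matrix). Subsampling
  stands in for LD pruning; at the cohort sizes used here the leading PCs
  are stable under it.

## Genomic inflation and the empirical null

The genomic inflation factor is λ = median(Φ⁻¹(p/2)²)/0.4549. When a
stage's λ exceeds 1.1, its signed z-scores are recalibrated with an
empirical null: a 3-component normal mixture (a dominant central null
component flanked by two signal components) fitted by EM; bias and
inflation are the null component's mean and sd, and corrected
z = (z − bias)/inflation.

Two identifiability guards matter in practice. The flanking components are
constrained to keep their means at least two null-sd away from the null
mean — otherwise, on signal-free data, they absorb the null's shoulders and
the fitted null sd shrinks below the truth (≈0.96 instead of 1.0, which
alone inflates the corrected λ to ≈1.08). Signal sds are floored at half
the null sd. If EM fails to converge, median/MAD estimates are used with a
warning. Note that at 5,000 tests the sampling noise of the median puts an
intrinsic ±0.03 wobble on λ; no correction can beat that.

## Common-variant gene scores

Variants with MAF ≥ 5% within 50 kb of the gene body (inclusive
boundaries; a variant may belong to several genes) contribute
T = Σ z_i², with |z_i| = Φ⁻¹(1 − p_i/2) capped at 37. Under the null,
T ~ Σ λ_j χ²₁ where λ_j are the eigenvalues of the local LD matrix —
Pearson correlation of mean-imputed dosages from the cohort's own
genotypes (no reference panel), shrunk as R ← (1−ε)R + εI with ε = 10⁻³ to
guarantee positive semidefiniteness. Genes with more than 3,000 variants
are thinned by highest MAF (eigendecomposition cost). Only the sum
statistic is implemented; direction is irrelevant to a sum of squares, so
z magnitudes come from two-sided p-values.

### Tail probabilities of chi-square mixtures

`quadform_tail` evaluates P(Σ λ_j χ²₁ > t):

- **Equal weights** reduce exactly to a scaled χ²_k survival function.
- **General weights** use numerical inversion of the characteristic
  function (Imhof's integral) by a vectorized midpoint rule. The step is
  2π/(t + μ + 40σ) with μ = Σλ, σ = √(2Σλ²), which pushes the aliasing
  period far beyond the distribution's mass; truncation uses the
  oscillatory tail bound 2E(U)/|θ′| (envelope E(u) = 1/(u·ρ(u)),
  θ′ → −t/2), which handles the polynomially decaying k = 2 envelope that
  a naive envelope bound cannot. Points are capped at 2×10⁵, where the
  residual oscillatory tail is ≲10⁻⁸ — far below every tolerance used.
- **Fallback.** If the inversion returns a non-finite value or p ≤ 10⁻¹²
  (absolute quadrature error would dominate such tails), the
  Liu–Tang–Zhang moment-matching approximation is used. The method
  actually used is reported.

## Measured-expression TWAS

"TWAS" here means association of measured expression with the trait, not
genotype-predicted expression. Genes with CPM < 3 in more than 98.5% of
samples are dropped; samples with > 8% intergenic reads (a supplied
metric) are dropped. Counts are transformed as log2(CPM + 0.5) — a
variance-stabilizing stand-in chosen because the package's claims concern
association calibration, not count modeling — then residualized on the
base covariates and adjusted stepwise (same rule as trait preparation)
for batch and the top 10 expression PCs, computed once on the
base-adjusted matrix.

Family structure enters through a single REML fit per trait of
V = σ²_g·2K + σ²_e·I (kinship K, intercept-only mean model, profiled
1-D optimization over σ²_g/σ²_e). Per-gene association whitens both sides
with V^(−1/2) and runs an OLS slope t-test; with K = 0 the whitener is a
scalar, so the procedure *is* OLS there — exactness that the shared-fit
shortcut (one variance model per trait rather than per gene) preserves.

## Rare-variant tests

Biallelic variants with MAF < 5% in the same ±50 kb window are split into
ten functional categories (synonymous, missense, plof, promoter CAGE,
promoter DHS, enhancer CAGE, enhancer DHS, upstream, downstream, UTR). A
category is testable only with ≥ 2 variants; each testable category gets a
SKAT variance-component test: Q = r′V⁻¹GW²G′V⁻¹r with null distribution
Σ λ_j χ²₁, λ from WG′P₀GW (P₀ the V-metric projection removing the
intercept), sharing the tail machinery above.

Weights combine the classic MAF factor with annotation evidence:
w_j² = Beta(MAF_j; 1, 25)² · aPC_j / mean(aPC), where aPC is the first
principal component of the standardized annotation scores, sign-oriented
to correlate positively with the standardized row mean, mapped to
percentiles u = rank/(n+1) and Phred-scaled as −10·log₁₀(1 − u). The aPC
is computed within each tested gene-category set (the unit that is
tested), keeping weights comparable within a test; whether the original
analyses standardized genome-wide is unknowable from the outside, and the
per-set choice is logged. Burden and ACAT-style tests are deliberately
absent (their null distributions were not uniform in the source analyses),
and the ten category p-values are kept separate rather than combined.

## Correlated meta-analysis

Each gene's p-values are mapped to upper-tail z = Φ⁻¹(1 − p) (direction-
free: rare-variant and sum-of-chi-square evidence carries no sign, so
signs are not commensurable across sources; TWAS betas are reported
separately). For each of the ten rare-variant categories, a gene × {GWAS,
TWAS, RVA-category} matrix is built and combined per gene over the
observed entries S: p = 1 − Φ(Σ_S z / √(1′Σ_SS1)). A single observed
source returns its own p exactly.

Σ is estimated empirically under the null: Pearson correlation of z over
genes whose observed sources all have p > 10⁻⁴ (signal genes would inflate
it; the mask keeps >99% of genes in realistic settings, and estimation
falls back to all genes below 50 null genes). A tetrachoric estimator
(median-dichotomized z, 1-D likelihood search over the bivariate-normal
quadrant probability) is available as a flag. Off-diagonals are clipped to
±0.99 and the matrix made PSD by eigenvalue clipping. Σ is re-estimated
per category run, since the RVA column changes.

Multiple testing aggregates across all ten runs: total tests = Σ over runs
of genes tested; a gene is significant iff any category p < 0.05/total.
Replication in a second cohort uses 0.05 divided by the count of
discovery-significant genes (GWAS/TWAS) or gene-category pairs (CMA/RVA),
plus direction-of-effect concordance where betas exist.

## Module enrichment and GO over-representation

Genes with evidence from fewer than two sources are removed from modules
(single-source support is exactly what the meta-analysis is designed to
discount); modules shrinking below two genes are dropped. A module's genes'
minimum-over-categories CMA p-values are fused as T = Σ_g Qχ²₁(1 − p_g)
against χ²_k (Fisher's −2Σlog p is available for sensitivity analysis).

Because the min over ten dependent category runs is anti-conservative as
an input, the recommended mode for headline calls replaces the analytic
tail with an empirical null: N size-matched random gene sets drawn from
the tested universe (default N = 10,000; scaled runs use 2,000), with the
add-one rank estimate. The analytic p is retained for speed and unit
checks. Correction over modules is Bonferroni by default; BH is
implemented as an alternative because the two conventions both circulate
for this step.

GO over-representation of an enriched module's genes is an upper-tail
hypergeometric test against the background of all genes entering the
meta-analysis for that trait, with BH FDR across terms, followed by greedy
Jaccard pruning (threshold 0.5) of overlapping terms — a deterministic
stand-in for affinity-propagation de-duplication.

## Synthetic cohort

The generator produces a desk-scale cohort with the statistical structure
the pipeline assumes; all randomness flows from one seed and regeneration
is bit-identical.

- **Genotypes.** Per gene, a block of common variants from a one-factor
  latent-Gaussian threshold model and independent rare variants
  (MAF 0.001–0.05). Block MAFs cluster around a per-block centre (variants
  sharing haplotype structure have similar margins; disparate margins
  would cap the achievable correlation). The latent loading is calibrated
  by inverting the threshold attenuation so the realized *dosage-scale* LD
  matches `rho_ld` (default 0.5) — the dosage correlation is what the
  statistics consume.
- **Relatedness.** Sib pairs share parental haplotypes (each sib inherits
  one maternal and one paternal haplotype, no recombination), giving
  expected kinship ¼; the kinship matrix records the pedigree expectation.
- **Trait.** Sum of planted common-variant scores (scaled to a target
  variance fraction), planted expression effects, a planted rare-variant
  burden, age/sex covariate effects, a polygenic term with covariance
  σ²·2K (default 0.2), and unit Gaussian noise.
- **Expression.** Negative-binomial counts (gamma–Poisson, dispersion 0.1)
  around library-size × baseline × 2^(latent/2); planted genes act on the
  trait through their latent expression. The latent-vs-count distinction
  means recovered effect sizes are attenuated relative to planted betas.
- **Annotations and categories.** Rare variants get standard-normal
  annotation vectors; causal rare variants are shifted by +1.5, making the
  annotation PC informative. Categories are uniform-random except causal
  variants, which are forced into the planted category.
- **Gene sets.** Null modules are drawn from genes *without* planted
  effects, so the planted/null contrast is clean; the planted module holds
  the planted genes padded with null fillers up to the minimum module
  size. Random GO sets plus one planted term. (Sampling null modules over
  all genes would let a random module that happens to contain the single
  strongest planted gene outrank the planted module — a statement about
  set overlap, not about enrichment detection.)

What the generator does **not** emulate: realistic human LD maps,
population stratification, sequence content, cell-type composition,
expression networks, or trait-to-expression reverse causation. Passing
tests therefore demonstrate statistical calibration and recovery under the
assumed covariance structures, not robustness to the full messiness of
cohort data.

## Problem sizes and default tolerances

The test-suite study conditions: null calibration uses three cohorts of
2,000 genes × 1,000 samples (five common and eight rare variants per
gene); signal recovery and module ranking use ten cohorts of 150 genes ×
500 samples with three multi-source planted genes (h²_GWAS = 0.05,
β_TWAS = 0.25, h²_RVA = 0.035), one weak single-source gene
(β_TWAS = 0.12) and 200 modules, with a 2,000-draw empirical null for
enrichment. Monte-Carlo oracles use 10⁶ draws (gene scores) and 10⁵
permutations (SKAT) at k ≤ 10, n ≤ 200. These sizes keep each property at
comfortable statistical resolution while a full run of the suite stays in
the tens of minutes on one core.

## Known limitations

- The empirical-null EM targets a unimodal, roughly symmetric z
  distribution; heavy one-sided signal loads may bias the fitted null
  mean.
- Per-gene tests share one variance model per trait; genes with strong
  effects violate the null variance fit slightly (standard practice, and
  immaterial at the planted effect sizes).
- The tetrachoric estimator uses median dichotomization, discarding tail
  information; it exists for robustness comparison, not as the default.
- Missing dosages are mean-imputed inside test statistics only; MAF always
  reflects observed alleles.
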