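# Methods

## The model

Regional heritability mapping (RHM) asks, for every short genomic window,
how much phenotypic variance the window's SNPs jointly explain.  For a
window *q* the model for one trait is

    y = 1 mu + u_q + u_g + e,
    u_q ~ N(0, sigma2_q Q),   u_g ~ N(0, sigma2_g G),   e ~ N(0, sigma2_e I),

where `G` is the whole-genome genomic relationship matrix (GRM) and `Q`
the regional GRM built from the window's SNPs only.  Phenotypes are
yield deviations — records pre-adjusted for systematic environmental
effects — so the fixed part is an intercept only (the model container
accepts extra covariates for reuse).  The regional heritability is
`h2_reg = sigma2_q / (sigma2_q + sigma2_g + sigma2_e)`.

Both relationship matrices use VanRaden's first method with observed
allele frequencies: `G = Z Z' / (2 Σ p_j (1 - p_j))` with `Z` the
genotype matrix centred by `2 p_j`.  The regional GRM's denominator sums
over the region's own SNPs, so `sigma2_q` is scaled per region and
`h2_reg` is directly interpretable.  The background GRM uses **all**
SNPs, including the region's (an exclusion flag exists via
`snp_subset`, but the default matches the method as published).
Missing genotypes are mean-imputed per SNP; monomorphic SNPs are dropped
with a logged count.  The pedigree alternative is the standard numerator
relationship matrix by the tabular method.

## Estimation

Variance components are estimated by average-information (AI) REML.
Each Newton step uses the AI matrix, is capped in length relative to the
parameter scale, and is step-halved until the restricted likelihood does
not decrease; if no AI step is acceptable an EM-flavoured update is
tried with the same halving.  Variance components are clamped at
`1e-8 * var(y)`; a component clamped for three consecutive iterations
*with a non-positive gradient* is fixed at the boundary.  Convergence
requires `|Δ logL| < 1e-6` and a maximum relative parameter change
below `1e-5` (at most 200 iterations).  Starting values split the
phenotypic variance equally across components unless supplied.

Two objective backends evaluate the identical restricted likelihood
(including the `-(n-p)/2 log 2π` constant):

- a dense backend for arbitrary component sets (regional scans, joint
  multi-region fits);
- a block-diagonal backend used after rotating the data by the
  eigenvectors of a single GRM, which makes single-component fits (the
  scan's null model, the GRAMMAR adjustment) and the bivariate model
  O(n) per iteration instead of O(n³).

The bivariate model stacks two traits with covariance
`Sigma_g ⊗ G + Sigma_e ⊗ I`.  The genetic 2×2 covariance is free; the
residual covariance is **diagonal by default**, because the phenotypes
modelled here are deviations whose cross-trait residual covariance is
not separately identifiable from the genetic one in the generator's
design (residual correlation is zero by construction);
`residual_cov=True` frees it.  The genetic correlation is
`rG = cov_g / sqrt(v_g1 v_g2)`, clipped to [-1, 1].

## Testing a window

The scan reuses one cached null fit (background + residual) per trait
and fits each window's full model warm-started from it, so
`LRT = max(0, 2 (logL_full - logL_null))` is non-negative by
construction (the line search never lets the likelihood decrease below
the initial point).  Because a single variance component is tested at
the boundary of its space, the LRT null is the 50:50 mixture
`0.5 δ0 + 0.5 χ²₁`; reported per-window p-values use this mixture.

Thresholds are Bonferroni-derived from `N = m/w` effective independent
tests — the number of *non-overlapping* windows, not the count of
overlapping ones; this is the definition that reproduces the standard
published threshold set exactly.  The genome-wide threshold controls
the family-wise rate at `alpha` on the mixture scale
(`chi2.isf(2 alpha / N, 1)`); the suggestive threshold (one expected
false positive per scan) is taken on the plain χ²₁ scale
(`chi2.isf(1/N, 1)`).  These two conventions differ; the published
numbers encode exactly this mixed convention, so it is the default, and
`null_dist={"mixture","chi2_1"}` makes either uniform.

Overlapping or SNP-adjacent significant windows on one chromosome merge
into a single QTL call; the call's level is the highest among its
windows and its peak is the max-LRT window (bp ties break low).
Windows never span chromosomes; trailing SNPs that do not fill a window
go untested.  A hard failure inside one window marks it unconverged
without aborting the scan.

## After the scan

*Pleiotropy.*  For a region significant in two traits, the Pearson
correlation between the two traits' regional EBVs (BLUPs
`u_hat = sigma2_q Q P y` from the univariate full fits) screens for a
shared causal locus.  A bivariate regional model could estimate the
same quantity with error propagation, but the univariate-BLUP reading
is the implemented convention; records where either regional variance
sits at the boundary are flagged not estimable.

*Joint partition.*  All called peak windows enter one model with the
background, giving per-region `h2_reg` free of double counting and the
proportion of genetic variance explained
`Σ h2_reg / (Σ h2_reg + h2_background)`, reported as a percentage
rounded to the nearest integer.  The joint fit's total genetic variance
may legitimately differ from the single-background fit's; both are
reported rather than reconciled.  No winner's-curse (Beavis-effect)
correction is applied; regional effects at selected windows are
expected to be somewhat inflated.

*GRAMMAR.*  The association comparator first removes the polygenic BLUP
(residuals equal `sigma2_e P y` exactly at the REML solution), then
regresses residuals on each SNP by OLS with a two-sided t test on n-2
df.  The adjustment makes the test mildly conservative; optional
genomic control rescales by the median chi-square.

## The synthetic generator

The generator emulates the 16th QTL-MAS workshop benchmark structure:
3,000 phenotyped females in three generations, five 99.95-Mb
chromosomes with 2,000 evenly spaced SNPs each, three correlated traits
(target h² 0.36/0.35/0.52, target rG 0.80/-0.43/0.17).  The benchmark
publishes neither its LD structure, its QTL, nor its trait mechanism,
so:

- **Pedigree**: each generation pairs the previous one into
  floor(size/2) disjoint matings with a configurable number of
  offspring (defaults: 1,000 founders × 2 offspring → 3 × 1,000).
- **Founder LD**: a two-state Markov chain along each chromosome with
  correlation 0.7 between adjacent alleles; allele frequencies uniform
  on `maf_range` (default 0.05–0.5).  Some LD is required for regional
  GRMs to tag QTL at all; 0.7 gives adjacent-SNP genotype correlations
  around 0.6–0.8 at 50-kb spacing, a dense-chip-like decay.
- **Meiosis**: crossovers as a Poisson process at 1 cM/Mb, no
  interference.
- **Traits**: genetic value = planted QTL effects (nine partly
  pleiotropic loci by default, signs following the benchmark's reported
  per-region correlation trends) plus an infinitesimal polygenic term
  with covariance `GRM ⊗ Sigma_u`.  The target correlation matrix is
  nearly singular (smallest eigenvalue ≈ 0.03), so the "target minus
  QTL" polygenic covariance is PSD-clipped and, by default, the total
  genetic values are then linearly recalibrated so their sample
  covariance equals the target exactly; residuals (uncorrelated across
  traits by default) are scaled so the realized variance-ratio
  heritability matches the target.  `calibrate_genetic_cov=False`
  disables the recalibration for mechanistic tests.
- **Determinism**: all draws flow from one master seed through named
  streams; identical configurations produce byte-identical files.

What the generator does **not** emulate: the workshop's actual QTL
(number, positions, effects are unpublished — the defaults are
illustrative), content traits as ratios of yields (traits here are
linear-additive), genotyping error and missingness, and real ascertained
SNP frequency spectra.  Passing tests therefore demonstrate that the
machinery recovers what it models under a realistic breeding-population
structure, not that it reproduces the workshop's exact estimates.

## Problem sizes and tolerances in the test suite

The statistical tests run at deliberately reduced sizes chosen so the
Monte-Carlo error is small against the asserted tolerance: the null
scan pools 400 windows of 20 SNPs from two n=500 cohorts over 2,020
SNPs (zero-LRT fraction asserted at 0.5 ± 0.1; at this size the
fraction sits near 0.58 because the background GRM already contains the
window's SNPs and absorbs chance regional signal — the asymptotic
mixture weight of one half is approached from above); regional-h²
recovery uses 20 seeds at n=1,000 (tolerance ±0.03); bivariate rG uses
three seeds at n=1,000 (tolerance ±0.1, Monte-Carlo SE ≈ 0.03); power
uses 20 seeds at n=1,000 with an 8%-variance QTL against the
genome-wide threshold of its 800-SNP genome.  The acceptance script
simulates 900 individuals over 1,500 SNPs with the default QTL map,
which keeps a full three-trait pipeline run within minutes while
retaining every stage of the full-size analysis.

## Known limitations

- Dense REML is O(n³) per iteration in the scan's full model; scans at
  n ≫ 5,000 need the planned low-rank regional updates.
- Multi-trait (>2) REML, dominance/epistatic matrices and
  leave-one-chromosome-out GRMs are out of scope.
- PLINK binary and VCF input are not supported; text ped/map only.
- The QTL-call merge rule (overlap or SNP-adjacency) is a reasonable
  reconstruction; published QTL counts depend on the original authors'
  unstated merging convention.
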