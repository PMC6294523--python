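# Methods

This note documents the generative models, analysis procedures, defaults
and numerical choices in `eqtlsim`, and what its synthetic data do and do
not capture about real eQTL studies.

## Synthetic genotypes

The genotype generator has two layers.

**Reference panel (coalescent).** `simulate_haplotype_panel` draws a panel
of phased haplotypes (default 100, the size of a small population reference
set) from a standard neutral coalescent with recombination over one
chromosome (default 20 Mb), then drops binary mutations on the genealogy.
Two properties motivate this choice over ad-hoc alternatives such as
copying mosaics of independently generated founder columns: (i) the neutral
site-frequency spectrum is automatically ∝ 1/p, populating every
minor-allele-frequency band from panel singletons (0.5% in a 100-haplotype
panel, after diploid sampling) to 50%; and (ii) pairwise r² decays smoothly
with inter-SNP distance on the scale 1/(4·Ne·c) while retaining realistic
heterogeneity, including perfect proxies (sites on the same genealogical
branch). An i.i.d.-founder mosaic cannot achieve both at once: with K
founders the expected short-range r² is bounded near 1/(K−1), so strong LD
forces a founder-frequency grid too coarse for rare variants. The mutation
rate is calibrated from the expected total tree length (2·Ne·Σ1/i for
haploid samples) to overshoot the requested SNP count by 60%, and sites are
thinned to the exact count (optionally with user-supplied MAF weights).

**Study samples (Li–Stephens mosaic).** `sample_genotypes` builds each
study haplotype by copying a random panel haplotype, switching template at
a Poisson rate per bp (default 10⁻⁶/bp, ~20 switches per 20 Mb haplotype)
and flipping alleles with a small copying-error rate (default 10⁻⁴ per
site). Diploid dosages are sums of two independent mosaics, recoded to
count the minor allele in the sample. This mirrors how reference-based
genotype simulators expand a panel while preserving its LD structure; the
error rate injects rare variation and mildly erodes perfect LD, as
population growth and genotyping error do in real data.

**QC.** `filter_variants` removes SNPs with sample MAF < 0.5% or a 1-df
chi-square Hardy–Weinberg goodness-of-fit p < 5×10⁻⁶ (the conventional
pre-analysis filters). Random mating is built into the sampler, so HWE
removals are rare.

**Default genome scale.** 16,000 SNPs on 20 Mb (800 SNPs/Mb) with 618
genes (uniform random TSS) and 200 true eGenes. The gene count and
true-eGene fraction mirror a single-chromosome study; the SNP density is
the closest to a dense chromosome map (several thousand SNPs/Mb) that keeps
a full 10-replicate scenario grid within minutes on one CPU. Density
matters mainly for the causal-identification metric (sparser maps have
fewer near-perfect proxies, inflating the rate) — the default was chosen
for LD realism before the acceptance quantities were finalized, and the
documented tolerance on that metric reflects its LD-profile dependence.

## Causal eSNP selection

`select_causal_esnps` picks `n_causal` (default 200) genes at random, and
for each draws a causal SNP uniformly from the SNPs within ±1 Mb of its TSS
whose sample MAF lies within ±20% (relative, configurable) of the scenario
MAF, subject to pairwise r² ≤ 0.3 with all previously selected causal SNPs
(greedy LD pruning). Coordinates are 1-based and the cis window is
inclusive at both edges. A capacity error naming the deficit is raised when
the band or pruning constraint cannot be satisfied.

## Expression models

True eGenes follow `y = Σ β_k·g_k + ε` with unit-variance noise; null genes
are pure noise. Variants:

* **Effect sizes**: constant β (grid values 0.25/0.5/1/1.5 s.d. of
  expression per allele are the conventional scan) or Gamma(shape 1.8,
  scale 0.35) draws. The gamma parameters are an explicit stand-in chosen
  to put most mass below 0.5 s.d./allele with a tail beyond 1.5, the shape
  empirical cohort effect-size distributions show; they are configurable.
* **Noise**: standard normal, or log-normal (log-mean 0, log-sd 1) to
  violate error normality; `inverse_rank_normalize` applies the per-gene
  rank-based inverse normal transform with ranks (r − 0.5)/n and average
  ranks for ties.
* **Codings**: additive (0,1,2), dominant (0,2,2), recessive (0,0,2).
* **Co-expression blocks**: genes binned by TSS into 1 Mb blocks; the true
  eGenes of a block share one causal eSNP located inside the block and
  noise `r_i·ε₁ + √(1−r_i²)·ε_i` with r_i ~ U(0.6, 0.9), so every noise
  term keeps unit variance.
* **Multiple causal eSNPs**: secondary causal variants are chosen so their
  |correlation| with the primary matches a Beta(2.6, 4.5) draw as closely
  as the available in-window SNPs permit (nearest-|r| matching; the
  matching rule is a package choice, as only the target distribution is
  standard).

## Cis mapping

`map_cis` fits `y ~ intercept + dosage` (df = n − 2) for every gene–SNP
pair within the inclusive ±1 Mb window. The engine standardizes expression
and dosages once and derives slope, SE, t and two-sided p from the
correlations, algebraically identical to per-pair OLS (verified against
closed-form and statsmodels oracles to ~10⁻¹⁰ relative error).
Zero-variance SNPs are skipped (the test is undefined) and logged; p-values
are floored at 10⁻³⁰⁰ to stay in (0,1]. Ties for a gene's top SNP are
broken by lower base-pair position.

## Multiple-testing correction

**Pooled**: Bonferroni, BH, BY (via statsmodels) or Storey–Tibshirani
q-values across all SNP–gene tests; an eGene is any gene with ≥1
significant pair at α = 0.05.

**Hierarchical (three steps)**: (1) adjust each gene's cis p-values
locally — ST/BH/BY, Bonferroni (×m cis SNPs), eigenMT-style Bonferroni
(×m_eff), or a permutation p per gene; (2) take each gene's minimum locally
adjusted p and adjust across genes; significant eGenes have globally
adjusted p ≤ α; (3) the local significance threshold is the largest
per-gene minimum locally adjusted p among significant eGenes, and a
significant eGene's eSNPs are the SNPs whose locally adjusted p is at or
below it. The comparison is inclusive: under a strict inequality the
threshold-defining gene would have no significant eSNPs at all, which
contradicts the threshold's definition; a 10⁻⁹ relative slack guards the
same boundary case against float rounding (and the analogous round-trip
through the beta quantile function for permutation methods, where the
top SNP of a significant gene is always retained).

**eigenMT effective tests**: cis SNPs are partitioned into consecutive
windows of 200; per window the dosage correlation matrix is
eigendecomposed and the number of leading eigenvalues reaching 99% of the
total variance counted; m_eff is the sum, clipped to [1, m]. Window size
and variance fraction follow the method's conventional settings and are
configurable. Inside `hierarchical_correct` the windows are aligned to a
fixed genome-wide grid so that the heavily overlapping cis windows of
neighbouring genes reuse cached eigendecompositions; only the two partial
edge windows are computed per gene (the standalone function uses the plain
gene-anchored partition; the difference affects at most the two edge
windows).

**Permutation schemes**: expression labels are permuted; the minimum
nominal p across cis SNPs per permutation forms the null. `exact` uses
p = (r+1)/(B+1) (the +1 convention avoids zero p-values); `beta` fits a
two-parameter beta distribution to the permuted minima by maximum
likelihood (scipy MLE with location 0 and scale 1 fixed, parameters floored
at 10⁻⁶) and evaluates its CDF at the observed minimum, allowing p-values
below the permutation floor; `adaptive` permutes in batches of 100 until 15
permuted minima beat the observed one (or 10,000 permutations), then
beta-fits. B defaults to 1000 and must be ≥ 100.

**Storey–Tibshirani π₀**: λ grid 0.05…0.90 step 0.05, cubic-polynomial
smoothing evaluated at λ = 0.90, clipped to [10⁻³, 1]; q-values are π₀
times the BH-adjusted values.

## Conditional analysis

For each significant eGene (eigenMT-BH or Bonferroni-BH gate), the nominal
threshold is the Step-3 locally adjusted threshold divided by the gene's
local multiplier. The forward stage starts from the top SNP and iteratively
adds the best SNP of a scan conditioned on all accumulated sentinels
(residualizing expression and candidate dosages on the sentinels plus
intercept; df = n − 2 − k), stopping when nothing passes the threshold or
after 10 iterations (a safety valve). Collinear sentinels (residual s.d.
< 10⁻⁸ on the earlier ones) are dropped, later-added first. The backward
stage re-tests each sentinel against all others in a leave-one-out model;
survivors form the independent-signal set.

## Winner's-Curse bootstrap

For each significant eGene, the top eSNP is fixed from the full-sample
analysis. Each of B = 200 bootstraps resamples n of n samples with
replacement (detection group; ~63.2% unique samples) and uses the
out-of-bag remainder as the estimation group. A bootstrap counts toward
B_e when the detection-group nominal p times the gene's original local
multiplier is below the original Step-3 threshold. Over counted bootstraps:
shrinkage = naive − mean(β_D − β_E); out-of-sample = mean(β_E); weighted =
0.368·naive + 0.632·mean(β_E). Genes with B_e = 0 keep the naive estimate
flagged as uncorrected; bootstraps with a degenerate estimation group
(< 3 samples) are skipped with a warning. Per-bootstrap RNG substreams are
keyed by (seed, bootstrap index) so results are reproducible regardless of
execution order.

## Scoring

A significant eGene is a true positive iff it was simulated as a true eGene
and at least one of its significant eSNPs has sample r² ≥ 0.8 with one of
its causal eSNPs; every other significant eGene (including true eGenes
detected only through low-LD SNPs) is a false discovery. TPR is the
fraction of simulated true eGenes recovered; FDR pools TP/FP counts across
replicates before forming the ratio (scenarios with zero calls report FDR
as missing). Top-eSNP scoring, over true-positive eGenes, counts the top
SNP as a causal hit when it is the causal SNP or has r² ≥ 1 − 10⁻⁹
(perfect LD up to float noise); among misses, the high-LD rate uses
r² ≥ 0.8. Estimator errors (estimate − true β) are computed on
true-positive eGenes against the gene's simulated effect.

## Reproducibility and seeds

All randomness derives from one master seed through named
`numpy.random.SeedSequence` streams (`eqtlsim._rng`), so adding a consumer
never perturbs existing streams, replicates are independent, and every
pipeline stage is bit-reproducible.

## Problem sizes used by the test suite and reproduction script

The reproduction script (`scripts/acceptance.py`) uses the default genome
(16,000 SNPs / 20 Mb / 618 genes / 200 true eGenes) with 10 replicates per
scenario; the test suite runs the same scenarios with 2–3 replicates, which
still pools several hundred eGene calls per check, keeping binomial
Monte-Carlo error on the reported rates near ±0.01. The causal-rate check
pools six constant-effect scenarios spanning the qualifying regime (power
≥ 80%, causal MAF ≤ 25%) from the detection boundary through comfortably
powered designs — (n=200, MAF 5%, β=1.5), (n=200, 10%, 1.0), (n=100, 25%,
1.0), (n=500, 5%, 1.5), (n=500, 10%, 1.0), (n=1000, 25%, 1.0) — excluding
any whose realized power falls below 0.8. The rate falls with causal MAF
(common eSNPs have more high-LD competitors), so the pooled value depends
on this scenario mixture as well as on the LD profile.

## What the synthetic data do not capture

* No covariates (age, sex, batch, population structure, expression PCs) and
  hence no covariate-induced confounding; mapping is simple OLS.
* Expression is Gaussian-scale, not counts; no mean–variance relationship,
  library-size or single-cell sparsity effects.
* One chromosome, no trans effects, no relatedness or admixture in the
  sample, no genotyping missingness (mean imputation is offered only for
  external data read through the VCF/TSV interfaces).
* The panel has a single constant-size population history; real LD is
  lumpier (hotspots) and its proxy density varies along the genome. Passing
  checks therefore demonstrate correctness and calibration of the
  *procedures* under a realistic-but-idealized genetic architecture, not
  quantitative transferability of every rate to any particular tissue or
  cohort.
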