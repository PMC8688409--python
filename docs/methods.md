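# Methods

## The mapping model

`cldla` implements combined linkage-disequilibrium and linkage analysis
(cLDLA) for a quantitative trait — here the life expectancy, in days, of
affected hemizygous males from an X-linked carrier-breeding colony.  The
trait model at a putative QTL position is the mixed linear model

    y = Xβ + u + q + e,
    u ~ N(0, σ²_u G),   q ~ N(0, σ²_q D_w),   e ~ N(0, σ²_e I),

with `y` the vector of lifespans of the n cases, `X` an intercept-only
fixed design (no covariates are modelled; see "Open choices"), `G` the
genome-wide VanRaden genomic relationship matrix and `D_w` the
locus-specific diplotype relationship matrix of window `w`.  The null
model drops `q`.  Both models are fitted by REML and compared with the
likelihood-ratio statistic LRT = −2(log L0 − log L1), referred to the
χ²₁ conventions of the protocol: LRT > 11.0 chromosome-wide,
LRT > 16.5 genome-wide significance.  These are the upper-tail χ²₁
quantiles at Bonferroni-corrected per-test levels 0.0009 and 0.000049;
`scan.lrt_threshold` reproduces them from α = 0.05 and the
independent-window equivalents 55.6 and 1020.4.  Because σ²_q = 0 lies
on the boundary of the parameter space, the true null distribution is
the 50:50 mixture {0, χ²₁}; the χ²₁ convention is therefore
conservative, which the null-calibration experiment confirms.

## Relationship matrices

*Genomic.*  G = ZZ′ / (2 Σ_k p_k(1−p_k)) with Z the dosage matrix
centred at 2p_k per marker; missing dosages are mean-imputed per marker
before centring; frequencies are estimated in-sample unless supplied.

*Haplotype IBD and diplotype.*  For each sliding window of W = 40 SNPs
the probability that two haplotypes are identical by descent is scored
by a midpoint-anchored identity run: scanning outward from between
markers W/2 and W/2+1, count consecutive identical alleles leftward and
rightward (each capped at W/2) and divide by W.  Missing alleles
terminate runs (conservative sharing).  The estimator is deterministic,
parameter-free and monotone in shared-segment length; it replaces
coalescent-model estimators that require base-population parameters
(Ne, T) which are not identifiable here, and it is a plug-in interface
so such an estimator can be substituted.  The 2n×2n IBD matrix is
converted to the n×n diplotype matrix by
D_ij = ½[p(i1,j1)+p(i1,j2)+p(i2,j1)+p(i2,j2)] (i≠j) and
D_ii = 1 + p(i1,i2).  Before entering the model every relationship
matrix is conditioned to minimum eigenvalue ≥ 1e−8 by the smallest
ridge εI found by a doubling search from 1e−10; ε is recorded.

## REML

The restricted log-likelihood

    ℓ_R = −½[(n−p) log 2π + log|V| + log|X′V⁻¹X| + y′Py]

is reported in natural log with the 2π constant included, so closed-form
oracles match absolutely.  The residual variance is profiled out
analytically over the variance ratios γ_c = σ²_c/σ²_e.  One-kernel
models use an eigen-decomposition of K so each evaluation is O(n); the
ratio is optimised by a coarse log-γ grid plus Brent refinement, with
the γ = 0 boundary checked explicitly.  Two-kernel models (the window
fits) use L-BFGS-B on (γ_u, γ_q) with the exact analytic gradient of
the profiled objective (envelope theorem at the profiled σ̂²_e), a
bound-respecting Nelder-Mead restart if the quasi-Newton step stalls,
and the best point ever evaluated is the reported optimum.  The
response is standardised internally so the ratio search is exactly
scale-equivariant.  Window fits are warm-started at the null solution
with γ_q = 0, which guarantees ℓ1 ≥ ℓ0 and hence LRT ≥ 0 after the
(−1e−6, 0) clamp; a more negative value raises instead of being
silently truncated.  Components below 1e−8·var(y) are reported as 0.
The null model is fitted once per data set and reused for every window.

## Quality control and phasing

QC follows the protocol's strict boundary wording: markers are removed
when the position is unknown, MAF < 0.025 or per-marker call rate
< 0.9; individuals are retained when their call rate is strictly
greater than 0.95.  Markers first, individuals second, one pass each;
the report tallies reconcile exactly.  X-linked markers are excluded
from phasing and scanning by default because the cases are hemizygous
(flag to include).

Phasing replaces a population HMM with a deterministic pedigree rule,
justified by the trio-complete design of the mapping cohort:

1. Mendelian-inconsistent trio sites are set missing and counted, never
   fatal (robustness on error-injected data).
2. Missing genotypes are imputed from two homozygous parents, otherwise
   as the rounded expected dosage 2p.
3. Homozygous sites phase trivially; heterozygous sites with at least
   one homozygous parent phase by Mendelian deduction (paternal
   haplotype first).
4. Founder haplotypes are reconstructed by transmission clustering:
   walking each chromosome, children vote with the alleles they
   demonstrably received, each child carrying a running which-haplotype
   state that flips at crossovers.
5. A child's remaining double-heterozygous sites take the allele of the
   parental haplotype it carries at the nearest informative flanking
   site (transmission continuity); the more frequent allele, ties
   broken by a seeded draw, is the final fallback.

On error-free data, step 3 sites phase exactly; the accuracy checks on
simulated trios with 2% missingness require ≥95% of heterozygous sites
correct, and the implementation typically exceeds 98%.

## The synthetic cohort generator

The generator emulates the statistical structure of the study colony,
not its genome: one heterozygous carrier founder dam mated to wild-type
boars (default 7 sires, 11 founder litters, Poisson litter sizes of
mean 11.6), carrier daughters recruited as dams in later generations
(avoiding sire–daughter matings), X-linked genotype classes drawn at
the Mendelian 1:1:1:1 ratios per litter (carrier × affected crosses
yield homozygous-null females, supporting the late-generation cross the
colony produced).  Chip-like marker maps are evenly spaced (~1 SNP /
50 kb, matching a ~60K chip on a ~2.5 Gbp genome); founder haplotypes
are i.i.d. per marker with frequencies drawn uniformly from
(0.05, 0.95); gametes are dropped through the pedigree with crossovers
as a Poisson process on the genetic map (1 cM/Mbp unless a cM column is
supplied; Haldane, no interference).

Lifespan is generated for affected males only (the mapping population)
as mean + a·x + g + e, rounded to whole days and floored at 0 (the
trait is a length of life in days).  `x` counts copies of the causal
allele at the configured QTL marker.  The polygenic deviate `g` is
produced by gene dropping 400 hidden unlinked biallelic loci of equal
and alternating effects scaled to the configured variance, so pedigree
and genomic kinship agree by construction; across replicate cohorts the
realised variance of `g` matches σ²_polygenic within 15% (the small
deficit reflects the relatedness of the cases).  Defaults
σ²_polygenic = 400, σ²_residual = 625 and mean 60 days give a
phenotypic SD of ~32 days with a mostly inactive floor.

What the generator does *not* emulate: founder linkage disequilibrium
(founders are i.i.d. per marker, so all marker–QTL association arises
by descent within the pedigree), litter/maternal environmental effects,
censoring, genotype-by-environment interaction, and the strongly
bimodal survival curve of the real colony (heavy first-week mortality
followed by a 3–4 month plateau) — the additive Gaussian trait model
is unimodal by construction; the survival-class tallies are therefore
exercised both on simulated lifespans and on the printed counts.  Passing tests
therefore demonstrate correctness of the machinery and calibration
under pedigree-driven sharing, not performance on populations with
ancestral LD.

All randomness derives from one root seed; each operation (pedigree
structure, class transmission, founder frequencies, founder haplotypes,
gene dropping, polygenic loci, residuals, missingness, phasing
tie-breaks) draws from an independent stream keyed by (seed, operation
label), so identical configurations reproduce outputs bit for bit.

## Calibration and recovery experiments

*Null calibration.*  48 independently seeded no-QTL cohorts of 60 cases
(polygenic + residual variance only), two chromosomes of 2,530 markers
at 50 kb spacing each, windows thinned to every 10th start so that
replicate cohorts rather than overlapping windows carry the statistical
weight: ≥24,000 window LRTs in total.  The empirical fraction exceeding
the chromosome-wide critical value 11.0 must not exceed the per-window
level 0.0009 (plus 3 binomial standard errors); the boundary mixture
argues for roughly half that level.

*Localisation.*  25 replicates of a 300-case cohort on one 40 Mbp
chromosome (800 markers), with a planted additive QTL at the centre:
allele frequency 0.5 and effect a = 0.5 phenotypic SD per copy (~16
days), i.e. ~11% of phenotypic variance.  A common variant is planted
because with i.i.d. founders the mapping information is pedigree
sharing, which is maximised for a balanced allele.  The recovery bar is
that the maximum-LRT window midpoint falls within 2 Mbp of the true
position in ≥80% of replicates.  Problem sizes (windows every 10
starts, one chromosome) keep each replicate under half a minute at
n=300.  Note that this bar is demanding for a generator without
ancestral linkage disequilibrium: an information-ceiling diagnostic
that scans the causal dosages directly (single-marker regression)
already misses the 2 Mbp target in a large share of replicates at this
effect size, because pedigree and polygenic structure produce
long-range spurious associations of comparable size; the
variance-component scan tracks that ceiling.  See "Known limitations".

## Numerical and design choices

- Coordinates are 1-based inclusive (PLINK/VCF convention); windows are
  reported as [start_bp, end_bp] of their first/last marker, midpoint
  between markers W/2 and W/2+1.
- PED alleles are written 1/2 with `0 0` missing; allele 1 is the
  reference/first-listed allele; dosage counts allele 2; strand is
  never flipped.
- Readers reject rather than coerce: triallelic markers, ragged lines,
  unphased or multiallelic VCF records all raise with the offending
  marker, line or record named.
- Failed window fits are recorded with a failure flag and missing LRT,
  never interpolated and never reported as 0.
- Peak calling keeps supra-threshold local maxima, merges peaks closer
  than 5 Mbp keeping the larger LRT, ties toward the smaller bp.
- Scan step defaults to 1 marker (the protocol says only "sliding");
  the calibration experiments thin to every 10th start for replicate
  breadth at fixed budget.

## Open choices

The protocol text does not state whether fixed covariates (litter,
birth season) entered the variance-component model, whether the X
chromosome was scanned, or how the average number of independent
windows per chromosome was obtained.  The package's defaults: no
covariates beyond the intercept, X excluded (hemizygous cases), and the
back-derived constants 55.6 / 1020.4 with an optional data-driven
estimator left to the caller.

## Known limitations

- The identity-run IBD score is a surrogate, not a coalescent
  probability; its absolute scale is only monotone-related to true IBD.
- Trio phasing accuracy degrades for founders with few genotyped
  offspring and at double-heterozygous sites near crossovers.
- With i.i.d. founders the localisation experiment understates the
  resolution real ancestral LD would provide: at a 0.5 SD per-copy
  effect and n=300 the maximum-LRT window does not reach the stated
  80%-within-2-Mbp recovery rate (the dedicated test reports the
  measured rate), while effects of ~1.5 SD localise reliably.  On real
  chip data, ancestral haplotype sharing supplies the LD component this
  generator deliberately lacks.
- REML standard errors of variance components are not computed.
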