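# Methods

## Study design and data model

`heteroscan` analyses common-reference hybrid panels: a set of inbred
accessions crossed to one (or, in the two-population design, two) shared
reference line(s), yielding F1 hybrids whose differences trace to the
variable parent. Phenotypes are replicate-level observations keyed by
(genotype, population, trait, replicate); genotypes are biallelic SNP calls
coded as allele counts in {0, 1, 2} (inbred parents carry only {0, 2}) with a
chromosome/position map; the pedigree maps each hybrid to its variable parent
and its reference parent within a population. The two populations are treated
as two independent experiments: accessions grown in both contribute
independent replicate sets to each.

## Heterosis statistics

Per hybrid and trait, on genotype means within one population:
MPV = (P1 + P2)/2; MPH = 100·(F1 − MPV)/MPV; BPH = 100·(F1 − P_best)/P_best;
MPH_ABS = F1 − MPV. Relative MPH is reported as undefined when MPV = 0
(division blow-up on count traits); MPH_ABS is always reported. The best
parent defaults to the higher-valued one; the direction is configurable per
trait (for a trait like rosette branching, fewer branches may be preferred).

Whether a hybrid significantly exceeds its best parent is tested two-tailed
on replicate values. The default is Welch's two-sample t-test, because
replicates in a randomized design carry no natural pairing; a paired mode
(pairing by replicate index) is available, and identical replicate vectors
return p = 1 by convention. Both modes can be run and compared since the
choice is a genuine judgement call.

Variance decomposition per (population, trait, role): V_G is the variance of
genotype means (divisor n−1 across genotypes) and V_E the mean of
within-genotype sample variances (divisor n−1 within genotype);
H² = V_G/(V_G + V_E) and CV_G = 100·√V_G/grand mean. "Mean within-genotype
sum of squares" admits several divisor conventions; the sample-variance
reading was chosen for unbiasedness. Because V_G from genotype means includes
a V_E/r sampling term (r replicates), H² is mildly inflated at small r; an
ANOVA expected-mean-square estimator ((MS_between − MS_within)/n₀) is
available behind `method="anova"`. H² is reported as undefined ("n.d.") for
traits without replicate-level data (pooled observations are treated as a
single replicate). Seed number is derived as NS = 10⁶ · SY / SW with SY in
g/plant and SW in mg per 1000 seeds.

One caveat that the synthetic panels made explicit: within one
common-reference population, every hybrid's MPH_ABS shares the reference
parent's replicate-noise term, so per-hybrid MPH_ABS values are positively
correlated and a naive across-hybrid t-test of "mean MPH_ABS = 0" is
anti-conservative. Panel-level nulls are therefore tested across independent
panels (or by explicitly modelling the shared term), and the test suite does
exactly that.

## Correlation analyses

Trait-by-trait matrices use Spearman's rank correlation (average ranks,
two-tailed p via the t approximation) on genotype means or per-hybrid MPH
values, with pairwise-complete deletion — trait availability differs across
genotypes, and listwise deletion would discard most rows. Cells with fewer
than 3 complete pairs are undefined. P-values are unadjusted by default;
an optional BH adjustment across cells exists.

Cross-population comparisons report squared Pearson correlations per trait,
matching parents by accession identity and hybrids (or their MPH values) by
shared variable parent.

Parental genetic distance is proxied by the kinship between a hybrid's two
parents, read directly as a similarity — so a *negative* Spearman correlation
between heterosis and kinship means more heterosis at greater distance. A
reference-substitution map supports panels whose reference lines are
engineered derivatives (tagged or male-sterile lines absent from the kinship
panel): the wild-type accession's kinship row is used in their place, a pure
lookup.

## Growth curves

Seedling leaf-area series confound establishment timing with post-
establishment growth. Each plant's series is collapsed to daily maxima (the
establishment rule is phrased in days) and t₀ is the first day the projected
area exceeds 2 mm² (roughly cotyledon emergence); the threshold is
configurable, the first crossing counts even if a noisy series later dips
below threshold, and an optional k-consecutive-days confirmation debounces
noisy input. t₀ is assigned per plant, not per genotype, then genotype-mean
curves are formed on the re-indexed offsets; time offsets supported by fewer
than 2 plants per genotype are dropped. MPH over time applies the heterosis
formula to genotype-mean areas at each shared offset, either on raw
days-after-sowing or t₀-normalized offsets; t₀ normalization removes a pure
time-shift between genotypes exactly, which the tests verify on noise-free
logistic curves. The visible-plant fraction per day uses the same threshold
and a two-proportion z-test for the hybrid-vs-parent difference per day.

## Association scan

Mixed model y = Xβ + g + e, g ~ N(0, σ²_g K), e ~ N(0, σ²_e I). The kinship
K is built from parental SNPs either as the standardized genomic relationship
matrix (per-SNP centered/scaled allele counts, cross-products averaged over
SNPs, normalized to unit mean diagonal) or as identity-by-state sharing; SNPs
with more than 20% missingness or no variation are dropped and remaining
missing calls mean-imputed (inside the scan only — files preserve
missingness). Hybrids inherit their variable parent's kinship row: all
hybrids of a population share the reference genome, so their relatedness is
driven by the variable parent.

λ = σ²_g/σ²_e is estimated once per response by REML profiled on the
eigendecomposition of K: a 61-point grid on log₁₀λ ∈ [−5, 5] followed by
bounded scalar refinement between the best point's neighbours. The procedure
is deterministic and needs no seed. A flat restricted likelihood (K
proportional to I, λ unidentifiable) or a grid-boundary optimum is flagged;
at the lower boundary the fit falls back to λ = 0 (ordinary least squares).
Per-SNP testing whitens the response and predictors by (λs_i + 1)^(−1/2) in
the eigenbasis and reduces each SNP's GLS fit to a two-parameter weighted
regression, vectorized over SNPs; effects, SEs and two-sided p-values come
from the t statistic with n − 2 degrees of freedom. This is the standard
two-stage ("population parameters previously determined") approximation; an
exact mode re-estimates λ per SNP for cross-checking. The two agree to
|Δ −log₁₀ p| ≤ 0.2 under null architectures; at a strong causal locus the
two-stage scan is conservative because the null fit absorbs QTL variance into
σ²_g — a known property of the approximation, not a defect of either mode.

Minor-allele frequencies are computed over the samples entering each model
(the variable parents, for both encodings) and SNPs with MAF strictly below
0.05 are removed; a SNP at exactly the threshold is kept. Constant predictors
after filtering are skipped with a reason. BH q-values are computed within
each (trait, model, population) scan, never pooled across traits. Scan
summaries flag SNPs by two criteria separately: −log₁₀(p) strictly greater
than 4, and q < 0.05. The additive encoding's orientation (reference
homozygote = 1) is a convention; the `nonref` flag flips only the effect
sign, which the tests assert. A per-SNP contingency of heterozygous vs
homozygous hybrids across MPH bins supports allele-class-by-heterosis-class
summaries at a focal SNP.

## Synthetic-data generator

The generator defines the conditions every statistical guarantee is tested
under. Defaults mirror the two-population design: 104 inbred accessions, two
reference lines, populations of 100 and 99 hybrids sharing 95 variable
parents, 10 replicates per genotype, nine traits with baselines and genetic
SDs on the scale of the real panel (e.g. flowering time 29 days ± 4.8;
height 50 cm ± 8.5). The SNP panel defaults to 1000 markers on 5
chromosomes — a desk-scale stand-in for a dense array that preserves the
design structure; allele frequencies are drawn independently per SNP within
(0.1, 0.5), i.e. no linkage disequilibrium, the simplest null that exercises
every stage.

Genotypic values are baseline + polygenic additive score + Σ QTL effects,
where a QTL contributes (+a, d, −a) for (2, 1, 0) copies of the counted
allele; |d| > |a| represents overdominance. The polygenic score draws one
additive effect per SNP and is affinely standardized across the inbred panel
to the trait's configured genetic SD; because F1 allele counts are parental
averages and the map is affine, additive architectures satisfy the mid-parent
identity exactly (noise-free MPH_ABS ≡ 0). Replicate noise is i.i.d.
Gaussian; its default SD of 0.8 × the genetic SD puts H² near 0.6, the middle
of the range replicated traits show in panels of this kind. No replicate-
level variance figures exist to calibrate against, so these defaults aim at
realistic CV ranges, not exact values. Growth curves are per-plant logistic
series with genotype-level lognormal variation in rate and asymptote,
per-plant onset jitter, and a configurable hybrid establishment advantage
(default 2.5 days earlier).

What the generator deliberately does not emulate: linkage disequilibrium and
recombination (hybrids are F1 only), block or GxE effects (block effects are
unidentifiable from population-level summaries), maternal/cytoplasmic
effects, and epigenetic inheritance. Tests passing on these panels therefore
demonstrate the correctness of the statistical machinery under the stated
model, not robustness to LD, spatial structure, or non-Gaussian noise in real
field data.

All randomness flows from a single integer seed through per-stage substreams
(genotypes, traits, curves), so identical configurations reproduce
byte-identical outputs and individual stages can be regenerated in isolation.

## Numerical and design choices

- Genotype calls outside {0, 1, 2, missing}, duplicate observation keys and
  unknown role labels are rejected, never coerced.
- QTL effects are oriented to the allele whose count the genotype matrix
  stores. With two reference parents a single matrix cannot be oriented to
  both, and shared accessions must have population-independent phenotypes;
  the global orientation is a pure sign convention.
- Kinship eigenvalues are clipped at zero within a 1e-6 relative tolerance;
  more negative spectra are rejected as non-PSD.
- BH q-values delegate to statsmodels' step-up implementation; the test suite
  checks it against a literal brute-force construction (agreement to one ulp).
- Scan problem sizes in tests and the acceptance script (100 hybrids × 1000
  SNPs, 50-run power studies) were chosen as the smallest designs at which
  the statistical properties under test are well-resolved.

## Known limitations

- REML λ estimates from a single realization are noisy even at n = 200 with
  structured kinship; parameter-recovery checks therefore test the median
  across seeds. The optimizer itself matches a brute-force matrix-inversion
  REML grid to < 0.05 in log₁₀ λ.
- The two-stage scan loses power at strong loci relative to per-SNP REML (see
  above); the exact mode exists but costs one eigen-REML fit per SNP.
- H² from genotype means is biased upward by V_E/r; use the ANOVA estimator
  when replicate counts are small and unbalanced.
- Real supplementary phenotype tables can be ingested via the trait-table
  reader (pooled observations as single replicates, missing values
  preserved), but no external dataset ships with the package.
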