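# Methods

This note documents the models and estimators implemented in
`paleodel`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not demonstrate about real data.

## Neutral expectation of archaic allele sharing (`demog`)

**Model.** Each variant is an independent, freely recombining locus: a
single coalescent genealogy for 216 YRI haploid genomes plus 2 haploids
for each of four archaic genomes (Denisovan, Altai, Vindija and
Chagyrskaya Neanderthals), simulated with msprime on the diploid
timescale. The default split topology is: Vindija–Chagyrskaya at 90 ky,
Altai at 130 ky, Denisovan at 400 ky, AMH–archaic at 700 ky, with a
generation time of 29 years. The archaic branch has constant diploid
Ne = 1,000. The AMH/ancestral lineage takes either a constant size
(default 14,474, the value used in the structured-ancestry runs) or a
piecewise-constant epoch table; variable-Ne histories inferred from
genome-wide genealogies can be entered as such tables. Exactly one
mutation is placed on each genealogy with probability proportional to
branch length (the `ms -s 1` convention), so every locus is segregating
in the full sample and the denominator definition is exact.

**Measurement.** The sharing proportion is computed over variants that
are YRI-polymorphic with minor allele count > 1 — both alleles carried
by ≥ 2 of the 216 YRI haplotypes; derived alleles fixed in YRI are
excluded — and counts the fraction with ≥ 1 derived archaic haplotype.
An empty denominator is an explicit signal (NaN proportion), never a
division error. Frequency-binned sharing partitions (0, 1] into equal
bins on the YRI derived frequency; empty bins report NaN.

**Archaic sampling times.** By default archaic haplotypes are sampled at
the present day, matching plain-ms usage; specimen-age sampling
(~120/80/50/70 ky) is available via `archaic_sampling_times`.

**Structured ancestry.** Backward in time, at the AMH–archaic split the
remaining lineages enter a symmetric island model of three demes of
diploid Ne 10,000 that persists indefinitely pastward. Lineages are
scattered uniformly across demes (the ms `-es` encoding of splitting a
population into latent subgroups); a variant with fixed source demes
per lineage group is available but degenerates at small m, because the
sampled population's ancestors then fully coalesce inside one deme
before migrating and essentially no deep YRI polymorphism survives.
Low migration preserves deep trans-species polymorphism, so the sharing
proportion *decreases* with m toward the panmictic limit (one merged
ancestral population of 30,000).

**Migration conventions.** `StructuredAncestryModel.m` is the
per-ordered-pair migrant fraction (msprime semantics). The classic ms
`-I` flag instead takes the *total* fraction of each subpopulation
replaced by migrants per generation and splits it evenly among the
other subpopulations; the two are related by
m_total = (n−1)·m_pair, exposed as `total_migrant_fraction`. Scan
results are compared in the total (ms) convention.

**Migration scan.** `scan_migration` simulates the sharing proportion on
a log-spaced m grid and returns the largest m whose sharing still
reaches the target (13.7%, the empirical proportion of ancient SNVs).
Under the study conditions the curve crosses the target on a flat
shoulder (~13.8% at m_pair = 2.5e-5 declining to a plateau of ~12.5%),
so raw per-point thresholding is dominated by Monte-Carlo noise at the
plateau. Because monotone non-increase in m is a verified property of
the model, the scan pools noise with a decreasing isotonic regression
(weighted by per-point denominators) before thresholding;
`smooth="none"` restores raw thresholding. Default grid: 33 points over
per-pair m in (1.25e-8, 1.25e-3), i.e. M = 4Nm_total in (0.01, 100).

**SFS comparison.** Goodness of fit between an observed and a
simulated-expected derived-allele-count spectrum uses a chi-square
statistic with adjacent frequency classes pooled until every expected
cell reaches 5; the choice of a chi-square goodness-of-fit test is a
package design decision.

## Read-depth genotyping (`archaic_depth`)

Reads and windows are 0-based half-open intervals; a read counts for a
window if they overlap by ≥ 1 bp (a read spanning two windows counts in
both). Normalized depth is count divided by window size. The modified
Z-score uses the unscaled median absolute deviation — no 0.6745
consistency constant — exactly as the calling threshold of −5 was
chosen; an optional switch applies the constant. The MAD is taken per
genome across all candidate windows by default, with a per-chromosome
option. A zero MAD raises an explicit
degenerate-spread error. Calls are strict (< −5) and binary: the caller
does not distinguish heterozygous from homozygous deletions. Calls are
invariant to uniform coverage rescaling, since median and MAD scale
together.

## LD companions and classification (`ld_classify`)

Haplotype r² is D²/(p_a q_a p_b q_b) on phased haplotypes. Companions
are SNVs with minor allele count > 1 within 50 kb of the nearer deletion
breakpoint (midpoint option available) whose derived allele has r²
strictly above 0.9 with the deletion allele. Deletions with no
companion cannot be screened for recurrence or introgression and are
excluded from classification (reported separately); this biases the
retained set toward low-recombination regions, conservatively for the
ancient-excess argument.

Shared deletions are partitioned with strict precedence:

1. **recurrent** — no companion derived allele present in any archaic
   genome carrying the deletion;
2. **introgressed** — YRI deletion allele count exactly 0 (a literal
   reading of "absent in Yoruba") and ≥ 1 companion on the published
   S*-significant introgressed-SNV list;
3. **ancient** — the remainder.

SNV "presence" in an archaic genome means ≥ 1 derived copy in that
genome's genotype record. Non-shared deletions are human-specific.

## Stability statistic and annotation transfer (`traj_stats`)

For each variant, f(t) is the number of ancestral lineages of the
present-day sample carrying the derived allele divided by the total
lineages remaining at time t (read at the grid time nearest the target).
The statistic is χ² = z², where z standardizes
Δ = f(5,000 y) − f(50,000 y) within strata of present-day frequency.
Variants whose lineage count at 50,000 y does not exceed 10% of the
sample size are excluded. Open choices, fixed as follows: strata are
deciles (quantile bins) of present-day derived frequency; a stratum
with < 2 members is flagged unstandardizable; an all-equal stratum
(zero SD, up to floating noise) yields z = 0.

**Domain of validity.** The χ²₁ null is an asymptotic claim. With
Ne ≈ 14,474 about 30 lineages remain at 50 ky, so for variants at
present-day frequency below ~5% or above ~70% the lineage-count change
is too discrete and skewed for the normal approximation, and z² departs
from χ²₁ in the tails. For intermediate-frequency variants — the regime
of the common deletion polymorphisms this statistic is applied to — the
calibration is clean (simulation: mean ≈ 1.05, KS vs χ²₁ p ≈ 0.5 at
n = 5,000). The calibration test therefore evaluates neutral variants
with present-day frequency in (0.1, 0.9).

Ages and stdβ² scores are never computed from genotypes; they are
transferred from companion SNVs: age as the maximum companion age
(dating-database rule) or the mean over companions tagging at r² > 0.9
(genealogy rule, always ≤ the max); stdβ² as the maximum (BETAMAX) or
as the score of the nearest companion among those attaining the highest
r², distance ties broken by lower position (BETAPRIME — the tie-break
is a package design decision).

## Overdominance simulator (`overdom`)

Genotype fitnesses are (1, 1+sh, 1+s); overdominance means the
heterozygote beats both homozygotes, with deterministic equilibrium
p* = h/(2h−1) under this parameterization (10/19 ≈ 0.526 at h = 10).
Trajectories are forward Wright–Fisher paths (viability-weighted
binomial sampling, frequency granularity 1/2N, default N = 10,000)
started at 1/(2N) and conditioned by rejection on segregating through a
fixed age, optionally with the present-day frequency inside a band;
the sampler reports its acceptance rate and fails loudly when the
budget is exhausted, since neutral segregation over tens of thousands
of generations is rare.

Linked variation is drawn from the structured coalescent conditioned on
the trajectory: the sample splits into derived/ancestral classes by
present-day frequency; within a class of k lineages the per-generation
coalescence probability is k(k−1)/2 / (2N·x_c); a lineage switches
class by recombination with probability (ρ/4N)·(frequency of the other
class); at the allele's origin the derived class merges into one
lineage that joins the ancestral class, and the remainder follows a
neutral coalescent of size 2N. Neutral mutations fall on branches at
θ/(4N) per generation. In the near-fixation, no-recombination limit the
derived class reproduces the neutral panmictic π = θ (verified within
Monte-Carlo error). `psecoal_sample` instead conditions a plain neutral
coalescent sample on containing a site at derived count 22–28 of 50
(frequency ≈ 0.44–0.56).

Summary statistics use the standard definitions (Watterson's θ = S/a₁;
π as mean pairwise differences; Tajima's D with the standard variance
constants; ZnS as mean pairwise r²; Fay & Wu's H = π − θ_H with
θ_H = Σ 2 S_i i² / (n(n−1)); haplotype count K and diversity
(n/(n−1))(1 − Σ p_k²)); all are verified against brute-force
enumeration oracles. PCA operates on the correlation form (columns
standardized; rows with undefined statistics dropped listwise;
zero-variance columns removed), and the separability report carries
per-statistic two-sided rank-sum p-values with Bonferroni correction
plus PC1/PC2 range-overlap coefficients.

**Scaled separability conditions.** The separability property (no
single statistic distinguishes overdominance from neutrality at matched
focal frequency and age) is evaluated at a diffusion-faithful rescaling
of the full-scale scenario: N = 1,000, age 4,000 generations, s = 0.05,
h = 10, which preserves 2Ns = 100, 2Nsh = 1,000, age = 2·(2N)
generations and the equilibrium 10/19, with θ = ρ = 10 per locus and
the focal band 0.44–0.56. The rescaling keeps every dimensionless
parameter of the coalescent process while making neutral rejection
sampling tractable.

## Synthetic cohorts (`synth`)

Defaults are the study conditions: population sizes YRI 108 / CEU 103 /
CHB 99 diploids, four archaic genomes, mean archaic depth 30 reads per
100 bp read length, deletion windows 1–10 kb, category mix equal to the
observed composition of the real deletion dataset (88.2% human-specific,
1.1% recurrent, 1.9% introgressed, 8.8% ancient of 4,863 deletions).
The default cohort size of 1,000 deletions keeps end-to-end runs fast;
all counts scale through `SynthConfig`.

Loci are spaced 200 kb apart (beyond twice the 50 kb LD radius), so
loci are independent. LD is planted by copying the deletion status onto
companion SNVs and flipping a balanced set of c carriers and c
non-carriers, which preserves allele frequency and gives
r = 1 − c/(n·p(1−p)) exactly in expectation; c targets the midpoint
between the configured r² floor and 1, shrinking toward a perfect copy
if sampling noise undershoots, and failing loudly naming the locus when
no companion can reach the target. Archaic reads are placed uniformly
at Poisson numbers around each window; carriers of a deletion have
reads overlapping the window thinned to a configurable residual
fraction (default 0 — a homozygous deletion). Annotation tables are
constructed consistently with the planted truth (pre-split companion
ages for ancient deletions, GWAS rows below 1e-8 only for flagged
deletions, exon rows overlapping exactly the exonic deletions), and
trajectory tables come from neutral coalescent lineage counts on a grid
containing 5,000 and 50,000 years. All randomness flows from the config
seed through named substreams, and re-running any generator reproduces
byte-identical files.

**What the synthetic data does not emulate:** recombination maps and
realistic LD decay (companions are direct noisy copies), sequencing
error and ancient-DNA damage, GC-biased coverage, multi-allelic or
overlapping deletions, background archaic allele sharing at non-planted
SNVs, and realistic SFS shapes for background SNVs. Passing the
planted-truth suites therefore demonstrates correctness of the
*measurement machinery* under the stated generative model, not
robustness to every artefact of real archaic genomes.

## Enrichment tests (`enrich`)

Analyses are restricted to deletions with pooled allele frequency > 5%
across YRI+CEU+CHB (a caller-side filter with logged before/after
counts). Empirical p-values use the add-one correction
p = (1 + #{more extreme}) / (n_perm + 1) and are two-sided on the
difference (the conservative reading of "more extreme"). For binary
features, label shuffling is
sampled exactly as a hypergeometric draw of the feature count among
ancient labels; the machinery matches exhaustive enumeration on small
inputs. Length percentiles use linear interpolation between order
statistics (the quantile rule being unstated). Category enrichment
consumes a curated trait-to-category map as data and reports raw
per-category p-values; multiple-testing correction across categories is
deliberately left to the caller.

## Problem sizes

Default verification sizes were chosen to give tight Monte-Carlo error
on one CPU: 200 replicates × 5,000 variants for the neutral sharing
distribution; 33 grid points × 8,000 (script) or 4,000 (test suite)
variants per point for the migration scan; 5,000 variants for the χ²
calibration; 100 replicates per scenario and three seeds for the
separability property; 1,000-deletion cohorts across five seeds for the
caller and classifier recovery suites.
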