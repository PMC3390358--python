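# Methods

## Overview

`synassoc` contrasts the signatures of *synthetic* associations
(significant common-marker signals driven by rare causal variants) with
*natural* associations (common causal variants) in simulated
case-control GWAS. The pipeline has five stages — panel simulation,
mosaic expansion, disease-risk assignment, region-wide association
scanning, and signature statistics — each a library module with the
`analysis/` drivers and the CLI as thin wrappers.

## Synthetic data

**Coalescent panels.** A disease locus (default 100 kb) plus flanks
(default 3 cM per side) is simulated with msprime under one of two
presets: `constant` (Ne = 10,000) and `bottleneck_growth` (Ne = 10,000
until 2,000 generations ago, bottleneck to 1,000, exponential growth to
10⁶ at present). The growth preset produces the rare-variant excess
characteristic of European-ancestry samples (in our default draws ~72%
of variants below MAF 0.04, vs ~45% under the constant preset).
Mutation rate is 1.25×10⁻⁸ per bp per generation; the recombination map
is piecewise with 100-kb segments whose rates are lognormal around
1.2 cM/Mb (σ = 0.6 on the log scale), giving realistic broad-scale map
heterogeneity; flank extents are defined in genetic distance, so their
physical size follows from the drawn rates. The default panel size is
220 haplotypes, matching the scale of resequencing reference panels.
Sites are biallelic 0/1 with 1-based physical positions; genetic
positions come from linear interpolation on the map, with constant-rate
extrapolation beyond the terminal anchors.

**Outgroup for the age partition.** For the mutation-age analysis a
sister population is simulated that splits from the focal population
(default 1,000 generations ago), the ancestral lineage following the
focal preset. The split time is effectively the age threshold of the
classification: a focal rare variant whose minor allele appears in the
sister panel is almost surely older than the split ("older"), one absent
from it is predominantly younger ("more_recent"). This is the synthetic analogue of
classifying against second-population resequencing panels; because both
classes are defined by presence in a finite sample, some old variants
lost by drift in the sister population are misclassified as recent, a
caveat the classification shares with its empirical counterpart.

**Mosaic expansion.** Panels are expanded to GWAS scale (default 10,000
diploids) with a Li–Stephens-style resampler: each output haplotype
starts from a uniformly chosen template and, between adjacent variants
separated by *d* cM, switches to a new uniform template with probability
1 − exp(−λ·d). The default λ = 4·Ne·0.01/k per cM (k = panel haplotype
count) is the Li–Stephens population-scaled switching rate; the per-site
copying-error rate ε defaults to 10⁻⁴ (near zero — the expansion is
meant to replicate, not mutate). Tests verify that expanded allele
frequencies stay inside exact binomial envelopes and that binned mean
r² decay (0.01-cM bins) matches the source panel within 0.05 for common
variants. Because the copying process is Markov in genetic distance,
expanding a column subset of the panel is distributionally identical to
expanding everything and subsetting; the pipeline exploits this and
expands only the analysis columns (array markers plus all disease-locus
variants), which keeps a 20,000-haplotype expansion around 100 MB.

**Array ascertainment.** Commercial genome-wide arrays have a strongly
common-biased MAF spectrum: their SNPs were discovered in small panels
and then selected as informative tags. We emulate this with a double-hit
discovery model — a variant is eligible if its panel MAF is ≥ 0.05 *and*
its minor allele is seen at least twice in a random 24-haplotype
discovery subsample — followed by one marker per 2-kb bin drawn with
probability proportional to discovery-sample heterozygosity 2f(1−f).
Under the growth preset this yields ~2,000–2,500 markers over the ~6-cM
region with ~11–13% of markers below MAF 0.1, versus ~26% under a pure
frequency floor. All three knobs (floor, spacing, discovery depth) are
arguments of `ascertain_array`.

## Disease model

Scenarios fix the number of causal variants, a risk-allele frequency
window measured in the *expanded* sample (common: 0.1–0.3; rare:
0.005–0.04; the age analysis narrows to 0.005–0.02, whose uniform mean
is 0.0125), a GRR γ, and the baseline risk π₀ = 0.15. Causal variants
are drawn uniformly from eligible sites inside the central locus only
(never the flanks), excluding singletons. Individual risk is
multiplicative per risk-allele copy, p = min(1, π₀·γᵃ); γ = 1 is then an
exact null. A carrier-dominant alternative (p = π₀·γ for a ≥ 1) is
available via `combination="carrier"` since the verbal description
"elevated if the individual has one or more risk alleles" admits either
reading. Statuses are Bernoulli(pᵢ); 1000 cases and 1000 controls are
sampled without replacement from the affected/unaffected pools, redrawn
(up to 10 times) if a pool falls short, which rare-causal scenarios can
produce. The standard design runs 50 causal sets × 10 phenotype
replicates per scenario and pools the 500 tests.

## Association scan

Each test fits logit P(case) = β₀ + β₁·g per marker by Newton scoring on
the 2×3 phenotype-by-dosage table (equivalent to, and cross-checked in
the tests against, a standard IRLS logistic fit; on a binary predictor
β₁ equals the 2×2 log odds ratio exactly). Significance is a Wald test
against α/M with M the number of markers polymorphic in the sampled
cohort; monomorphic markers are reported NA and excluded from M. Markers
showing separation or non-convergence (|β₁| > 12, exploding SE, or no
convergence in 40 iterations) are refitted with Firth's bias-reducing
penalty on the same grouped representation and flagged — dropping them,
as some tools do, would bias the capture statistics against the rare-MAF
markers that matter most here. The tested set is every array marker
whose genetic position lies in the closed interval [locus start − 3 cM,
locus end + 3 cM], minus markers that are themselves causal variants.

## Signature statistics

*Distances.* For each significant marker, r² against every causal
variant is computed from phased haplotype counts; the record holds the
genetic distance to the argmax-r² causal (ties broken by genetic
proximity, then bp — deterministic and conservative) and to the closest
causal. Capture curves report, over a 0–10 cM window grid (0.005-cM
steps), the fraction of tests with at least one association within the
window of its highest-r² causal; denominators are tests with any
significant association.

*LD blocks.* Gabriel-style blocks are estimated on array markers from
|D′| confidence intervals computed by the likelihood-grid method on
phased haplotype counts (strong LD: CI ⊆ [0.70, 1] with upper ≥ 0.98;
strong recombination: upper < 0.90; a block needs a strong outermost
pair and ≥ 95% of informative pairs strong, within a 200-kb span;
greedy acceptance by span). Accepted blocks are expanded by 0.0005 cM
per side. An association is block-captured iff it lies in a block whose
flanked interval contains a causal variant's genetic position;
associations outside all blocks count as not captured.

*MAF statistics.* Median, fraction below 0.1, and standard deviation
(n−1 denominator) of the sample MAF of pooled significant associations,
plus the MAF of each test's most significant association (p ties broken
by larger |β₁|, then bp). Scenario contrasts report differences of
pooled medians with bootstrap CIs that resample *tests* (1,000 draws,
seeded), respecting the set/replicate structure.

## Reproducibility and problem sizes

All stages derive child seeds from the master seed via
`numpy.random.SeedSequence` keyed on stable index tuples, so any single
test is independently reproducible and every per-test output row names
its seed path. The test suite and the acceptance script run the design
at desk scale — one to two loci per preset, 13–25 causal sets × 4
replicates (so ≥ 100 tests per scenario-region), full 1000+1000 cohorts
from 10,000 individuals for disease scenarios, and 2,000 individuals for
the random-label null calibration (uniform labels do not constrain the
affected pool). These sizes preserve every statistic's definition at
reduced Monte-Carlo precision; `ExperimentConfig.scale()` and the CLI
`--scale` flag change counts, never schemas.

## What the generator does and does not emulate

The synthetic world reproduces: dense rare variation with
demography-dependent site-frequency spectra, map heterogeneity,
common-biased array ascertainment, LD- and frequency-preserving cohort
expansion, and the full case/control testing design. It does **not**
emulate genotyping error, array QC filters (HWE, call-rate), gene
conversion, or recurrent mutation. The last three erode the
perfect-phylogeny allele nesting of coalescent data, in which low-MAF
markers in high r² with common variants are systematically more common
than in empirical panels; consequently the fraction of *natural*
associations with MAF < 0.1 lands at roughly 1.5–3% here rather than
below 1%, and passing tests should be read accordingly. Similarly,
Gabriel block calls on a 20,000-haplotype expansion use far tighter D′
CIs than block calls on ~100 individuals, so although block *spans*
match (~0.006 cM flanked), block coverage — and hence absolute
block-capture rates — are lower than on small empirical samples; the
natural-vs-synthetic ordering of block capture is unaffected.

## Numerical notes and edge cases

- Logistic Newton steps are clipped to ±5 per iteration; convergence is
  max |step| < 10⁻¹⁰.
- D′ likelihood grids use 1,001 points with probabilities clipped at
  10⁻¹²; CI bounds are the 5%/95% cumulative crossings.
- `r2` raises on monomorphic input; vectorized tables return NaN there.
- Maps reject non-increasing physical or decreasing genetic anchors;
  map text I/O prints 17 significant digits and parses with round-trip
  float precision, so coordinates survive file round-trips bit-exactly.
- A marker whose expanded-sample frequency drifts below the array floor
  stays on the array (as in reality); one monomorphic in a sampled
  cohort is NA for that test only.
- An empty marker set after ascertainment warns rather than raises (a
  legitimate outcome for extreme floors); empty causal pools raise with
  the eligible count.
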