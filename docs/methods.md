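# Methods

This note documents the models, estimators and numerical choices behind
`hetmap`, and what its simulation-based validation does and does not
establish.

## Generative model

**Karyotype.** The default genome mirrors a passerine assembly: 28
autosomes spanning ~5–144 Mb plus a 73 Mb Z, with chromosomes 1–7 and 1A
classed as macro-chromosomes and the rest as micro-chromosomes. All of
this is configurable; every coordinate is anchored to the chromosome
lengths.

**Crossovers.** Each gamete's crossover count on a chromosome is
Poisson with mean λ (the chromosome's genetic length in Morgans, per
sex), positions i.i.d. from
`g(x) = w·Beta(β, β) + (1 − w)·Uniform(0, 1)` scaled to the chromosome.
`w = end_weight` concentrates crossovers near chromosome ends when
β < 1. Crossovers are independent (no interference), which makes the
generator exactly Haldane-consistent: the recombinant probability of an
interval of m Morgans is (1 − e^(−2m))/2, and the expected cumulative
genetic position at physical position x is 100·λ·G(x/L) cM with G the
mixture CDF. An obligate-chiasma option draws from a zero-truncated
Poisson whose rate is solved numerically (Brent's method) so the mean
stays λ; it requires λ > 1 and mildly violates Haldane consistency, so
it is off by default.

**Defaults.** Female genetic lengths default to an avian-like scaling
of 45 + 0.55·size_Mb cM per autosome (a ~50 cM floor reflecting the
obligate crossover, growing with physical size); male lengths are
1.157× the female ones with `end_weight = 0.7`, `β = 0.5` — a male map
15.7% longer with telomere-concentrated crossovers, while the female
landscape is uniform. On Z only males recombine (females are the
heterogametic ZW sex; the W and the pseudo-autosomal region are not
modelled). The pedigree defaults to 36 full-sib families of two
offspring (144 genotyped individuals), a quarter with all four
grandparents genotyped, genotyping error 0.002 per call (a single
allele flips) and missingness 0.02 — SNP-array-like values chosen once
as realistic study conditions.

**What the generator does not emulate:** linkage-disequilibrium
background structure among founders, W-linked or pseudo-autosomal
inheritance, marker ascertainment bias, batch or plate effects, and
genotype-calling error that correlates across samples. Passing
recovery tests therefore show estimator correctness under the stated
model, not robustness to every artefact of real array data.

## Genotype QC

The filter chain is fixed: sample missingness → marker missingness
(recomputed) → founder MAF → exact Hardy–Weinberg and Mendelian-error
filters on autosomes only → merge Z back → duplicate-position
resolution (lower missingness wins; ties keep the later-listed copy).
Removal uses strict inequalities, matching PLINK. MAF and the
Hardy–Weinberg test use founders only, avoiding family-structure
inflation. The Hardy–Weinberg p-value is the exact conditional test:
conditioning on the allele counts, heterozygote counts share the parity
of the rare-allele count, and the p-value sums the probabilities of all
configurations no more probable than the observed one (computed in
normalized log space; no mid-p correction). `--me`-style filtering
treats a trio-marker as an error when the offspring dosage cannot be
composed from parentally transmittable alleles; with the per-trio
threshold at 1.0 no sample is ever removed. The chain is idempotent.

## Map estimation

Marker order is always physical; de novo ordering is out of scope.

**Transmissions.** For each parent–offspring pair, the transmitted
allele at a parent-heterozygous marker is recorded when the trio
determines it uniquely (both-heterozygous parents with a heterozygous
offspring stay unresolved; Mendelian-inconsistent calls become missing,
not exceptions). Where grandparents are genotyped, the parent's
paternal allele at each heterozygous marker is resolved from the
grandparental trio, giving phased meioses.

**Two-point estimates.** For a marker pair, a grandparent-phased parent
contributes its recombinant count k directly; a phase-unknown parent
contributes min(k, n − k), the maximum-likelihood count under r < 0.5.
Phase-unknown parents with n < 2 resolvable meioses for a pair are
excluded entirely — min(k, n − k) is identically 0 at n = 1, which
would otherwise bias maps downward. r̂ is the pooled ratio across
parents, capped at 0.49 (Haldane diverges at 0.5; capped intervals are
flagged), and converted with d = −50·ln(1 − 2r̂).

**Chromosome-long maps.** Building a cumulative map from isolated
two-point estimates wastes most meioses (a given pair is resolved in
only ~10% of them), so the map constructor works at the meiosis level:

- Each parent is phased along the chromosome by chaining consecutive
  informative markers. Grandparent anchors fix a link's phase exactly;
  otherwise the relative phase is the majority vote of the offspring
  resolved at both ends — the per-link analogue of min(k, n − k).
- Per link, the folded switch count and voter count accrue to the
  atomic marker intervals it spans (spread proportionally to physical
  length). A tied vote is orientation-free for counting (at m = 2,
  e = 1 exactly one of the two meioses recombined, whichever the
  phase), so ties still count their recombinant.
- For phase purposes, ties and links with fewer than two voters are
  chain *breaks*. A meiosis unresolved at intermediate markers
  contributes one Bernoulli span between its consecutive resolved
  markers, but only when no break lies inside; since that meiosis is
  never a voter at those links, the censoring is independent of its own
  recombination status and costs coverage, not bias.
- Genotyping errors masquerade as immediate double crossovers. A
  resolved call whose two nearest resolved neighbours share an origin
  different from its own — judged against a leave-one-out phase
  reference, so a meiosis cannot poison its own test — is masked before
  counting. True double crossovers within a few marker intervals are
  orders of magnitude rarer than a miscalled genotype at array error
  rates, so the masking trades a negligible loss of genuine events for
  a large bias reduction.

Atomic intervals with length-weighted coverage below `n_min` (default
5 meioses) are merged rightward until coverage suffices; within any
multi-marker span the estimated distance is interpolated linearly in
physical position. Cumulative maps start at 0 cM at the first marker
and are non-decreasing by construction. Chromosomes with ≤ 70 markers
are dropped. The sex-averaged map is re-estimated from the pooled
male + female meioses (not averaged from the two sex maps), which keeps
it between the female and male lengths per chromosome.

**Known limitations.** The map is measured between the first and last
marker, so crossover mass beyond the terminal markers is invisible —
negligible for uniform landscapes, a few percent for strongly
telomere-concentrated ones. Residual genotyping-error inflation
survives the double-recombinant masking (errors at terminal resolved
markers and at links without a leave-one-out reference), so maps built
from error-prone genotypes still come out somewhat long.
Likelihood-based error modelling over the whole pedigree would reduce
this further but is out of scope; recovery validation is therefore run
on error-free genotypes, where replicate-averaged lengths are accurate
to within 10% per chromosome and the male:female total-length ratio is
recovered to within ±0.03.

**Contig ordering.** Contigs with ≥ 3 markers are ordered by mean
genetic position; orientation is the sign of the within-contig rank
correlation of physical against genetic position (ambiguous
correlations default to '+' and are flagged); output is AGP 2.1 with
100 bp gaps. Steep terminal runs (> 2 cM per marker within < 100 kb by
default) are flagged for manual truncation, never removed
automatically.

## Landscape statistics

Per-chromosome rate is map length over physical size; the mean
autosomal rate is the ratio of totals, not the mean of ratios. The
chromosome-scale heterochiasmy index is (F − M)/A; at the interval
scale the denominator is the mean of the two sex rates — the only
reading consistent with the ±2 bounds (+2 ⇔ no male recombination).
When neither sex recombines in an interval the index is defined as 0.

Intervals tile [0, L) in fixed 1 Mb bins anchored at 0 (the trailing
partial bin is kept; bin identity is reported so users can re-anchor).
An interval's rate is the genetic distance between its first and last
marker over their physical separation; intervals with fewer than two
markers are excluded from downstream statistics rather than imputed.
Gene counts use strict containment of *named* genes in the half-open
interval; distance to the nearest chromosome end uses the interval
midpoint, in bp and rescaled to [0, 0.5]. Marey curves use proportional
genetic position (0 to 1 per sex) and LOESS with tricube weights, local
degree 1, no robustness iterations, span = min(1, 50/n_markers);
chromosomes under 10 markers get raw points only.

## Interval-level inference

Outlier regions use Tukey fences on the raw rate difference
rate_f − rate_m (never on the relative index, which flags intervals
with trivially small absolute differences): type-7 quartiles, k = 1.5
for outliers and k = 3 for extreme heterochiasmy; values below the
lower fence are male-biased, above the upper female-biased.
Correlations are Spearman's rho with average ranks and the
t-approximation for p (no multiple-testing correction is applied, and
the report says so).

The zero-one-inflated beta regression treats an observation as boundary
with probability `zoi` (equal to 1 with probability `coi`), otherwise
Beta(μφ, (1 − μ)φ) with logit(μ) = β0 + β1·x; only μ carries the
covariate. The likelihood factorizes, so `zoi` and `coi` have
closed-form MLEs and the interior beta component is maximized
numerically (L-BFGS-B from a moment-based start plus random restarts;
non-convergence is flagged). Intervals are 95% Wald intervals from the
inverse observed information (central-difference Hessian). The
covariate is standardized before fitting for optimizer stability;
coefficients are reported on both scales. Inference is frequentist
maximum likelihood; the decision surface — does the 95% interval for β1
exclude zero, and in which direction — mirrors the credible-interval
reading of the Bayesian fit it replaces, without an MCMC dependency.
Calibration (built into `hetmap.experiments.zoib_calibration`): at
n = 5,000 with β1 = 0.8 the point estimate lands within ±0.1 and the
95% interval covers the truth in at least 90% of replicates and the
permutation null at a near-nominal rate.

## Validation experiments and problem sizes

`hetmap.experiments` packages the recovery studies the tests and the
acceptance script run:

- `recovery_study`: 12 replicate datasets of 36 families × 6 offspring
  on a four-chromosome toy genome (80/40/20/10 Mb, 500 markers each),
  uniform landscapes in both sexes and error-free genotypes — the
  conditions under which the configured lengths are identifiable within
  the marker span. Replicate-averaged lengths are compared per
  chromosome and sex (a single replicate carries 1/√(λ·216) ≈ 7%
  Poisson noise, which no estimator can beat), and the male:female
  total ratio against the configured 1.157.
- `haldane_consistency`: 20,000 gametes across a 1 Morgan interval
  against the closed form (1 − e^(−2))/2.
- `zoib_calibration`: 100 replicates at n = 5,000.
- `directional_landscape_study`: 50,000 gametes per sex on four
  chromosomes (250 markers each) with male end_weight 0.7 against a
  uniform female landscape; checks that the interval |rate_f − rate_m|
  is larger near chromosome ends (relative distance < 0.1) than
  centrally (> 0.4) and that the zoib coefficient of |HI|/2 on relative
  distance is negative with an interval excluding zero.

These sizes keep each study within a couple of minutes on one CPU while
leaving the Monte-Carlo error several times smaller than the quantities
being checked.

## Conventions

All internal interval arithmetic is 0-based half-open; marker positions
are 1-based single-base coordinates (PLINK MAP convention); BED output
is 0-based half-open and AGP 1-based inclusive; every output table
declares its convention in a header comment. Each pipeline stage draws
from its own RNG stream derived from the master seed and the stage
name, so stages rerun independently and whole-pipeline runs are
byte-reproducible under a fixed seed.
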