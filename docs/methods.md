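# Methods

## Scope and model

`genassoc` implements the statistical core of a candidate-gene case-control
association study: a handful of biallelic SNPs, genotyped by PCR-RFLP,
tested for association with a binary disease status in a few hundred
subjects. Analyses operate on contingency counts; subject-level tables are
a convenience layer on top. The bundled example dataset
(`genassoc.datasets`) carries the published counts of a North-Sardinian
breast-cancer panel — five polymorphisms in *MTHFR*, *XRCC1* and *OGG1*,
135 cases and 112 controls — which double as the package's reference
results.

## Odds ratios and confidence intervals

Every effect size is an odds ratio from a 2×2 table oriented with group 1
(cases, or the first-listed class of a case-only subgroup) in the top row
and the tested genotype/haplotype category in the left column. The 95%
interval is Woolf's logit interval with the exact normal quantile
z = 1.959964 (not 1.96); the difference is invisible at two decimals but
documented for reproducibility. Tables with a zero cell use the
Gart-adjusted logit interval: 0.5 added to **all four** cells — not only
the zero ones — for the point estimate and the interval alike. This is the
variant that reproduces the reference results (e.g. the Her2⁺ table
(2, 40 / 0, 88) gives OR 10.93, CI 0.51–232.80). Tables with an empty row
or column have no defined odds ratio and are rejected (as a statistic) or
skipped with a warning (in the pipeline), mirroring how published tables
omit such rows.

Two display quirks of the reference tables are documented rather than
imitated: their zero-cell point estimates appear truncated rather than
rounded (10.9259 printed as 10.92; 0.0961 printed as 0.09), and the Her2
interval upper bound prints as 232.81 where the computation yields 232.80.
One published row (the *MTHFR* A1298C allele-count row) lists allele
counts inconsistent with its own genotype counts; the package derives
allele counts from genotypes, giving OR 1.13 where 1.18 was printed from
the inconsistent counts.

## Hypothesis tests

Association contrasts use the classical Pearson chi-square with **no
continuity correction** — the choice that reproduces the reference
p-values 0.049 and 0.0465 — with df = (R−1)(C−1) and the upper-tail
p-value. Fisher's exact test (two-sided, by hypergeometric probability
ordering) and Student's t (pooled variance, Welch optional) are provided
for descriptive comparisons; both are delegated to scipy, with Fisher
verified in the test suite against exhaustive enumeration of all tables
with n ≤ 40.

Hardy-Weinberg equilibrium is evaluated two ways per group: the 1-df
chi-square on observed vs expected genotype counts (expectations np²,
2npq, nq² at the observed allele frequency, optional Yates correction off
by default), and the exact conditional test that sums the probabilities of
all heterozygote counts, given the allele counts, no more probable than
the observed one. The two can disagree materially at rare alleles — for
128/7/0 the chi-square gives ≈0.76 while the exact test gives ≈1.00 — and
converge only slowly as n grows (the heterozygote-count lattice coarsens
the exact p; <0.02 disagreement in ≥95% of replicates is reached around
n ≈ 20,000 at MAF 0.3). Both p-values therefore travel with every result,
and only the control-group HWE is meant to gate marker inclusion.
Monomorphic markers return p = 1 with a warning so multi-marker pipelines
do not abort.

Bonferroni thresholds are α/m reported to four significant digits with
round-half-even (0.05/18 = 0.002778; the common truncation 0.0027 is not
imitated). The example dataset declares two families: 18 descriptive
tests and 5 association tests (one per SNP).

## Inheritance models

Codominant contrasts are reported and tested per 2×2 row (het vs ref-hom,
alt-hom vs ref-hom), not as a single 2-df test, because per-row odds
ratios are what such studies tabulate. "Additive" association is rendered
as the allele-count 2×2 (each subject contributes two alleles), matching
the "Allele" rows of the reference table; a Cochran-Armitage trend test is
available separately as a model-free alternative but is not part of the
reference rendering. Codominant classes absent from both groups are
dropped with a flag; contrasts whose table has an empty margin are skipped
with a warning.

## Haplotypes and LD

For two biallelic loci the four haplotype frequencies are estimated from
unphased genotype counts by EM: all cells of the 3×3 joint-dosage table
except the double heterozygote resolve deterministically into gametes, and
the E-step splits the double-heterozygote mass between cis and trans phase
in proportion to the current frequency products. Initialisation is at
linkage equilibrium (products of observed allele frequencies), convergence
when the largest frequency change falls below 1e-10, cap 1000 iterations
(non-convergence returns the best estimate with a warning). The test suite
checks the EM against a coarse-to-fine grid maximiser of the multinomial
likelihood and against generator truth.

D is the haplotype-frequency covariance p_AB − p_A·p_B; D′ is D divided by
its attainable bound given the allele frequencies and reported as a
magnitude with the sign of D carried separately; r² is D² over the product
of the four allele variances. A monomorphic locus leaves D′ and r²
undefined (returned as missing rather than 0).

Haplotype case-control association contrasts each haplotype against the
most common haplotype in the pooled sample (ties broken by
lexicographically smallest label, making the reference deterministic);
zero-cell contrasts fall back to the Gart interval. Haplotype counts may
be supplied verbatim (the published-counts path) or estimated from cohort
genotypes via the EM; the bundled haplotype tables are consumed verbatim,
as published, without attempting to re-derive them from the genotype
table.

## Case-only subgroups and gene-environment interaction

Subgroup association replaces case/control status with a binarised
clinical variable among cases only (receptor status, Her2, Ki67 at 30%
inclusive, age at diagnosis at 40 inclusive, sporadic vs familial
disease); the machinery is otherwise identical, with the scheme's
first-listed class as group 1. The bundled OGG1×PgR and OGG1×Her2 tables
were published only as their recessive collapse; the dataset folds the
heterozygote column into the reference class, which leaves the published
recessive contrasts intact while codominant/overdominant contrasts for
those variables are degenerate and skipped.

Gene-environment interaction fits status ~ genotype + exposure +
genotype×exposure by IRLS (log-likelihood tolerance 1e-8, at most 50
iterations; statsmodels GLM/binomial) and reports the Wald test of the
interaction coefficient from the observed information. Genotype coding
defaults to dominant (0/1), with recessive and per-allele codings
available; the exposure must be binary with both levels present. Complete
or quasi-complete separation — a fitted probability within 1e-6 of 0 or 1
together with a diverging coefficient — yields a flagged result with no
p-value rather than a spurious one. No reference exposure codings were
published, so these defaults are the package's own and are labelled as
such in reports.

Covariate screening mirrors the unadjusted design of the reference
analysis: the main association path is unadjusted; a covariate can be
checked in a preliminary logistic fit and dropped when its Wald p > 0.05.

## Synthetic cohorts

The generator draws genotypes as two independent allele draws at the
configured MAF (HWE by construction), assigns disease by the logistic
model with configurable baseline odds (default 0.1, ≈9% prevalence),
genotype effect under a chosen inheritance model, and optional
exposure-main and multiplicative-interaction terms, then collects cases
and controls by rejection from the population stream (exact, at the cost
of extra draws; capped at 10⁷). Default group sizes are 135/112,
emulating the bundled study. The two-locus generator draws haplotype
pairs from a frequency 4-vector and returns both the unphased 3×3 table
and the true phased counts for oracle use. A fragment emitter produces
RFLP patterns (with configurable dropout of sub-resolution fragments) to
exercise the virtual gel caller end to end. All randomness flows from a
single seeded NumPy generator per run.

What the generator does **not** emulate: population structure,
relatedness, genotyping error beyond fragment dropout, covariate
confounding, or the retrospective sampling of real enrolment. Passing
calibration tests therefore shows the statistics are correct under the
model's own assumptions, not that real cohorts satisfy them.

## RFLP genotype calling

A marker's three genotype classes are defined by fragment-length
multisets. A pattern matches a signature when every fragment above the
resolution limit (default 25 bp — the 21–23 bp invariant control
fragments of the bundled assays may run off a 3% gel) is present at full
multiplicity and no observed fragment is foreign. Signatures whose
above-limit cores are not pairwise distinct are rejected at definition
time, which provably precludes ambiguous calls for valid markers; the
caller nevertheless refuses to guess (error naming the candidates) if
ambiguity arises, and returns missing-with-warning for patterns matching
nothing. Multiplexed digests (the XRCC1 codon-194/codon-399 assay) are
partitioned by each marker's fragment universe — disjoint by construction
— before per-marker calling.

## Problem sizes in tests and the acceptance script

Deterministic reproductions run on the published counts (247 subjects,
494 chromosomes) in well under a second. Calibration checks use 5000
null replicates at 250+250 for the chi-square type-I error, 2000
replicates at 500 per group for Woolf coverage (simulating OR 1.5, MAF
0.3, dominant), n = 10,000 for EM recovery, exhaustive enumeration for
Fisher at n ≤ 40, and 10,000 random tables for the odds-ratio
reciprocity/log-symmetry identities — sizes chosen to make the Monte
Carlo bands (e.g. type-I error in [0.04, 0.06]) tight enough to detect
real miscalibration while completing in minutes on one CPU.

## Known limitations

Two-locus haplotypes only; no phasing beyond the double heterozygote, no
multi-allelic markers, no X-chromosome handling (the bundled genes are
autosomal), no covariate-adjusted odds ratios in the main path, no exact
conditional OR intervals or mid-p Fisher variants, and no in-silico
digestion — RFLP signatures are configured, not derived from sequence.
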