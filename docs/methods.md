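# Methods

This note records the statistical models implemented, the defaults and
why they were chosen, the reasoning behind the genuinely open design
choices, and what the synthetic-data tests do and do not demonstrate.

## Data model

SSR alleles are integer fragment sizes (bp); a genotype is an unordered
pair, and a locus call is either complete or missing (`0/0` or blank on
disk, a sentinel in memory — the GenAlEx convention). Population labels
partition samples; region labels partition populations and come either
from a column in the genotype file or a population→region map supplied
as configuration, because the regional clustering itself (a Bayesian
cluster analysis in the reference study) is an input to this package,
not something it re-derives. Missing data are deleted pairwise: each
statistic uses every individual called at the loci it touches, which
maximises data use; the reference study does not state its own rule.

## Allele-frequency databases and the minimum-frequency floor

Frequencies are allele counts over `2 ×` (non-missing individuals at the
locus in the group). The forensic floor is `5/(2N)` of the group,
rounded half-up to four decimals — the only rule consistent with both
published regional thresholds (N = 381 → 0.0066, N = 1029 → 0.0024) —
and is overridable. Floored frequencies are deliberately **not**
renormalised to sum to one: leaving the excess mass in place can only
increase profile frequencies, which is the conservative direction in
court, and the reference study gives no renormalisation statement.
Floors apply only to forensic profile-frequency calculations; the
descriptive statistics (He, PIC, distances) use raw frequencies.

## Per-locus forensic parameters

He uses the unbiased small-sample correction `(2n/(2n−1))(1 − Σpᵢ²)`
(GDA convention). PIC = `1 − Σpᵢ² − Σ_{i<j} 2pᵢ²pⱼ²`. MP is the sum of
squared *observed* genotype proportions (PowerStats convention), not the
HWE-expected one, and PD = 1 − MP identically. The HWE test is the
Guo–Thompson Monte-Carlo exact test: the 2n observed alleles are
shuffled into n diploid genotypes, extremeness ranked by the conditional
probability of the genotype array given the allele counts, with
p = (#extreme + 1)/(n_perm + 1); default n_perm = 10,000. The LD test
permutes one locus's single-locus genotypes among individuals (both
marginals preserved) with a G log-likelihood-ratio statistic on the
two-locus genotype table. Both tests are deterministic under a seed.
Bonferroni thresholds are α/k.

## Weir–Cockerham F-statistics

Per allele and locus the 1984 variance components a (among populations),
b (among individuals within populations) and c (within individuals) are
computed with the exact unequal-sample-size weights, then **summed**
over alleles and loci before taking ratios ("ratio of averages", the
original recommendation and GDA's behaviour): θ = Σa/Σ(a+b+c),
f = 1 − Σc/Σ(b+c), F = 1 − Σc/Σ(a+b+c). At complete fixation there is
no within-population variation and f is reported as NaN (0/0) rather
than an arbitrary value. Confidence intervals are percentile bootstrap
over loci (n = 1000), the locus being the resampling unit as in GDA.
With only ten loci the percentile interval is known to under-cover
slightly; the recovery tests document coverage near, not exactly at,
the nominal 95%.

## Profile frequencies under the subpopulation-cum-inbreeding model

Two standard readings are implemented and labelled, because the phrase
"subpopulation-cum-inbreeding model" is used in the literature for both
and the reference study does not print its formulas:

- **unconditional-frequency** (default): the expected genotype frequency
  in a subpopulation at coancestry θ with inbreeding f,
  `f·p + (1−f)·p[θ + (1−θ)p]` for homozygotes and `(1−f)·2pq(1−θ)` for
  heterozygotes. These sum to exactly 1 over the genotype space for all
  (θ, f), which the tests assert by enumeration.
- **conditional-match**: the Balding–Nichols match probabilities
  (NRC-II 4.10) with f folded to zero, since no published combined
  (θ, f) conditional formula exists and fabricating coefficients would
  be worse than documenting the restriction.

A multilocus profile frequency is the product across loci of genotype
frequencies from floored allele frequencies; no imputation of missing
loci is allowed. Extreme profiles are all-heterozygous for the two most
common (resp. rarest, after flooring) alleles per locus, frequency ties
broken toward the smaller fragment size. Random match probability is the
reciprocal, formatted to three significant figures on the largest named
scale (million/billion/trillion/quadrillion).

A mathematical point that shaped the calibration design: conditional-
match probabilities are non-decreasing in θ for every homozygote, and
for heterozygotes exactly when `1/p + 1/q > 5` at small θ — a
heterozygote for two common alleles (p = q = 0.5 gives
`0.5(1+θ)/(1+2θ)`) *decreases* with θ. Multilocus products over
realistic multi-allelic loci are dominated by rarer alleles and grow
with θ in practice, but the monotonicity is not universal.

## Conservativeness and θ calibration

For each reference individual, d = log₁₀(P_origin/P_combined):
P_origin from the individual's own population database with θ = 0 (the
cognate population *is* the subpopulation) and the regional f; P_combined
from the pooled regional database at the calibration θ. The alternative
reading (a population-level θ inside P_origin) is exposed through the
params objects rather than hard-coded. The database is conservative when
every d < 0. Calibration walks θ up a fixed grid (step 0.005, reported
at four decimals, so published-style values like 0.1900 are
representable) and returns the first grid point with all d < 0 — in
conditional-match mode (the default for calibration, per the
monotonicity argument above) that point is grid-minimal. A θ_max cap
turns pathological cases (notably unconditional mode, where all-het
profiles get rarer as θ grows) into an explicit non-convergence report
instead of a loop. Individuals with incomplete profiles are excluded and
logged before calibration.

## Self-assignment

Leave-one-out: the focal individual's two allele copies are removed from
its own population's counts before scoring. Scoring is the
Rannala–Mountain Bayesian criterion — a Dirichlet posterior per
population with uniform prior mass 1 split as 1/K per allele (K =
alleles seen at the locus across all populations), genotype scored by
its Pólya-urn posterior-predictive probability, multiplied across the
individual's non-missing loci. This is the default criterion of the
GENECLASS2 program named by the reference study, which does not say
which criterion it ran; ties go to the first population in input order
with a logged warning. Unseen alleles retain prior mass, so no
likelihood is ever zero. Population accuracy is the percentage assigned
home; regional accuracy the percentage whose assigned population lies in
the right region.

## Distances and trees

Nei's DA = `1 − (1/L) Σ_loci Σ_alleles √(x_a y_a)`; a locus empty in
either member of a pair is dropped for that pair with a warning. UPGMA
is arithmetic-average linkage with merge ties broken by the
lexicographically smallest label pair, so output is deterministic and
ultrametric; Newick is the single tree format (branch lengths at 10
significant digits, which keeps round-tripped root-to-tip depths equal
to 1e-9). Node support bootstraps loci (POPTREE2 convention), counting
the percentage of replicate trees containing each original clade.

## cpDNA haplotypes

Coordinates are 0-based half-open internally, 1-based in reports. A
substitution site is a column with ≥ 2 distinct non-gap states (N is
missing and never creates a site). A deletion event is a maximal gap run
shared identically by some but not all samples — one event regardless of
length; overlapping but unequal runs are distinct events. A haplotype is
the state tuple over all variable sites; names H1..Hk descend by count
with ties by first observation. Samples with N at a variable site join a
haplotype only when exactly one is compatible, else they are flagged
unresolved. Inputs must be pre-aligned; alignment construction is out of
scope. Origin inference is a lookup: diagnostic (one region), shared
(several) or unknown (absent — a caveat inherent to any finite reference
collection).

## Synthetic data

The SSR generator is the standard F-model: ancestral frequencies per
locus ~ symmetric Dirichlet; regional frequencies ~ Dirichlet with
concentration `(1−θ_region)/θ_region × parent`; population frequencies
likewise with θ_pop — the Balding–Nichols parameterisation whose
expected Weir–Cockerham θ equals the parameter. Individuals are
autozygous (one draw duplicated) with probability f, else two
independent draws. Defaults (two regions × six populations × 32 trees,
ten loci, 12 alleles each, θ ≈ 0.05, f = 0.08) mirror the weakly
structured, moderately inbred tropical-tree setting the package targets;
allele labels 100 + 2k bp imitate dinucleotide ladders. Loci are
simulated unlinked — observed LD can arise only from structure and
inbreeding — and no mutation model is imposed, so the generator
reproduces the *statistical* structure (drift hierarchy, autozygosity,
allele-count spectra) but not mutational features of real
microsatellites such as allele-size constraints, homoplasy or null
alleles. Passing tests therefore validate the estimators and the
pipeline logic under the assumed model, not robustness to genotyping
artefacts.

The cpDNA generator derives haplotypes from a random reference by
single-carrier substitutions and gap runs placed apart from each other
and from marker boundaries, one dominant haplotype per region plus rare
endemics confined to one population, every defined haplotype emitted at
least once. Each simulated event is recoverable as exactly one variable
site by construction, which is what makes exact site-count and
membership recovery (ARI = 1) a meaningful oracle. Real spacer
alignments additionally contain recurrent indels, ambiguous bases and
alignment error that this generator deliberately omits.

## Problem sizes used in the shipped analyses and tests

The analysis drivers run the defaults above (384 trees; 1000 bootstrap
replicates; 2000 HWE permutations). The estimator-recovery study uses 50
replicate simulations of 30 populations × 30 individuals at θ = 0.05,
f = 0.08 with seeds equal to the replicate index; HWE calibration uses
200 null replicates of 50 individuals at 500 permutations. These sizes
give stable checks at interactive runtimes.

## Known limitations

- The combined (θ, f) conditional match probability has no published
  closed form; conditional-match mode therefore sets f = 0.
- Percentile locus-bootstrap CIs under-cover slightly at ten loci.
- θ calibration in unconditional mode may legitimately fail to converge
  (reported, not looped).
- Haplotype state calling treats a sample whose gap run extends beyond
  an event's run as *not* carrying that event; with heavily nested
  indels this can split haplotypes more finely than a human curator
  would.
- No null-allele estimation, mixture likelihood ratios, kinship indices,
  or model-based (STRUCTURE-style) clustering: region membership is an
  input.
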