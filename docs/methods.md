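# Methods

This note records the statistical models, the conventions chosen where the
design was genuinely open, the defaults of the synthetic-data generators,
and the limits of what the test suite demonstrates.

## Haplotype database

Variable sites are extracted per spacer alignment: substitution sites are
columns (outside gap runs) with at least two distinct unambiguous bases;
contiguous runs of gap-bearing columns are collapsed into a single indel
event coded as one presence/absence character regardless of length
("simple indel coding"). A sample that is partially gapped or carries an
ambiguous base inside an event gets an unknown state at that site. Whether
a multi-column indel adjacent to a substitution should ever be split into
two characters is a convention, not a fact about the data; the coding here
is declared and fixed.

Haplotypes are exact state-vector classes. IDs (H1, H2, ...) are assigned
by descending count with first-occurrence tie-break; the numbering is
presentation-only and carries no meaning downstream. Classification is
strict exact matching by default; up to k unknown sites can be tolerated
under unique-completion matching (default k = 0 — the forensically
cautious setting, since a wrong completion asserts an origin).

Origin inference is deliberately regional: a confined haplotype attributes
the sample to its region, a shared haplotype is ambiguous, a novel one is
unattributed. Population-level output is the candidate set of populations
where the haplotype was observed, never a point assignment — chloroplast
resolution does not support tracing to individual forest reserves.

## STR characterization

* Allele frequencies and observed heterozygosity use per-locus complete
  cases; multilocus profile work uses profiles complete at every locus.
* The frequency floor is 5/(2N) with N the pool's individual count.
  Flooring raises sub-floor frequencies **without renormalizing** the
  rest — the conservative convention, since renormalization would shrink
  common-allele frequencies and understate genotype probabilities.
  Renormalization is available behind a flag. Floored lookups also give
  unseen query alleles the floor mass.
* Expected heterozygosity is Nei's unbiased estimate
  (2n/(2n−1))(1 − Σp²); PIC = 1 − Σp² − Σ_{i<j} 2p_i²p_j²; MP is the sum
  of squared observed genotype proportions and PD = 1 − MP.
* The HWE exact test is Monte-Carlo: the 2n alleles are re-paired at
  random; the statistic is the conditional probability of the genotype
  array given allele counts, and p = (hits + 1)/(reps + 1). The
  linkage-equilibrium test permutes one locus's genotypes among
  individuals and uses the G statistic of the two-locus genotype
  contingency table. Full-enumeration chains are out of scope; the
  Monte-Carlo p-values are seeded, reproduce exactly, and converge within
  ±0.01 when replicates increase tenfold (default 10 000, floor 1 000).
* Multiple testing: Bonferroni (p < α/m) and sequential Holm (ascending
  p_(i) < α/(m−i+1), stopping at the first failure).

## F-statistics

Weir–Cockerham (1984) variance components per locus and allele — among
populations (a), among individuals within populations (b), within
individuals (c) — with the n̄/n_c weights for unequal sample sizes and
observed heterozygote frequencies. Multilocus estimates are ratio-of-sums:
θ = Σa/Σ(a+b+c), f = 1 − Σc/Σ(b+c). With one population, a is undefined
and only f is estimable (the small-sample b, c terms still apply; a fully
heterozygous sample gives exactly f = −1). With no within-population
variation f is 0/0 and reported as NaN.

Confidence intervals are percentile bootstrap over loci (default 1000
replicates, 2.5%/97.5% bounds), the convention when the locus panel is the
sampling unit. Populations are the grouping unit at every hierarchical
level; regional levels simply select population subsets. The test suite
checks the implementation against an independent nested-ANOVA
mean-squares formulation of the same estimator.

## Match probabilities

The conditional ("match") form is the Balding–Nichols sampling formula
for a structured population, with inbreeding entering as an IBD mixture at
the second allele draw (the equations in the README). Binding identities,
all enforced by tests: at f = 0 the formulas are Balding–Nichols; at
θ = f = 0 they are Hardy–Weinberg; the unconditional mode sums to one over
all genotypes at a locus; the homozygote match probability is strictly
increasing in θ. The heterozygote match value can drop below 2p_ip_j for
common alleles — a property of the conditional model, documented rather
than "fixed". A Dirichlet Monte-Carlo oracle (E[(2q_iq_j)²]/E[2q_iq_j]
under q ~ Dirichlet(p(1−θ)/θ)) independently confirms the heterozygote
formula.

Genotype homozygosity is passed explicitly by all internal callers; the
frequency-equality inference in `genotype_frequency` is only a
convenience for scripted use with distinct frequencies.

## Conservativeness

P_origin is computed against the profile's regional frequency database
using the regional (θ, f); the inputs are config, so the alternative
convention (national f in P_origin) is one switch away. P_combined uses
the national database. Individuals, not unique profiles, are the test
units; populations under 16 individuals are excluded; only complete
profiles enter. The θ sweep starts at the national θ estimate, steps by
0.01, recomputes only P_combined, and returns both the first grid value
achieving 100% negative d per region and the full trace (mean d,
proportion negative, mean profile frequency) for plotting. Failure to
reach full conservativeness by θ_max = 0.5 is a reported outcome, not an
error. For homozygote-only profiles the sweep is provably monotone (the
homozygote match probability increases in θ); with heterozygotes the
proportion-negative curve can be locally non-monotone, which is why the
sweep scans rather than bisects.

## Assignment

Candidate scores are Dirichlet(1/k, ..., 1/k) posterior-predictive
likelihoods with k the number of distinct alleles observed at the locus
across the whole candidate reference — the convention of the cited
Bayesian assignment method. Missing loci are skipped symmetrically.
Self-assignment removes the focal individual's two alleles from its own
population's counts (leave-one-out) by default; without it the rates are
upward-biased, which a test demonstrates. Region-level accuracy is the
share of individuals whose best *population* lies in the true region (the
alternative — pooled regional references — would change the candidate set,
not just the aggregation, and is not implemented). Ties are broken by
candidate order with a logged warning. Query assignment reports candidates
whose normalized score falls below the threshold (default 80%) as
unassigned.

## Synthetic data

The STR generator is hierarchical Dirichlet: per locus, ancestral
frequencies ~ symmetric Dirichlet over A alleles (A drawn uniformly from
12–31 unless fixed); regional ancestral vectors ~ Dirichlet(ancestral ·
(1−θ_b)/θ_b); population vectors ~ Dirichlet(regional · (1−θ_r)/θ_r);
genotypes take one draw with probability f (IBD) and two otherwise;
calls are masked missing at rate 0.005. Defaults are the reference study
design: 27 populations with the published sample sizes (1032 individuals,
933 Western / 99 Eastern), θ_r = 0.0333/0.1064 and f = 0.0358/0.1248 for
Western/Eastern. The between-region layer θ_b = 0.10 was set so the pooled
national θ̂ lands near the study's 0.06 given those regional values; the
pooled estimate is dominated by the large Western stratum, so θ_b must
exceed the within-region values. Because the generator *is* the model
under which the θ-corrected match probabilities and the W–C estimators are
derived, parameter recovery is a fair test of the estimators — and no more
than that: passing says nothing about mutation dynamics, null alleles,
genotyping error, or isolation-by-distance in real populations, none of
which the generator emulates. Allele labels are arbitrary 2-bp ladders,
not a mutation model.

The chloroplast generator is constructive, not coalescent: it plans a
haplotype count vector (one widespread western haplotype at 57.5% of 214
samples, present in every western population; exactly two shared
haplotypes; eight eastern-confined; sixteen singletons), deals haplotypes
into populations under the per-population sample sizes, and embeds the 39
variable sites (31 substitutions, 8 two-column indel events) into seven
alignments of lengths 314/277/531/449/362/559/400 bp with sites spaced so
events never merge. Haplotype-to-site structure is combinatorial (each
non-reference haplotype owns one or two derived sites), so the database
has no phylogeographic signal beyond the placement — sufficient for
exercising extraction, collapse, classification and attribution, and
nothing else.

The planted-stand fixture emits 40 haplotype calls in the composition
27 H1 / 4 H2 / 2 H3 / 1 H5 / 6 novel (novel vectors are two-site
combinations absent from the database) plus 40 STR queries drawn from the
latent frequencies of four northwestern populations (codes 10, 12, 13,
15), for the end-to-end query demonstration.

## Numerical and scale choices

* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; fixed seeds give byte-identical datasets.
* Monte-Carlo exact tests compare log-probabilities with a 1e−9 slack to
  absorb float noise in the "as extreme" comparison.
* The suite's calibration runs use 300 null loci / 150 null pairs at
  n = 100 with 1500 replicates, and 50 simulation seeds for bootstrap-CI
  coverage — sizes chosen to keep Monte-Carlo error well inside the
  asserted 99% binomial bands while the full suite stays fast.
* Degenerate inputs are defined, not fatal: monomorphic loci give p = 1
  exact tests and (A=1, Ho=He=PIC=0, MP=1, PD=0) summaries; empty
  references still yield finite assignment likelihoods through the prior
  mass; fixed populations give θ = 1 with f undefined (NaN).

## Known limitations

* The haplotype database supports exclusion only to the extent of its
  sampling: absence of a haplotype from the database is evidence of a
  novel source, not proof of non-Malaysian origin.
* Exact-test p-values are Monte-Carlo, not full enumeration; at extreme
  significance they saturate at 1/(reps+1).
* The probabilistic exclusion test of the cited assignment program
  (resampling-based rank test) is out of scope; the reported score is a
  normalized likelihood, not an exclusion probability.
* Null-allele handling, mixture/kinship likelihood ratios and
  subpopulation-specific databases beyond the three pools are out of
  scope.
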