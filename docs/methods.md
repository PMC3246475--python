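# Methods

This note documents the statistical procedures, the modelled assumptions,
the synthetic-data design, and the numerical choices behind
`tp53spectrum`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and classification

Variants are expressed in 1-based coding (HGVS `c.`) coordinates on the
coding strand; intronic positions use offset notation (`c.375+1`) and
carry no CpG context. The supported grammar covers single-base
substitutions (with optional intronic offsets), deletions, insertions
and deletion–insertions; anything else is a parse error carrying the raw
string.

A substitution's category is its strand-normalized base-pair change:
the twelve possible single-base changes collapse to six pair classes
(A:T>C:G, A:T>G:C, A:T>T:A, G:C>A:T, G:C>C:G, G:C>T:A), with G:C>A:T
split into CpG and non-CpG. CpG context is evaluated on the coding
strand only: the base participates in a 5′-CG-3′ if it is a C followed
by G or a G preceded by C. Because a CpG on the coding strand pairs with
a CpG on the template strand, this covers both strands; the equivalence
is exercised in tests by comparing against an exhaustive CG-dinucleotide
scan. Two consequences worth noting:

* the CpG split is applied only to G:C>A:T transitions (the one class
  for which CpG deamination is the canonical mechanism); CpG status at
  other G:C changes is not a separate category;
* dinucleotide context at exon boundaries uses the spliced CDS
  neighbors, because only the CDS is supplied. A CpG spanning an
  exon–intron junction in the genome is therefore invisible — a known
  limitation that cannot affect any bundled analysis, whose CpG
  placements are all exon-internal.

Protein effect is predicted by translating the affected codon before and
after the change (silent / nonsense / missense); indels are frameshift
unless the net length change is a multiple of 3; offset variants are
splice. Indels never carry a substitution category; multi-base
substitutions go to `complex_other` — the safest bucket for events the
category system does not describe. In spectrum tables, "Others" is
deletions + insertions + complex/splice events, i.e. everything that is
not a single-base substitution; this definition makes the bundled
cohort's exon 5–8 "Others" cell equal 16 of 101, consistent with the
published table it mirrors.

## Spectrum comparison

Cohort spectra are compared with the uncorrected Pearson chi-square:
globally on the 2×k table (df = k−1) and per category on 2×2 tables
(category vs all others). Three deliberate choices:

* **No Yates continuity correction.** The uncorrected statistic
  reproduces the published post-hoc CpG p-value of 0.002 from the
  printed counts; the corrected statistic gives ≈0.004. The comparison
  tables at this scale (n ≈ 100 per cohort) do not need the correction,
  and consistency with the source analysis decides the tie.
* **No multiple-testing adjustment by default** (the post-hoc tests are
  descriptive follow-ups to one global test); Bonferroni-adjusted values
  are available behind a flag.
* **Expected cells below 5 raise a flag, not an exact test.** The
  `warning_small_expected` field signals the situation; switching to
  Fisher's exact test would change the family of statistics mid-analysis.

Categories with zero counts in *both* cohorts are dropped before the
global test: they contribute no information and would otherwise inflate
the degrees of freedom (and break the expected-count matrix). This also
makes the global test on a two-category table coincide exactly with the
post-hoc test, a property the suite asserts.

## The mutation-record analysis unit

Associations between mutation types and covariates use one row per
mutation, plus one row per wild-type participant. This convention is
what makes per-stratum percentages reproduce from the cohort margins:
e.g. a stratum with 46 participants, 44 of them mutated, carrying 47
mutations contributes 47 + 2 = 49 records. The record-conservation
invariant (records = mutations + wild-type participants; 132 = 120 + 12
at study scale) is asserted in tests. The cost of this convention is
that a participant with multiple mutations appears in several rows;
no within-participant correlation adjustment is applied (none was used
in the source analysis), which will mildly understate standard errors
when multiplicity is high. At the observed 10% multi-mutation rate the
effect is negligible relative to the CI widths involved.

Crude odds ratios are OR = ad/bc with Woolf CIs,
exp(ln OR ± z·√(1/a+1/b+1/c+1/d)). A zero cell makes the OR undefined
and is reported as such (`zero_cell`, rendered "(-)"); the
Haldane–Anscombe +0.5 correction is available behind a flag but off by
default, because an undefined estimate is more honest than a
correction-dependent one at these counts.

Reference levels: age < 66 years (the cohort median; age is also used
continuously), female, non-Turkmen, rural, no tobacco/opium, tea poured
≥ 4 minutes before drinking. Missing covariate values are explicit and
excluded per-analysis (complete-case).

## Logistic regression and separation

Adjusted odds ratios come from maximum-likelihood logistic regression
fitted by iteratively reweighted least squares: Newton steps on the
log-likelihood with convergence declared when the log-likelihood changes
by less than 1e-8 (cap 100 iterations). The covariate set is age
(continuous), sex, ethnicity, residence, tobacco/opium and tea interval;
the categorical age-group rows come from a model that swaps age-group in
for continuous age (and is not adjusted for it). Design matrices are
reference-coded with an explicit collinearity check.

Separation — a covariate level whose records are all events or all
non-events — drives the corresponding coefficient to ±∞. It is detected
by a diverging coefficient (|β| > 15 on the log-odds scale, far beyond
any plausible epidemiological effect) or a singular/degenerate Hessian,
and reported per level as `not_converged` rather than as a spurious
estimate; the remaining levels of the same model stay estimable and are
reported. The hottest-tea stratum of the bundled cohort, which contains
no G:C>T:A records, exercises exactly this path.

The IRLS fit is validated against statsmodels' independent
maximum-likelihood optimizer (coefficients and log-likelihood to 1e-6)
and against the saturated-model identity: with a single binary covariate
the adjusted OR equals the crude 2×2 OR exactly.

## IHC scoring and agreement

Composite score = percent category × intensity (0–12), binned 0 /
1–4 / 5–8 / 9–12 into negative / weak / moderate / strong; positive =
moderate-or-strong (configurable). Samples missing either antibody are
excluded from agreement statistics. Weighted kappa uses disagreement
weights w_ij = |i−j|/(k−1) (linear) by default, quadratic behind a flag;
the weighting scheme behind published single-number kappas is often
unstated, so neither scheme is asserted to reproduce any particular
published value — the suite instead checks the identity (κ = 1), the
independence limit (|κ| < 0.02 at n = 10⁵), and exact agreement with
scikit-learn's implementation.

Functional classes for the expression contrast: a sample with any
missense mutation is `missense`; otherwise any nonsense/splice/frameshift
makes it `protein_null`; remaining mutated samples (silent or in-frame
only) are `other_mutant`; unmutated samples are `wild_type`. The
missense-vs-null positivity contrast reuses the spectrum module's
chi-square.

## The deterministic study-scale fixture

`paper_cohort()` builds, in code, a 119-participant cohort (12 wild-type;
96/9/2 participants with 1/2/3 mutations; 120 mutations) whose stratum
margins equal the published cohort tables: per covariate stratum, the
participant count, mutated-participant count, mutation count, and the
counts of the three analysed categories (G:C>A:T, G:C>A:T-at-CpG,
G:C>T:A); the hottest-tea stratum additionally contains none of the four
category classes reported absent there. Covariate assignment is one
independent partition per covariate (the analyses are all marginal in
one covariate, so no joint distribution is asserted), found by a seeded
local-search solver that swaps participants between strata until every
constrained margin is met exactly — the build fails loudly rather than
approximately if it cannot.

The 120 mutations' category × effect × exon composition is fixed by a
plan whose exon 5–8 slice equals the published eight-way table
(8/11/3/16/26/15/5/17, total 101) and whose totals give 46 G:C>A:T
(16 at CpG), 20 G:C>T:A and 16 deletions; 9 mutations sit at hotspot
codons and 8 of the 20 G:C>T:A at PAH-adduct codons. The 19 mutations
outside exons 5–8 are distributed over exons 4, 9 and 10 with a
composition chosen once for consistency with all published totals (the
source figure does not print the full per-category breakdown outside
exons 5–8).

The gene model uses the real TP53 exon boundaries in coding coordinates
(exons 2–11; e.g. exon 5 = c.376–559, codons 126–187) but a synthetic,
deterministically generated 1182-nt CDS: the real sequence is not
bundled, and no statistic in the package depends on the sequence itself
— only on category/effect/exon composition, which the plan fixes.
Selected codons are engineered (e.g. codon 175 = CGA) so hotspot and
PAH-site placements admit the intended substitution classes, and each
exon carries a small block of utility codons guaranteeing at least one
site per required class × effect. Variant descriptions are chosen from
an exhaustive site index classified by the annotator itself, so
generated strings re-annotate to their intended class by construction
(asserted in tests); unsolicited placements avoid hotspot/PAH codons so
those tallies stay exact.

IHC ratings are generated so that, of 107 evaluable cases (12 cores
lost), the missense and protein-null classes have 50 and 36 evaluable
members with 41 and 8 positives respectively, and the two antibodies
agree on the expression category for 95 of 107 pairs. Positivity rates
for wild-type and other-mutant classes (2/12 and 2/9) are not published
per-class and were fixed once at plausibly low values; they enter no
acceptance quantity.

Two published-table inconsistencies surfaced while constructing the
fixture and are resolved as follows: the per-stage mutation totals are
not jointly consistent with the cohort's multiplicity structure, so
stage (which enters no analysis) is constrained only on participant and
mutated-participant counts; and the sex rows' printed percentages are
not consistent with the sex margins under any reading, so the fixture
follows the printed counts (which are consistent as margins) and not the
percentages.

## The synthetic-cohort generator

`simulate_cohort` is the randomized counterpart of the fixture and
defines the study conditions it emulates: covariate marginals matching
the cohort (e.g. 71.4% rural; tea 43.4/40.6/16.0% with 13/119 missing),
age ~ Normal(65.5, 11²) truncated to [30, 95], multiplicity
(12, 96, 9, 2)/119 over 0–3 mutations — making the expected mutation
total exactly 120 at n = 119 — and a baseline spectrum equal to the
120-mutation composition. Covariate effects act on category
probabilities via a multinomial logit, so a shift δ on one category is a
true odds ratio e^δ for that category against all other *mutation*
categories; the default effect set encodes the observed hottest-tea
shift (CpG transitions enriched ~5.5-fold; transversions and A:T
changes suppressed). IHC positivity is conditioned on functional class
(0.82 missense, 0.222 protein-null, 0.10 otherwise) with 12/119 cores
lost and 88.8% antibody agreement.

What the generator does *not* emulate: sequencing error and chromatogram
review, within-participant correlation of mutation categories (draws are
independent given covariates), covariate–covariate dependence (marginals
are independent), and any genomic context beyond the toy CDS. Passing
tests therefore demonstrate that the statistical machinery recovers what
the generative model plants — not that the biological conclusions of any
particular dataset are correct.

Parameter recovery (the validation harness for the adjusted-model
machinery, whose published values are not numerically reproducible
without individual-level data) simulates cohorts of 5000 participants,
200 replicates, plants a log-OR of log 6 on the CpG category in the
hottest-tea stratum, and re-estimates it through the full
annotate → record-unit → crude-OR chain: the suite requires |bias| < 0.1
on the log scale and Woolf-CI coverage in [90%, 98%]. The contrast is
taken among mutation records (wild-type excluded) because that is the
scale on which the multinomial-logit shift is exactly the odds ratio.
These problem sizes keep the whole suite under a minute for the
recovery check while leaving Monte-Carlo noise well inside the asserted
bands.

## Numerical choices and degenerate inputs

* Chi-square: scipy's contingency machinery with correction disabled;
  the O/E margin formula is the independent oracle in tests.
* Logistic link: linear predictors clipped to ±30 before
  exponentiation to avoid overflow; log-likelihood via log1p.
* Normal quantiles for Woolf CIs at (1+level)/2 from scipy.
* Empty spectra compare as an error (no information), empty mutation
  tables produce an all-zero spectrum and skip association, and an
  outcome that never (or always) occurs after complete-case filtering
  is an error rather than a degenerate fit.
* Mutating a codon that is already a stop translates as missense
  (stop-loss is not modelled separately; none of the bundled data
  contains one).
* All randomness flows through numpy Generators seeded explicitly; the
  fixture's internal seeds are fixed constants, so its output is
  byte-identical across runs and platforms.
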