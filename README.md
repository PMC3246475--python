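# tp53spectrum

Analysis toolkit for TP53 somatic mutation spectra in tumor case series,
built around the analytic chain used in esophageal squamous cell carcinoma
(ESCC) molecular epidemiology: classify each confirmed somatic mutation,
compare cohort spectra, test mutation types against exposure covariates,
and check mutation class against p53 protein expression.

It is aimed at molecular epidemiologists working with small, deeply
annotated case series — one row per confirmed mutation from direct
sequencing, a covariate table per participant, and tissue-microarray
immunohistochemistry (IHC) ratings — rather than at genome-scale variant
calling.

## What it computes

**Classification** (`annotate`). Each HGVS-c description (`c.524G>A`,
`c.5_6delCG`, `c.375+1G>T`, ...) is parsed and reduced to a
strand-normalized base-pair category as used by the IARC TP53 mutation
database: a change and its reverse complement fall in the same class
(G>A ≡ C>T ≡ G:C>A:T). G:C>A:T transitions are split by CpG dinucleotide
context (a C followed by G, or a G preceded by C, on the coding strand —
the signature of 5-methylcytosine deamination). Each record also carries a
predicted protein effect (missense / nonsense / silent / frameshift /
in-frame / splice), its codon and exon, and flags for recurrent "hotspot"
codons {175, 245, 273, 282} and PAH-adduct sites {157, 158, 245, 248, 273}.

**Spectrum comparison** (`spectrum`). Per-cohort category counts
(eight-way, or six-group with all A:T changes merged), compared with the
uncorrected Pearson chi-square on the 2×k table,

χ² = Σ (O − E)² / E,  df = k − 1,

plus per-category post-hoc 2×2 tests (category vs all others, cohort vs
cohort), unadjusted by default.

**Association analysis** (`assoc`). The analysis unit is the *mutation
record*: a participant with m ≥ 1 mutations contributes m records and a
wild-type participant contributes one record — the denominator convention
that reconciles per-stratum percentages with the cohort margins. Crude
odds ratios come from 2×2 tables, OR = ad/bc, with Woolf confidence
intervals

exp( ln OR ± z·√(1/a + 1/b + 1/c + 1/d) ),

zero-cell tables reported undefined ("(-)"). Adjusted odds ratios come
from a multivariate logistic regression fitted by iteratively reweighted
least squares, with separation / non-convergence reported per covariate
level instead of silently estimated.

**IHC concordance** (`ihc`). Composite score = percent-stained category
(0–4) × intensity (0–3), binned negative (0) / weak (1–4) / moderate
(5–8) / strong (9–12); positive means moderate-or-strong. Inter-antibody
agreement is percent agreement and weighted Cohen's kappa
(κ = 1 − ΣwO/ΣwE with linear disagreement weights by default), and
mutation functional class (missense vs protein-null) is tested against
positivity by chi-square.

**Synthetic cohorts** (`synthetic`, `paper_cohort`). A configurable
simulator draws covariates, per-participant mutation multiplicity, and
categories from a multinomial logit (covariate shifts are true odds
ratios), emitting variant descriptions that re-annotate to the intended
class by construction. A separate deterministic study-scale fixture
reproduces the published cohort's stratum margins exactly, so the whole
chain is testable without any external data.

## Worked example

```python
from tp53spectrum import (paper_cohort, count_spectrum, tehran_spectrum,
                          global_compare, build_record_units, crude_or)
from tp53spectrum.assoc import stratum_table

cohort = paper_cohort()                 # 119 participants, 120 mutations
records = cohort.annotated()

six = count_spectrum(records, exon_filter=(5, 8)).to_six_group()
print(six.counts)
# {'A:T': 22, 'Others': 16, 'GC>AT': 26, 'GC>AT_CpG': 15, 'GC>CG': 5, 'GC>TA': 17}

res = global_compare(six, tehran_spectrum().to_six_group())
print(round(res.p_value, 3), res.df)    # 0.065 5

units = build_record_units(cohort.participants, records)
t = stratum_table(units, "GC>AT_CpG", "tea_interval", "0-1", "4plus")
r = crude_or(t)
print((t.a, t.b, t.c, t.d))             # (5, 14, 3, 46)
print(f"{r.or_point:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})")  # 5.48 (1.16-25.84)
```

The global p of 0.065 at 5 df says the two cohorts' spectra differ at
borderline significance overall, driven by the CpG-transition cell
(post-hoc p = 0.002); the odds ratio says CpG transitions are about
5.5-fold enriched among the hottest-tea drinkers relative to those who
let tea cool 4 minutes or more.

The `examples/` directory has one short narrative script per capability
(annotation, spectrum comparison, odds ratios, IHC concordance,
simulation and parameter recovery); each prints the numbers it computes
and a line on what they mean. A thin CLI exposes the same chain
(`tp53spectrum annotate|spectrum|compare|assoc|ihc|simulate|full-run`).

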