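# Methods

## The interpretation problem

Site-level population databases (gnomAD-style exports) report, for each
unique variant, its transcript consequence, in-silico pathogenicity and
conservation scores, ClinVar status, and allele counts (AC) out of
allele numbers (AN) overall and per genetic-ancestry and sex stratum.
Estimating the carrier burden of damaging germline *KMT2A–D* variation
requires (i) a classification of every variant into likely benign (LB),
uncertain (VUS), likely pathogenic (LP) or pathogenic (P), and (ii)
population arithmetic turning the P/LP set into allele frequencies and
1-in-D carrier prevalences. Two classification routes are implemented so
their disagreement is itself a result: a liberal, epidemiology-oriented
manual rule scheme and a conservative ACMG/AMP evidence-combining
engine.

## Manual scheme

Decision order for a record triaged to one of ten consequence classes:

1. frameshift, nonsense, canonical splice (the ±2 intronic bases) → P;
2. missense in a hotspot region → P;
3. missense with a literature report → P;
4. missense with a ClinVar P/LP assertion → P;
5. missense with CADD ≥ 30 **or** REVEL ≥ 0.75 → LP;
6. missense with CADD in [20, 30) **or** REVEL in [0.5, 0.75) → VUS;
7. other missense → LB;
8. UTR designated ncRNA → VUS, else LB;
9. stop-lost and in-frame indels → VUS, unless scores are present and
   high (→ LP via the score branch) — a ClinVar P/LP assertion keeps
   them at VUS rather than escalating, so the P set stays restricted to
   the four types in rule 1 plus missense;
10. synonymous, intronic, non-canonical splice (> 2 and < 10 bp from
    the boundary) → LB.

Thresholds are closed on the pathogenic side exactly as written (CADD
30.0 is high; 29.99 intermediate). Missing scores never satisfy a
threshold. CADD ≥ 30 / REVEL ≥ 0.75 mark roughly the 0.1 % most
deleterious substitutions and the 20–29 / 0.5–0.74 bands the top 1 %,
which is what motivates LP vs VUS. The hotspot/literature/ClinVar
branches (2–4) all yield P, so their relative order only affects the
recorded provenance label; it is fixed as above for reproducibility.

**Hotspots.** A residue seeds a hotspot iff at least one missense
variant at that residue invokes ACMG PM1 *and* lies in a mammalian
conserved region, defined as agreement of both conservation models:
GERP ≥ 2.0 and PhyloP ≥ 1.0 by default (conventional constrained-site
values; the cutoffs are configurable because no canonical pair exists).
Seeds within `merge_window` residues merge into one region; the default
window is 0 (residue-exact) since no region-growing rule is established
for these genes. Curated regions — e.g. the first PHD finger of KMT2C,
the family's one previously described missense hotspot — can be
supplied as protein-space BED and bypass calling.

## ACMG/AMP engine

Automatic assignments: PVS1 (loss of function), PM1 (hotspot), PM2
(AF < 1e-4), PM4 (protein-length change), PP3 / BP4 (score cutoffs
mirroring the manual bands; BP4 needs both scores present and benign),
PP5 / BP6 (ClinVar), BA1 (AF > 0.05), BS1 (AF > 0.01), BP7 (synonymous
with a benign score profile). PM2 and BS1 cutoffs are common community
defaults and configurable. PS2/PM6 are structurally excluded (no
parental samples in population data); PS1, PS3, PS4, PM5, PP2 and BS2
are accepted only as user-supplied curation because they require
knowledge the inputs lack. Every invocation is logged with its
triggering annotation to a per-variant audit table.

Combining follows the published rule table; the "1 Strong ∧ …" clauses
are evaluated with ≥ counts, which is outcome-equivalent because the
≥ 2-Strong rule is checked first. If both a pathogenic-side and a
benign-side rule fire the call is CONFLICTING. When no rule fires, the
uncertain band is shaded VUS/weak-pathogenic or VUS/weak-benign by
whichever side holds any evidence, matching commercial auto-classifier
output categories. Collapse onto the shared scale: {B, LB} → LB, every
uncertain or conflicting shade → VUS, LP → LP, P → P.

The engine makes no claim of reproducing any commercial pipeline's
per-variant calls; its correctness surface is the combining table
(checked exhaustively against an independent transcription over all
≤ 6-code evidence sets) and the collapse mapping.

## Population statistics

* AF = AC/AN computed exactly; reporting rounds to 3 significant
  figures in scientific notation.
* Prevalence = 1 in round(n_individuals / count), half rounded up. Two
  conventions exist in published tables and both are implemented and
  labelled: AC-based (count = summed allele count over P/LP variants;
  approximates carriers, assuming each allele sits in a distinct
  person) and N-based (count = number of distinct P/LP variants). The
  AC-based denominator never exceeds the N-based one (each variant
  contributes ≥ 1 allele); this is asserted on every summary. The
  "abstract-style" AF companion to the N-based convention is N/(2n).
* Sex comparison: Welch (unequal-variance) two-sample t-test on the
  per-variant male and female AF vectors; Welch is the safer default
  when only "two-sample t-test" is specified. Zero-variance degenerate
  vectors return p = 1 (equal means) or 0.
* Ancestry/sex group effects: binomial GLM of allele carriage on group
  membership over aggregated (ac, an) counts — aggregated rather than
  per-variant, and labelled as such. Groups with ac = 0 or ac = an
  separate perfectly and are flagged with an unbounded CI.
* In per-gene summaries the ancestry AF denominator is the stratum AN
  (the largest AN observed for the stratum in that gene), not a sum
  over variants: allele numbers are a property of the cohort.

Default cohort size is 74,025 individuals per gene (the midpoint-scale
value of a ~74k-per-gene survey), always configurable per gene. One
published manual prevalence denominator (458 alleles → 1/161) is not
reachable from any cohort size in the stated 74,019–74,032 range — all
give 162; the package computes 162 and records the printed figure as an
inconsistency rather than chasing it.

## Synthetic cohorts

`generate_cohort` emulates a gnomAD-like *KMT2A–D* export at about one
tenth of survey scale by default: 239/299/432/460 variants per gene,
consequence mix proportional to a real export (≈ 39 % missense, 33 %
intronic, 21 % synonymous, small LOF classes), ancestry AN vector
proportioned like gnomAD v3 non-cancer (large NFE and AFR, tiny Amish
and Middle Eastern strata) scaled to 5,000 individuals for speed and
configurable up to survey scale. True allele frequencies are
singleton-heavy (60 % at 1/AN, 30 % log-uniform rare, 8 % common, 2 %
very common); stratum ACs are binomial draws from the true AF, so
ancestry ACs always sum to the total, and a variant drawn unobserved is
seeded with one allele in an AN-weighted stratum (a site-level row
exists only because the allele was seen). Missense annotations are
drawn by branch (3 % hotspot, 3 % literature, 2 % ClinVar P/LP, 2.3 %
high-score, 60 % intermediate, rest benign — mirroring the published
class shares) with scores kept 0.5 CADD / 0.01 REVEL away from every
threshold, and non-hotspot missense never invokes PM1 nor sits within a
planted region, so the planted classification is recovered by the
classifier with 100 % agreement by construction rather than by luck.

What the generator does **not** emulate: genotypes, relatedness,
linkage, per-exon coverage variation, joint sex-by-ancestry strata, or
realistic HGVS/positional annotation. Passing recovery tests therefore
demonstrates the classifier and the allele bookkeeping, not performance
on real annotation noise. One scale consequence worth knowing: at 5,000
individuals a singleton's AF is exactly 1e-4, which does not clear the
PM2 < 1e-4 cutoff, so the synthetic ACMG route is even more
conservative than on survey-scale data (typically zero P/LP); ACMG
worked examples use explicit sub-cutoff AFs instead.

`generate_from_marginals` is the deterministic counterpart: it rebuilds
requested per-gene / per-consequence / per-class marginal counts as
singleton records whose annotations force the manual classifier to the
target class (literature-driven P missense, CADD-35 LP, CADD-25 VUS,
…), and raises for infeasible combinations such as a pathogenic
synonymous variant. Running the classifier over its output reproduces
the requested marginals exactly, which is how printed summary tables
are exercised as classifier input.

## Numerical and degenerate-input choices

* Missing scores are absent (`None`), never zero; absent means
  "threshold not met".
* Structural boundary: indels with |len(ref) − len(alt)| > 50 bp are
  excluded as structural (the conventional SV size bound).
* Prevalence rounding is half-away-from-zero; count 0 yields "none
  observed" rather than a ratio.
* `an_total = 0` is rejected at construction; a stratum with AC > 0 and
  AN = 0 is an error in summaries.
* The inclusion filter is idempotent and logs every exclusion with its
  reason.

## Problem sizes

The default test and acceptance workloads are a 1,430-variant synthetic
cohort of 5,000 pseudo-individuals, the exhaustive 10-class × score ×
flag decision grid (~19,000 cells) and all ≤ 6-code ACMG evidence
subsets (~21,800 sets) — sizes chosen so the full suite runs in
seconds while the oracles remain exhaustive.

## Known limitations

* Literature reporting and several ACMG criteria are consumed as input
  flags; no text mining or external database lookup is performed.
* HGVS strings are carried, not parsed or normalised; no liftover.
* Published per-gene sex-comparison p-values and ancestry regression
  outputs cannot be reproduced without the underlying per-variant
  stratified vectors, which are not redistributable; those operations
  are validated by property tests and closed-form oracles instead.
* Intronic VUS counts reported by some manual curation efforts rely on
  unstated criteria; here intronic records stay LB unless ncRNA-flagged
  UTR rules apply.
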