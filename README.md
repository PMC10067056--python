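# kmt2pop

Germline variant interpretation and population prevalence statistics for
the *KMT2A–D* histone methyltransferase genes, built for gnomAD-style
site-level variant exports.

The *KMT2* family (*KMT2A*, *KMT2B*, *KMT2C*, *KMT2D*) encodes H3K4
methyltransferases central to developmental gene regulation; germline
loss-of-function and damaging missense variants in these genes are linked
to severe congenital syndromes and, increasingly, to leukemia
predisposition. Estimating how common putatively pathogenic germline
variants are in cancer-free adults requires classifying every unique
variant in a population database and turning allele counts into carrier
prevalence — this package implements that pipeline for epidemiological
use.

## What it does

* **Consequence triage and IO** (`variant_model`) — a ten-class
  sequence-ontology triage (frameshift, nonsense, canonical and
  non-canonical splice, missense, stop-lost, in-frame indel, synonymous,
  UTR, intronic), readers/writers for an annotated variant TSV and for
  biallelic VCF with a configurable INFO-key map, and the inclusion
  filter that drops multi-allelic and structural records.
* **Manual rule-based classifier** (`manual_classifier`) — four ordered
  categories LB < VUS < LP < P. Loss of function ⇒ P; missense in a
  mutational hotspot, with a literature report, or with a ClinVar P/LP
  assertion ⇒ P; otherwise missense is scored: CADD ≥ 30 or REVEL ≥ 0.75
  ⇒ LP, CADD 20–29 or REVEL 0.5–0.74 ⇒ VUS, else LB. Hotspots are
  protein-coordinate regions seeded by missense variants that invoke
  ACMG PM1 *and* lie in a mammalian conserved region (GERP and PhyloP
  agreement).
* **ACMG/AMP engine** (`acmg_classifier`) — explicit, configurable
  evidence assignment (PVS1, PM1, PM2, PM4, PP3, PP5, BA1, BS1, BP4,
  BP6, BP7 automatic; PS1/PS3/PS4/PM5/PP2 only via curation input;
  PS2/PM6 excluded — no parental data in population databases), the
  published combining rules, and a collapse of the fine call
  (P/LP/VUS±weak/LB/B/conflicting) onto the same four categories.
* **Population statistics** (`popstats`) — AF = AC/AN, 1-in-D prevalence
  under both the allele-count and the variant-count convention,
  ancestry- and sex-stratified summary tables, Welch t-tests of
  per-variant male vs female AFs, and logistic regression of allele
  carriage on group membership.
* **Synthetic cohorts** (`synthetic_gnomad`) — a seeded generator of
  gnomAD-like cohorts with known ground truth (true AF, planted
  classification, hotspot membership), plus a deterministic builder that
  reconstructs printed marginal count tables as classifier input.
* **CLI** (`kmt2pop classify | summarize | simulate | lollipop`) — full
  pipeline runs with per-variant calls, summary tables, hotspot BED,
  ACMG audit logs and MutationMapper-style lollipop export.

## Worked example

```python
from kmt2pop import (
    GeneratorConfig, generate_cohort, classify_cohort_manual,
    classify_cohort_acmg, summarize,
)

cohort, truth = generate_cohort(GeneratorConfig(seed=1))
manual = classify_cohort_manual(cohort)
print(manual.by_gene)
#call    LB  VUS  LP   P
#gene
#KMT2A  160   61   4  14
#KMT2B  206   81   3   9
#KMT2C  299  107   4  22
#KMT2D  332  109   6  13

summary = summarize(cohort, manual.classifications, "manual")
print(summary[["gene", "n_plp_variants", "ac", "prevalence"]].head(1))
#    gene  n_plp_variants   ac prevalence
# 0  KMT2A              18  269       1/19
```

The per-gene table counts the four interpretation categories over a
1,430-variant synthetic cohort; the summary row says *KMT2A* carries 18
P/LP variants totalling 269 alleles in 5,000 pseudo-individuals, i.e.
roughly one P/LP allele per 19 individuals under the allele-count
convention (synthetic cohorts are deliberately enriched relative to real
surveys, where denominators run into the hundreds).

Prevalence arithmetic on real published counts:

```python
from kmt2pop import prevalence, allele_frequency, format_af
from kmt2pop.popstats import PrevalenceConvention

format_af(allele_frequency(290, 148_038))          # '1.96E-03'
prevalence(290, 74_019, PrevalenceConvention.AC_BASED)   # 255
prevalence(660, 74_025, PrevalenceConvention.N_BASED)    # 112
```

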