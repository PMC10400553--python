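# cilioscreen

Variant-interpretation pipeline for NGS-based expanded carrier screening
of recessive-disease gene panels, built around a 118-gene ciliopathy
panel. It is aimed at people who build or evaluate carrier-screening
analyses: it implements the interpretation stages that sit between an
annotated variant call table and a couple-level risk report, and ships a
synthetic-cohort generator so every stage is testable without access to
patient data.

## What it computes

Given per-sample annotated calls (consequence class, gnomAD MAF, CADD,
M-CAP, seven categorical predictor calls, ClinVar/HGMD assertions, a
structure-based deleteriousness score, depth and alternate-read
fraction), a pedigree and a per-gene knowledge table, the pipeline:

1. **Call QC** — drops calls with alternate-read fraction < 16% or depth
   < 20×, gates out samples with < 85% of the exome at ≥ 20×, and
   separates remaining true calls from artifacts with a linear SVM
   (hinge loss, L2 penalty, z-scored features; decision sign(w·x + b)).
2. **Tiering** — assigns each high-confidence call exactly one tier by
   ordered rules with an audit trail:
   * `PATHOGENIC`: whitelisted recurrent allele at any MAF; or rare
     (MAF ≤ 0.1%) LOF with PVS1 + PM2 and a ClinVar-P and/or HGMD-DM
     assertion; or rare non-truncating ClinVar-P **and** HGMD-DM with
     sufficient supporting information;
   * `NOVEL_LOF`: rare predicted LOF absent from both databases
     (formally LP under PVS1 + PM2);
   * `STRONG_VUS`: rare and predicted deleterious — LOF that ClinVar
     calls VUS, ClinVar LP with limited evidence, HGMD DM/DM?, or the
     ensemble rule CADD ≥ 20 ∧ M-CAP ≥ 0.025 ∧ ≥ 4/7 predictors
     deleterious;
   * `EXCLUDED`: everything else, including database-benign calls
     (a DM label contradicted by a ClinVar benign assertion is treated
     as unreliable).
3. **Prioritization** — ranks strong VUS by the per-gene *missense
   score* ms = m/M (missense P/LP alleles over all P/LP alleles) and a
   VIPUR-style structural score; *first priority* = ms > 0.1 and
   structural score > 0.7; per-gene cohort vs patient variant-type
   spectra are compared by total-variation divergence.
4. **Cohort report** — carrier frequencies per tier set, per-individual
   burden, variant recurrence/deduplication, trio cis/trans phasing
   (child carries both or neither of a parent's same-gene pair → cis;
   exactly one → trans), couples at risk (both partners carrying a
   qualifying variant in the same gene), and observed vs expected
   carrier frequency under Hardy–Weinberg (prevalence K ⇒ q = √K,
   carrier fraction 2q(1−q)).

## Worked example

The deterministic fixture cohort (395 individuals, 177 couples of which
21 consanguineous, qualifying calls interleaved with rule-violating
distractors) classifies to an exact, known accounting:

```python
from cilioscreen.simulate import generate_reference_cohort
from cilioscreen.classify import classify_cohort
from cilioscreen.report import build_report, expected_carrier_frequency

fx = generate_reference_cohort()
tiered, counts = classify_cohort(fx.calls, fx.whitelist)
rep = build_report(tiered, fx.individuals, fx.pedigree)

print(counts.as_dict()["PATHOGENIC"])
# {'total': 48, 'lof': 26, 'missense_like': 22}
print(rep.carriers["pathogenic"])
# {'n_carriers': 43, 'frequency': 0.10886075949367088}
print(rep.carriers["reportable"])
# {'n_carriers': 80, 'frequency': 0.20253164556962025}
print(rep.recurrence["strong_vus_missense_like"]["n_unique"])
# 239
print(rep.couples["at_risk"]["strong_vus"]["n"])
# 7
```

So ~11% of the cohort carries a pathogenic allele and ~20% carries a
reportable (pathogenic or novel-LOF) allele; 262 missense-like strong-VUS
observations collapse to 239 unique variants; strong VUS are shared
within a gene by 7 couples. For a disease with prevalence 10⁻⁴,
`expected_carrier_frequency(1e-4)` returns `0.0198` (≈ 1/51) — observed
panel-wide carrier frequencies far above such expectations are exactly
what makes prevalence-based gene selection for screening difficult.

The same stages are available as a CLI:

```bash
cilioscreen simulate --seed 3 --n-individuals 120 --out-dir sim
cilioscreen qc --variants sim/variants.tsv --metrics sim/metrics.tsv --out sim/hq.tsv
cilioscreen classify --variants sim/hq.tsv --whitelist sim/whitelist.tsv --out sim/tiered.tsv
cilioscreen prioritize --tiered sim/tiered.tsv --panel sim/panel.tsv --out sim/priority.tsv
cilioscreen report --tiered sim/tiered.tsv --ped sim/cohort.ped --out sim/report.json
```

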