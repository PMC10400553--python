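# Methods

## Problem setting

Expanded carrier screening reports heterozygous variants in recessive
disease genes to healthy individuals. Interpretation in this setting is
unusual: phenotype match, segregation and a second allele in trans are
unavailable as evidence, so classification leans entirely on population
frequency, database assertions and in-silico prediction. The package
models that interpretation pipeline for a 118-gene ciliopathy panel:
call-quality filtering, tier assignment, VUS prioritization, and cohort
and couple statistics.

## Quality control

Two rule cut-offs act per call: alternate-read fraction ≥ 16% and depth
≥ 20×, both inclusive (a call exactly at a cut-off is retained; the
cut-offs are stated as minima). A sample gate excludes whole exomes with
strictly less than 85% of the target covered at ≥ 20×.

Residual artifacts are removed by a linear support vector machine. The
upstream feature list for this classifier is not standardized, so the
model uses the quantities the QC rules themselves name or imply: depth,
alternate-read fraction, strand balance and mean base quality, z-score
standardized. The fit is a libsvm linear-kernel SVC (hinge loss, L2
penalty of strength 1/C, default C = 1), deterministic for a fixed seed
and row order. Decision-boundary ties classify as true calls: at the QC
stage a screening test should favor sensitivity. The fitted model
serializes to JSON (weights, bias, standardization constants) and
reloads with bit-identical decisions.

## Tier assignment

Rules are evaluated in a fixed order; the first match wins, so tiers
partition the post-QC calls. Order: whitelist → database-benign
exclusion → rarity gate (MAF ≤ 0.1%, absent MAF = 0) → LOF with
ClinVar-P/HGMD-DM → non-truncating P∧DM with sufficient evidence → LOF
ClinVar-VUS → novel LOF → LP with limited evidence → HGMD DM/DM? →
in-silico ensemble → excluded.

Numerical choices:

* CADD and M-CAP bounds are inclusive (≥ 20, ≥ 0.025). Both conventions
  (> vs ≥) appear in practice; the inclusive reading is implemented and
  the thresholds are configurable.
* ClinVar CONFLICTING counts as neither pathogenic nor benign: it is
  ignored by the pathogenic rules but leaves a call eligible for the
  VUS rules.
* An HGMD DM label contradicted by a ClinVar benign assertion is
  treated as unreliable and excluded. This `benign_override` is a
  configurable flag; disabling it lets such calls fall through to the
  DM rule (strong VUS).
* "Sufficient supporting information" is operationalized as an explicit
  boolean input column (`clinvar_limited_evidence`); the underlying
  judgement is a curation decision made upstream, not something the
  pipeline can derive.
* Variant keys are parsimony-trimmed `chrom:pos:ref:alt` strings
  (1-based, VCF-compatible), so alternative indel spellings collapse
  before deduplication and whitelist matching.

The whitelist exists because a small number of recurrent founder
alleles are firmly established as pathogenic despite exceeding the 0.1%
rarity cut-off; entries match by (gene, variant key) or HGVS string and
outrank every other rule.

## Prioritization

The per-gene missense score ms = m/M (missense P/LP alleles over all
P/LP alleles) captures whether missense variation is an established
disease mechanism in a gene; it is undefined (and disqualifying) when
the gene has no described P/LP allele. Structural deleteriousness
scores in [0, 1] bucket at strict thresholds: > 0.7 strongly
deleterious, > 0.5 deleterious, otherwise neutral; missing structural
coverage is a distinct unscored category that can never reach first
priority. First priority requires ms > 0.1 and structural score > 0.7,
evaluated on variants deduplicated by key (priority is a property of
the variant, not of the carrier). The spectrum comparison reduces each
gene to two classes (truncating vs missense-like) and reports the
total-variation distance between cohort and patient proportions — a
deliberate simplification chosen because two classes are what the
per-gene knowledge table provides.

## Cohort statistics

* Carrier status ignores zygosity (a homozygote is one carrier) and is
  monotone in the tier set.
* A couple is at risk when both partners carry a qualifying variant in
  the same gene. Two same-gene variants proven cis in one individual
  are one carrier allele and never create risk by themselves; the
  both-partners rule encodes this collapse. Risk is prospective:
  offspring genotypes never remove a couple.
* Phasing: for a parent heterozygous at two same-gene sites with an
  available child genotype, both-or-neither transmitted → cis, exactly
  one → trans, any missing child genotype → uninformative.
* Couple fractions always use the number of couple records present in
  the pedigree input; no denominator is hard-coded.
* Displayed means and percentages round half-up to two decimals; raw
  fractions are always retained in the JSON report.
* Expected carrier frequency under Hardy–Weinberg with full penetrance:
  prevalence K gives allele frequency q = √K and carrier fraction
  2q(1−q). The report includes observed/expected ratios per gene when
  prevalences are supplied. The package deliberately offers no
  residual-risk (post-test probability) calculator: with an unknown
  fraction of VUS being true disease alleles, such a number would be
  misleading.

## Synthetic data

The sampled generator (`generate_cohort`) emulates a parental screening
cohort at clinical-exome scale. Defaults, chosen to mirror that
setting: 395 individuals, 176 couples (21 consanguineous), mean
coverage 287×, per-individual retained-call counts from a negative
binomial (r = 5) truncated to [1, 24] with mean 9.3, 92% of calls rare
(MAF ≤ 0.1%), tier mix 1.3% pathogenic / 1.0% novel LOF / 7.2% strong
VUS / 90.5% benign, and 25% of calls planted as QC artifacts violating
the 16%/20× cut-offs. The negative-binomial choice is a stand-in: only
the mean and range of the per-individual distribution are known.

Predictor calls derive from a latent per-variant deleteriousness
z ~ N(μ_tier, 1): each tool's continuous score is a_t·z plus
independent noise, thresholded to a categorical call (5% missing).
Loadings span 0.8 down to −0.15 (one anti-correlated, FATHMM-style
tool), so pairwise Pearson correlations of the continuous scores fall
in roughly [−0.15, 0.7] — the band observed among real predictor
ensembles. Calls planted as ensemble-route strong VUS have the vote
count enforced, since the rule is a hard conjunction. A configurable
`db_conflict_rate` gives benign-database calls an HGMD DM label,
reproducing the DM-but-benign conflict pattern; such calls are labeled
benign in truth because exclusion is the intended interpretation.

Trio children inherit each parental HOM allele always and each HET
allele with probability ½, independently per parent, so Mendelian
consistency holds by construction. A separate planted-phase generator
places two het variants on known haplotypes of one parent and derives
the child genotype from a randomly transmitted haplotype; informative
children identify the planted phase deterministically.

The deterministic fixture (`generate_reference_cohort`) is hand
constructed, not sampled, so its accounting is exact: 48 pathogenic
calls (26 LOF / 22 missense-like) in 43 carriers, 38 novel-LOF calls in
37 carriers, 265 strong VUS (262 missense-like observations, 239 unique
variants, 23 recurring in exactly two individuals) in 197 carriers each
holding 1–5, 177 couples (21 consanguineous) with exactly 2
consanguineous couples at reportable risk and 7 non-consanguineous
couples sharing VUS in one gene, plus one distractor call per
individual violating a specific rule (common allele, benign assertion,
CADD 19, M-CAP 0.01, 3/7 votes, common LOF, missing scores). The
fixture exercises every rule branch positively and negatively.

What the synthetic data does *not* model: real per-gene allele-frequency
spectra, linkage between sites, sequencing batch effects, population
structure, and genuine database error patterns beyond the single
conflict mode above. Passing tests therefore demonstrate correctness of
the *interpretation logic* under controlled conditions, not calibration
against any real population. The gene panel knowledge table and
whitelist coordinates are likewise synthetic stand-ins (real gene
symbols, generated values).

## Problem sizes

The test suite and the acceptance script run at deliberately modest
scale: the fixture cohort has 746 calls over 395 individuals; the SVM
check trains on 3,000 labeled feature vectors and scores 4,420; the
rule-engine oracle comparison fuzzes 100,000 random calls; property
suites use cohorts of ~500 individuals and 150–200 trios. Everything
completes in well under a minute on one CPU.

## Known limitations

* Real QC training labels do not exist here; the SVM's 4420 → 3702
  partition is emulated on planted-artifact fixtures with controlled
  class separation, not learned from real sequencing artifacts.
* The tier rules implement the operational screening subset of ACMG/AMP
  evidence, not the full 28-criteria framework.
* VCF ingestion assumes annotations arrive as INFO keys (mapped via a
  YAML key map) with Number=A semantics for per-allele fields; it does
  not annotate raw VCFs against live databases and performs no liftover.
* `ms_score` inputs come from a static table; no live database queries.
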