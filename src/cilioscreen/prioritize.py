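"""Prioritization of strong VUS for future functional testing.

Two orthogonal evidence layers rank the variants of uncertain significance
left after tiering:

* a gene-level *missense score* — the fraction of described pathogenic /
  likely-pathogenic disease alleles in the gene that are missense.  In a
  gene whose disease alleles are almost exclusively truncating (score near
  0), a missense VUS in a healthy carrier is unlikely to be a disease
  allele; a high score means missense variation is an established disease
  mechanism in that gene.
* a structure-informed per-variant deleteriousness score (VIPUR-style, in
  [0, 1]): > 0.5 suggests and > 0.7 strongly suggests deleteriousness;
  variants without structural coverage stay unscored.

A VUS is *first priority* when its gene's missense score exceeds
``ms_min`` (default 0.1) and its structural score exceeds
``vipur_strong`` (default 0.7, strict inequalities).

A per-gene spectrum comparison contrasts the variant-type composition
(truncating vs missense-like) of the screened cohort with the published
patient spectrum; large divergence (e.g. patients nearly all truncating,
cohort nearly all missense) marks genes whose cohort VUS are likely benign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    GenePanelEntry,
    LOF_CONSEQUENCES,
    MISSENSE_LIKE_CONSEQUENCES,
    Thresholds,
    Tier,
    TieredVariant,
    ValidationError,
    VipurCategory,
)

#: Flag for genes without any described P/LP allele (missense score undefined).
NO_PLP_DATA = "NO_PLP_DATA"


@dataclass(frozen=True)
class GeneScore:
    """Missense score m/M for one gene; ``score`` is None when M = 0."""

    gene: str
    score: Optional[float]
    flag: Optional[str] = None


def missense_score(entry: GenePanelEntry) -> GeneScore:
    """Ratio of missense P/LP alleles over all P/LP alleles for a gene."""
    if entry.n_missense_plp > entry.n_total_plp:
        raise ValidationError(
            f"{entry.gene}: n_missense_plp {entry.n_missense_plp} exceeds "
            f"n_total_plp {entry.n_total_plp}"
        )
    if entry.n_total_plp == 0:
        return GeneScore(entry.gene, None, flag=NO_PLP_DATA)
    return GeneScore(entry.gene, entry.n_missense_plp / entry.n_total_plp)


def vipur_category(
    score: Optional[float], thr: Thresholds = Thresholds()
) -> VipurCategory:
    """Bucket a structural deleteriousness score (strict thresholds)."""
    if score is None:
        return VipurCategory.UNSCORED
    if not 0.0 <= score <= 1.0:
        raise ValidationError(f"structural score must lie in [0, 1], got {score!r}")
    if score > thr.vipur_strong:
        return VipurCategory.STRONG_DELETERIOUS
    if score > thr.vipur_deleterious:
        return VipurCategory.DELETERIOUS
    return VipurCategory.NEUTRAL


@dataclass(frozen=True)
class PrioritizedVariant:
    variant: TieredVariant
    ms_score: Optional[float]
    vipur_category: VipurCategory
    first_priority: bool

    @property
    def variant_key(self) -> str:
        return self.variant.call.variant_key


def prioritize(
    vus: Sequence[TieredVariant],
    gene_scores: Mapping[str, GeneScore] | Iterable[GeneScore],
    thr: Thresholds = Thresholds(),
) -> list[PrioritizedVariant]:
    """Rank strong VUS; first-priority variants sort to the front.

    Inputs must all carry tier ``STRONG_VUS``.  Observations of the same
    variant in several carriers are deduplicated by variant key before
    ranking (priority is a property of the variant, not the carrier).
    Order: first-priority first, then structural score descending
    (unscored last), ties broken by (gene, variant key).
    """
    if not isinstance(gene_scores, Mapping):
        gene_scores = {g.gene: g for g in gene_scores}
    for tv in vus:
        if tv.tier is not Tier.STRONG_VUS:
            raise ValidationError(
                f"prioritize expects STRONG_VUS inputs, got {tv.tier} "
                f"for {tv.call.variant_key}"
            )

    seen: dict[str, TieredVariant] = {}
    for tv in vus:
        seen.setdefault(tv.call.variant_key, tv)

    out: list[PrioritizedVariant] = []
    for tv in seen.values():
        gs = gene_scores.get(tv.call.gene)
        ms = gs.score if gs is not None else None
        cat = vipur_category(tv.call.vipur, thr)
        first = (
            ms is not None
            and ms > thr.ms_min
            and cat is VipurCategory.STRONG_DELETERIOUS
        )
        out.append(PrioritizedVariant(tv, ms, cat, first))

    def sort_key(pv: PrioritizedVariant):
        vip = pv.variant.call.vipur
        return (
            0 if pv.first_priority else 1,
            -(vip if vip is not None else -math.inf),
            pv.variant.call.gene,
            pv.variant_key,
        )

    return sorted(out, key=sort_key)


@dataclass(frozen=True)
class SpectrumRow:
    """Variant-type composition of one gene: cohort vs patient cohort."""

    gene: str
    n_cohort_variants: int
    cohort_truncating_prop: float
    cohort_missense_prop: float
    patient_truncating_prop: Optional[float]
    patient_missense_prop: Optional[float]
    divergence: Optional[float]


def spectrum_comparison(
    tiered: Sequence[TieredVariant],
    panel: Sequence[GenePanelEntry],
) -> list[SpectrumRow]:
    """Per-gene truncating/missense-like composition vs patient spectrum.

    Uses every non-excluded cohort variant.  Divergence is the total
    variation distance over the two classes, i.e.
    ``|cohort_missense_prop - patient_missense_prop|``; it is None for
    genes lacking a published patient spectrum.  Genes with no cohort
    variants are omitted.
    """
    by_gene: dict[str, list[TieredVariant]] = {}
    for tv in tiered:
        if tv.tier is Tier.EXCLUDED:
            continue
        by_gene.setdefault(tv.call.gene, []).append(tv)

    panel_by_gene = {e.gene: e for e in panel}
    rows: list[SpectrumRow] = []
    for gene in sorted(by_gene):
        items = by_gene[gene]
        n_trunc = sum(1 for tv in items if tv.call.consequence in LOF_CONSEQUENCES)
        n_mis = sum(
            1 for tv in items if tv.call.consequence in MISSENSE_LIKE_CONSEQUENCES
        )
        n = n_trunc + n_mis
        if n == 0:
            continue
        c_trunc, c_mis = n_trunc / n, n_mis / n
        entry = panel_by_gene.get(gene)
        if entry is not None and entry.spectrum_missense is not None:
            p_trunc = entry.spectrum_truncating
            p_mis = entry.spectrum_missense
            div = abs(c_mis - p_mis)
        else:
            p_trunc = p_mis = div = None
        rows.append(
            SpectrumRow(gene, n, c_trunc, c_mis, p_trunc, p_mis, div)
        )
    return rows
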