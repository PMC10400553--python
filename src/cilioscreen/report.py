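"""Cohort- and couple-level statistics for a screened population.

Covers carrier frequencies per tier set, per-individual variant burden,
variant recurrence/deduplication, trio-based cis/trans phase inference,
couples at reproductive risk, and the observed-vs-expected carrier
frequency comparison under Hardy-Weinberg equilibrium.

Phase inference uses offspring genotypes: when a parent carries two
heterozygous variants in one gene, the variants are *cis* if the child
inherited both or neither, *trans* if exactly one.  Two variants proven
cis in one individual represent a single carrier allele, so they never
put a couple at risk by themselves; a couple is at risk when *both*
partners carry a qualifying variant in the same gene.

Under Hardy-Weinberg with full penetrance, a recessive disease of
prevalence K implies allele frequency q = sqrt(K) and carrier fraction
2q(1-q); carrier frequencies observed far above this expectation flag
either underestimated prevalence or non-pathogenic alleles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence

from .model import (
    AnnotatedCall,
    GenePanelEntry,
    MISSENSE_LIKE_CONSEQUENCES,
    PedigreeSet,
    Phase,
    PhaseCall,
    Thresholds,
    Tier,
    TieredVariant,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Named tier sets used for carrier / couple statistics.
TIER_SETS: dict[str, frozenset[Tier]] = {
    "pathogenic": frozenset({Tier.PATHOGENIC}),
    "reportable": frozenset({Tier.PATHOGENIC, Tier.NOVEL_LOF}),
    "strong_vus": frozenset({Tier.STRONG_VUS}),
    "any_retained": frozenset({Tier.PATHOGENIC, Tier.NOVEL_LOF, Tier.STRONG_VUS}),
}


def carrier_frequency(
    tiered: Sequence[TieredVariant],
    individuals: Sequence[str],
    tier_set: Iterable[Tier],
) -> tuple[int, Optional[float]]:
    """Count carriers of >= 1 variant in ``tier_set`` among ``individuals``.

    Returns ``(n_carriers, frequency)``; the frequency is None (reported
    as NA) for an empty cohort.  Homozygous carriers count once; carrier
    status ignores zygosity.
    """
    tier_set = set(tier_set)
    pop = set(individuals)
    carriers = {
        tv.call.sample_id
        for tv in tiered
        if tv.tier in tier_set and tv.call.sample_id in pop
    }
    n = len(pop)
    return len(carriers), (len(carriers) / n if n else None)


def infer_phase(
    parent_id: str,
    gene: str,
    variant_key_a: str,
    variant_key_b: str,
    parent_variant_keys: Iterable[str],
    child_genotypes: Mapping[str, Optional[bool]],
) -> PhaseCall:
    """Infer cis/trans for two same-gene variants of one parent.

    ``child_genotypes`` maps variant key -> whether the child carries the
    allele (None = no genotype at that site).  Child carries both or
    neither -> CIS; exactly one -> TRANS; any missing genotype ->
    UNINFORMATIVE.
    """
    keys = set(parent_variant_keys)
    if variant_key_a not in keys or variant_key_b not in keys:
        raise ValidationError(
            f"parent {parent_id} does not carry both {variant_key_a} and {variant_key_b}"
        )
    has_a = child_genotypes.get(variant_key_a)
    has_b = child_genotypes.get(variant_key_b)
    if has_a is None or has_b is None:
        phase = Phase.UNINFORMATIVE
    elif has_a == has_b:
        phase = Phase.CIS
    else:
        phase = Phase.TRANS
    return PhaseCall(parent_id, gene, variant_key_a, variant_key_b, phase)


def couples_at_risk(
    pedigree: PedigreeSet,
    tiered: Sequence[TieredVariant],
    tier_set: Iterable[Tier],
    phase_calls: Sequence[PhaseCall] = (),
) -> tuple[list[dict], Optional[float]]:
    """Couples where both partners carry a qualifying variant in one gene.

    Returns ``(at_risk, fraction_of_all_couples)``.  Each at-risk record
    lists the shared genes and the couple's consanguinity.  Risk is
    prospective: offspring genotypes never remove a couple.  Two cis
    variants in a single partner are one carrier allele and do not create
    risk without the other partner (``phase_calls`` is accepted for
    audit/report purposes; the both-partners rule already encodes the
    collapse).
    """
    tier_set = set(tier_set)
    genes_by_sample: dict[str, set[str]] = {}
    samples_with_data = {tv.call.sample_id for tv in tiered}
    for tv in tiered:
        if tv.tier in tier_set:
            genes_by_sample.setdefault(tv.call.sample_id, set()).add(tv.call.gene)

    at_risk: list[dict] = []
    for couple in pedigree.couples:
        a, b = couple.members()
        for member in (a, b):
            if member not in samples_with_data:
                logger.warning(
                    "couple member %s has no variant data; counted as non-carrier",
                    member,
                )
        shared = genes_by_sample.get(a, set()) & genes_by_sample.get(b, set())
        if shared:
            at_risk.append(
                {
                    "partner_a": a,
                    "partner_b": b,
                    "consanguineous": couple.consanguineous,
                    "genes": sorted(shared),
                }
            )
    n_couples = len(pedigree.couples)
    return at_risk, (len(at_risk) / n_couples if n_couples else None)


def recurrence_and_unique(
    tiered: Sequence[TieredVariant],
    tier_set: Iterable[Tier],
    consequence_classes: Optional[Iterable] = None,
) -> tuple[int, int, dict[str, int]]:
    """Deduplicate variants of a tier set by variant key.

    Returns ``(n_observations, n_unique, recurrence_table)`` where an
    observation is one distinct carrier of one unique variant and the
    recurrence table lists variants carried by >= 2 distinct individuals.
    ``consequence_classes`` optionally restricts the analysis (e.g. to
    the missense-like classes).
    """
    tier_set = set(tier_set)
    classes = set(consequence_classes) if consequence_classes is not None else None
    carriers: dict[str, set[str]] = {}
    for tv in tiered:
        if tv.tier not in tier_set:
            continue
        if classes is not None and tv.call.consequence not in classes:
            continue
        carriers.setdefault(tv.call.variant_key, set()).add(tv.call.sample_id)
    n_unique = len(carriers)
    n_obs = sum(len(s) for s in carriers.values())
    recurrent = {k: len(s) for k, s in sorted(carriers.items()) if len(s) >= 2}
    return n_obs, n_unique, recurrent


@dataclass(frozen=True)
class BurdenStats:
    mean: float
    mean_display: str  # half-up to 2 decimals, as printed in summaries
    min: int
    max: int


def burden_stats(
    calls: Sequence[AnnotatedCall] | Sequence[TieredVariant],
    individuals: Sequence[str],
) -> BurdenStats:
    """Per-individual call burden over the given cohort (zeros included)."""
    if not individuals:
        raise ValidationError("burden_stats requires a non-empty cohort")
    counts = {sid: 0 for sid in individuals}
    for item in calls:
        call = item.call if isinstance(item, TieredVariant) else item
        if call.sample_id in counts:
            counts[call.sample_id] += 1
    total = sum(counts.values())
    mean = total / len(counts)
    display = str(Decimal(repr(mean)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))
    return BurdenStats(mean, display, min(counts.values()), max(counts.values()))


def expected_carrier_frequency(prevalence: float) -> float:
    """Hardy-Weinberg carrier fraction 2q(1-q) with q = sqrt(prevalence).

    Assumes a fully penetrant single-locus recessive model at equilibrium,
    so disease prevalence K = q^2.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValidationError(f"prevalence must lie in [0, 1], got {prevalence!r}")
    q = math.sqrt(prevalence)
    return 2.0 * q * (1.0 - q)


@dataclass
class CohortReport:
    """Assembled cohort statistics; JSON-serializable and round-trippable."""

    n_individuals: int
    n_failed_samples: int
    tier_counts: dict
    carriers: dict          # tier-set name -> {n_carriers, frequency}
    burden: dict            # {mean, mean_display, min, max}
    recurrence: dict        # tier-set name -> {n_observations, n_unique, recurrent}
    couples: dict           # {total, consanguineous, at_risk: per tier set}
    per_gene: dict          # gene -> counts, frequencies, observed vs expected
    phase_calls: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortReport":
        return cls(**d)

    @classmethod
    def empty(cls) -> "CohortReport":
        return build_report([], [], PedigreeSet([], [], []))


def build_report(
    tiered: Sequence[TieredVariant],
    individuals: Sequence[str],
    pedigree: PedigreeSet,
    panel: Sequence[GenePanelEntry] = (),
    phase_calls: Sequence[PhaseCall] = (),
    n_failed_samples: int = 0,
    thr: Thresholds = Thresholds(),
) -> CohortReport:
    """Assemble every cohort statistic into one report.

    ``individuals`` is the post-gate cohort; every tiered call should come
    from it (calls from unknown samples raise a consistency error).  Tier
    counts cross-check against the number of input calls.
    """
    pop = set(individuals)
    stray = {tv.call.sample_id for tv in tiered} - pop
    if stray:
        raise ValidationError(
            f"tiered calls reference samples outside the cohort: {sorted(stray)[:5]}"
        )

    from .classify import TierCounts

    counts = TierCounts()
    for tv in tiered:
        counts.add(tv)
    tier_counts = counts.as_dict()
    assert sum(v["total"] for v in tier_counts.values()) == len(tiered)

    carriers = {}
    for name, tset in TIER_SETS.items():
        n_c, freq = carrier_frequency(tiered, individuals, tset)
        carriers[name] = {"n_carriers": n_c, "frequency": freq}

    burden = (
        asdict(burden_stats(tiered, individuals))
        if individuals
        else {"mean": None, "mean_display": None, "min": None, "max": None}
    )

    recurrence = {}
    for name, tset in TIER_SETS.items():
        n_obs, n_uniq, rec = recurrence_and_unique(tiered, tset)
        recurrence[name] = {
            "n_observations": n_obs,
            "n_unique": n_uniq,
            "recurrent": rec,
        }
    n_obs, n_uniq, rec = recurrence_and_unique(
        tiered, {Tier.STRONG_VUS}, MISSENSE_LIKE_CONSEQUENCES
    )
    recurrence["strong_vus_missense_like"] = {
        "n_observations": n_obs,
        "n_unique": n_uniq,
        "recurrent": rec,
    }

    couples: dict = {
        "total": len(pedigree.couples),
        "consanguineous": pedigree.n_consanguineous,
        "at_risk": {},
    }
    for name, tset in TIER_SETS.items():
        risk, frac = couples_at_risk(pedigree, tiered, tset, phase_calls)
        n_consang = sum(1 for r in risk if r["consanguineous"])
        couples["at_risk"][name] = {
            "n": len(risk),
            "fraction": frac,
            "n_consanguineous": n_consang,
            "couples": risk,
        }

    prevalence = {e.gene: e.disease_prevalence for e in panel}
    per_gene: dict = {}
    genes = sorted({tv.call.gene for tv in tiered if tv.tier is not Tier.EXCLUDED})
    n_pop = len(pop)
    for gene in genes:
        gene_tiered = [tv for tv in tiered if tv.call.gene == gene]
        entry: dict = {}
        for name, tset in TIER_SETS.items():
            n_c, freq = carrier_frequency(gene_tiered, individuals, tset)
            entry[name] = {"n_carriers": n_c, "frequency": freq}
        k = prevalence.get(gene)
        if k is not None and n_pop:
            expected = expected_carrier_frequency(k)
            observed = entry["reportable"]["frequency"]
            entry["expected_carrier_frequency"] = expected
            entry["observed_over_expected"] = (
                observed / expected if expected > 0 else None
            )
        per_gene[gene] = entry

    return CohortReport(
        n_individuals=len(pop),
        n_failed_samples=n_failed_samples,
        tier_counts=tier_counts,
        carriers=carriers,
        burden=burden,
        recurrence=recurrence,
        couples=couples,
        per_gene=per_gene,
        phase_calls=[asdict(pc) for pc in phase_calls],
    )
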