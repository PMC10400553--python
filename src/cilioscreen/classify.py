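"""Tier assignment for high-confidence calls.

Each post-QC call receives exactly one tier with an audit trail of the
criteria that fired:

``PATHOGENIC``
    ACMG/AMP-style pathogenic: a whitelisted recurrent disease allele at
    any frequency; or a very rare (MAF <= 0.1%) loss-of-function allele
    (PVS1 + PM2) already pathogenic in ClinVar and/or disease-causing
    (DM) in HGMD; or a rare non-truncating allele pathogenic in ClinVar
    AND DM in HGMD with sufficient supporting information.
``NOVEL_LOF``
    A very rare predicted loss-of-function allele absent from both
    databases — formally likely pathogenic under PVS1 + PM2.
``STRONG_VUS``
    A very rare allele that is not reportable but predicted deleterious:
    a LOF allele ClinVar calls VUS; ClinVar LP with only limited
    supporting information; HGMD DM or DM?; or the in-silico ensemble
    (CADD >= 20, M-CAP >= 0.025, >= 4 of 7 categorical predictors
    deleterious).
``EXCLUDED``
    Everything else, including alleles a database calls (likely) benign
    — a DM label contradicted by a ClinVar benign assertion is treated
    as unreliable and excluded (configurable via
    ``Thresholds.benign_override``).

Rules are evaluated in a fixed order and the first match wins, so the
tiers partition the input.  ClinVar ``CONFLICTING`` never counts as P or
benign; it behaves as absent for the pathogenic rules while remaining
eligible for the VUS rules.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence
import logging

from .model import (
    AnnotatedCall,
    ClinVar,
    Hgmd,
    MISSENSE_LIKE_CONSEQUENCES,
    Thresholds,
    Tier,
    TieredVariant,
    ToolPrediction,
    WhitelistEntry,
)

logger = logging.getLogger(__name__)

# Criterion identifiers recorded in the audit trail.
WHITELIST = "WHITELIST"
PVS1 = "PVS1"
PM2 = "PM2"
CLINVAR_P = "CLINVAR_P"
HGMD_DM = "HGMD_DM"
CLINVAR_VUS_LOF = "CLINVAR_VUS_LOF"
NOVEL_LOF_RULE = "NOVEL_LOF"
CLINVAR_LP_LIMITED = "CLINVAR_LP_LIMITED"
HGMD_DM_ONLY = "HGMD_DM_ONLY"
ENSEMBLE = "ENSEMBLE"

# Exclusion reasons.
EXCL_BENIGN_DB = "BENIGN_DB"
EXCL_COMMON_AF = "COMMON_AF"
EXCL_NO_CRITERIA = "NO_CRITERIA"


def ensemble_vote(call: AnnotatedCall, thr: Thresholds = Thresholds()) -> tuple[int, bool]:
    """Count deleterious predictor votes and test the ensemble rule.

    Returns ``(vote_count, passes)`` where ``vote_count`` is the number of
    the seven categorical tools predicting deleterious, and ``passes``
    requires CADD >= ``cadd_min``, M-CAP >= ``mcap_min`` and at least
    ``votes_min`` votes.  A missing CADD or M-CAP score fails the rule
    (deleteriousness cannot be asserted from absent evidence).
    """
    votes = sum(
        1 for pred in call.tool_calls.values() if pred is ToolPrediction.DELETERIOUS
    )
    passes = (
        call.cadd is not None
        and call.mcap is not None
        and call.cadd >= thr.cadd_min
        and call.mcap >= thr.mcap_min
        and votes >= thr.votes_min
    )
    return votes, passes


def _whitelist_index(whitelist: Iterable[WhitelistEntry]) -> dict[tuple[str, str], WhitelistEntry]:
    return {(e.gene, e.variant_key): e for e in whitelist}


def classify_variant(
    call: AnnotatedCall,
    whitelist: Iterable[WhitelistEntry] = (),
    thr: Thresholds = Thresholds(),
) -> TieredVariant:
    """Assign one tier to one high-confidence call (first matching rule wins)."""
    wl = whitelist if isinstance(whitelist, dict) else _whitelist_index(whitelist)

    # 1. Whitelisted recurrent disease allele — pathogenic at any frequency.
    entry = wl.get((call.gene, call.variant_key))
    if entry is None and call.hgvs is not None:
        entry = next(
            (e for e in wl.values() if e.gene == call.gene and e.hgvs == call.hgvs),
            None,
        )
    if entry is not None:
        return TieredVariant(call, Tier.PATHOGENIC, (WHITELIST,))

    # 2. Database-benign override.
    if thr.benign_override and call.clinvar in (ClinVar.B, ClinVar.LB):
        return TieredVariant(call, Tier.EXCLUDED, (), exclusion_reason=EXCL_BENIGN_DB)

    # 3. Rarity gate (absent MAF counts as 0).
    if call.maf_or_zero > thr.maf_max:
        return TieredVariant(call, Tier.EXCLUDED, (), exclusion_reason=EXCL_COMMON_AF)

    clinvar_p = call.clinvar is ClinVar.P
    hgmd_dm = call.hgmd is Hgmd.DM

    # 4. Rare LOF already pathogenic / disease-causing in a database.
    if call.is_lof and (clinvar_p or hgmd_dm):
        fired = [PVS1, PM2]
        if clinvar_p:
            fired.append(CLINVAR_P)
        if hgmd_dm:
            fired.append(HGMD_DM)
        return TieredVariant(call, Tier.PATHOGENIC, tuple(fired))

    # 5. Rare non-truncating allele P in ClinVar AND DM in HGMD with
    #    sufficient supporting information.
    if (
        not call.is_lof
        and clinvar_p
        and hgmd_dm
        and not call.clinvar_limited_evidence
    ):
        return TieredVariant(call, Tier.PATHOGENIC, (PM2, CLINVAR_P, HGMD_DM))

    # 6. LOF that ClinVar itself calls uncertain.
    if call.is_lof and call.clinvar is ClinVar.VUS:
        return TieredVariant(call, Tier.STRONG_VUS, (CLINVAR_VUS_LOF,))

    # 7. Novel LOF: absent from both databases.
    if call.is_lof and call.clinvar is ClinVar.ABSENT and call.hgmd is Hgmd.ABSENT:
        return TieredVariant(call, Tier.NOVEL_LOF, (NOVEL_LOF_RULE, PVS1, PM2))

    # 8. ClinVar LP with limited supporting information.
    if call.clinvar is ClinVar.LP and call.clinvar_limited_evidence:
        return TieredVariant(call, Tier.STRONG_VUS, (CLINVAR_LP_LIMITED,))

    # 9. HGMD DM / DM? without the stronger evidence above.
    if call.hgmd in (Hgmd.DM, Hgmd.DM_QUERY):
        return TieredVariant(call, Tier.STRONG_VUS, (HGMD_DM_ONLY,))

    # 10. In-silico ensemble.
    votes, passes = ensemble_vote(call, thr)
    if passes:
        return TieredVariant(call, Tier.STRONG_VUS, (ENSEMBLE,))

    # 11. Nothing retained it.
    return TieredVariant(call, Tier.EXCLUDED, (), exclusion_reason=EXCL_NO_CRITERIA)


@dataclass
class TierCounts:
    """Per-tier call totals with the LOF vs missense-like breakdown."""

    total: Counter = field(default_factory=Counter)
    lof: Counter = field(default_factory=Counter)
    missense_like: Counter = field(default_factory=Counter)

    def add(self, tv: TieredVariant) -> None:
        self.total[tv.tier.value] += 1
        if tv.call.is_lof:
            self.lof[tv.tier.value] += 1
        elif tv.call.consequence in MISSENSE_LIKE_CONSEQUENCES:
            self.missense_like[tv.tier.value] += 1

    def as_dict(self) -> dict:
        return {
            tier.value: {
                "total": self.total.get(tier.value, 0),
                "lof": self.lof.get(tier.value, 0),
                "missense_like": self.missense_like.get(tier.value, 0),
            }
            for tier in Tier
        }


def classify_cohort(
    calls: Sequence[AnnotatedCall],
    whitelist: Iterable[WhitelistEntry] = (),
    thr: Thresholds = Thresholds(),
    panel_genes: Optional[set[str]] = None,
) -> tuple[list[TieredVariant], TierCounts]:
    """Classify every call; every input appears exactly once in the output.

    ``panel_genes`` (optional) triggers a configuration warning for
    whitelist entries naming genes outside the panel; the entries are
    still honored.
    """
    wl = _whitelist_index(whitelist)
    if panel_genes is not None:
        for gene, _ in wl:
            if gene not in panel_genes:
                logger.warning("whitelist entry for gene %s not in panel", gene)
    tiered = [classify_variant(c, wl, thr) for c in calls]
    counts = TierCounts()
    for tv in tiered:
        counts.add(tv)
    return tiered, counts
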