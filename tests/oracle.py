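"""Independent brute-force re-implementations used as test oracles.

Kept deliberately separate from the package: the tier oracle evaluates
every retention rule as an unordered predicate table and resolves them by
an explicit precedence list, instead of the package's sequential
first-match control flow.
"""

from __future__ import annotations

import numpy as np

from cilioscreen.model import (
    AnnotatedCall,
    ClinVar,
    Consequence,
    Hgmd,
    PREDICTOR_TOOLS,
    Thresholds,
    Tier,
    ToolPrediction,
)


def oracle_tier(call: AnnotatedCall, whitelist_keys: set, thr: Thresholds) -> Tier:
    """Declarative tier assignment: all predicates, then precedence."""
    lof = call.consequence in (
        Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.CANONICAL_SPLICE
    )
    maf = 0.0 if call.maf is None else call.maf
    votes = sum(1 for v in call.tool_calls.values() if v == ToolPrediction.DELETERIOUS)
    ensemble = (
        call.cadd is not None and call.mcap is not None
        and call.cadd >= thr.cadd_min and call.mcap >= thr.mcap_min
        and votes >= thr.votes_min
    )
    predicates = {
        "whitelist": (call.gene, call.variant_key) in whitelist_keys,
        "benign": thr.benign_override and call.clinvar in (ClinVar.B, ClinVar.LB),
        "common": maf > thr.maf_max,
        "lof_db_pathogenic": lof and (call.clinvar == ClinVar.P or call.hgmd == Hgmd.DM),
        "nonlof_p_and_dm": (
            not lof and call.clinvar == ClinVar.P and call.hgmd == Hgmd.DM
            and not call.clinvar_limited_evidence
        ),
        "lof_clinvar_vus": lof and call.clinvar == ClinVar.VUS,
        "novel_lof": lof and call.clinvar == ClinVar.ABSENT and call.hgmd == Hgmd.ABSENT,
        "lp_limited": call.clinvar == ClinVar.LP and call.clinvar_limited_evidence,
        "dm_any": call.hgmd in (Hgmd.DM, Hgmd.DM_QUERY),
        "ensemble": ensemble,
    }
    precedence = [
        ("whitelist", Tier.PATHOGENIC),
        ("benign", Tier.EXCLUDED),
        ("common", Tier.EXCLUDED),
        ("lof_db_pathogenic", Tier.PATHOGENIC),
        ("nonlof_p_and_dm", Tier.PATHOGENIC),
        ("lof_clinvar_vus", Tier.STRONG_VUS),
        ("novel_lof", Tier.NOVEL_LOF),
        ("lp_limited", Tier.STRONG_VUS),
        ("dm_any", Tier.STRONG_VUS),
        ("ensemble", Tier.STRONG_VUS),
    ]
    for name, tier in precedence:
        if predicates[name]:
            return tier
    return Tier.EXCLUDED


def random_calls(n: int, seed: int) -> list[AnnotatedCall]:
    """Annotation-space fuzzer covering every rule branch."""
    rng = np.random.default_rng(seed)
    consequences = list(Consequence)
    clinvars = list(ClinVar)
    hgmds = list(Hgmd)
    preds = [ToolPrediction.DELETERIOUS, ToolPrediction.TOLERATED, ToolPrediction.MISSING]
    calls = []
    for i in range(n):
        maf_kind = rng.integers(3)
        maf = (None, float(10 ** rng.uniform(-6, -3.1)),
               float(10 ** rng.uniform(-3, -0.5)))[maf_kind]
        calls.append(AnnotatedCall(
            sample_id=f"R{i}",
            gene="BBS1" if rng.random() < 0.02 else f"G{rng.integers(30)}",
            chrom="1", pos=int(1 + rng.integers(10_000_000)),
            ref="A", alt="T",
            consequence=consequences[rng.integers(len(consequences))],
            maf=maf,
            cadd=None if rng.random() < 0.15 else float(rng.uniform(0, 50)),
            mcap=None if rng.random() < 0.15 else float(rng.uniform(0, 1)),
            tool_calls={t: preds[rng.integers(3)] for t in PREDICTOR_TOOLS},
            clinvar=clinvars[rng.integers(len(clinvars))],
            clinvar_limited_evidence=bool(rng.random() < 0.3),
            hgmd=hgmds[rng.integers(len(hgmds))],
            depth=int(rng.integers(0, 400)),
            alt_fraction=float(rng.uniform(0, 1)),
        ))
    return calls
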