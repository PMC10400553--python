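import pytest
from hypothesis import given, settings, strategies as st

from cilioscreen.classify import classify_cohort, classify_variant, ensemble_vote
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
from cilioscreen.simulate import default_whitelist, BBS1_M309R

from oracle import oracle_tier, random_calls

D, T, M = ToolPrediction.DELETERIOUS, ToolPrediction.TOLERATED, ToolPrediction.MISSING


def call(**kw):
    base = dict(sample_id="s", gene="CEP290", chrom="12", pos=1000, ref="A",
                alt="G", consequence=Consequence.MISSENSE, depth=100,
                alt_fraction=0.5)
    base.update(kw)
    return AnnotatedCall(**base)


def tools(n_del, n_missing=0):
    out = {}
    for i, t in enumerate(PREDICTOR_TOOLS):
        out[t] = D if i < n_del else (M if i >= 7 - n_missing else T)
    return out


@pytest.mark.parametrize(
    "kw, expected",
    [
        (dict(cadd=25.0, mcap=0.03, tool_calls=tools(4)), (4, True)),
        (dict(cadd=19.9, mcap=0.9, tool_calls=tools(7)), (7, False)),   # CADD < 20
        (dict(cadd=30.0, mcap=0.5, tool_calls=tools(3)), (3, False)),   # < 4 votes
        (dict(cadd=20.0, mcap=0.025, tool_calls=tools(4)), (4, True)),  # inclusive bounds
        (dict(cadd=None, mcap=0.5, tool_calls=tools(7)), (7, False)),   # missing CADD
    ],
)
def test_ensemble_vote(kw, expected):
    assert ensemble_vote(call(**kw)) == expected


@pytest.mark.parametrize(
    "kw, tier",
    [
        # whitelisted recurrent allele wins despite MAF > 0.1%
        (dict(gene="BBS1", chrom=BBS1_M309R["chrom"], pos=BBS1_M309R["pos"],
              ref="T", alt="G", maf=0.002), Tier.PATHOGENIC),
        # novel LOF: rare frameshift absent from both databases
        (dict(consequence=Consequence.FRAMESHIFT, maf=0.0005, ref="A",
              alt="AT"), Tier.NOVEL_LOF),
        # ClinVar LP with limited evidence stays a VUS
        (dict(maf=0.0005, clinvar=ClinVar.LP, clinvar_limited_evidence=True),
         Tier.STRONG_VUS),
        # common synonymous allele is out
        (dict(consequence=Consequence.SYNONYMOUS, maf=0.05), Tier.EXCLUDED),
        # HGMD DM contradicted by ClinVar benign: excluded
        (dict(maf=0.0005, hgmd=Hgmd.DM, clinvar=ClinVar.B), Tier.EXCLUDED),
        # rare LOF with ClinVar P
        (dict(consequence=Consequence.NONSENSE, maf=0.0002, clinvar=ClinVar.P),
         Tier.PATHOGENIC),
        # rare missense P + DM with sufficient evidence
        (dict(maf=0.0005, clinvar=ClinVar.P, hgmd=Hgmd.DM), Tier.PATHOGENIC),
        # LOF that ClinVar calls uncertain
        (dict(consequence=Consequence.CANONICAL_SPLICE, maf=0.0002,
              clinvar=ClinVar.VUS), Tier.STRONG_VUS),
        # HGMD DM? alone
        (dict(maf=0.0005, hgmd=Hgmd.DM_QUERY), Tier.STRONG_VUS),
    ],
)
def test_classify_variant_rules(kw, tier):
    tv = classify_variant(call(**kw), default_whitelist())
    assert tv.tier is tier
    assert tv.reportable == (tier in (Tier.PATHOGENIC, Tier.NOVEL_LOF))
    if tier is not Tier.EXCLUDED:
        assert tv.fired_criteria


def test_benign_override_is_configurable():
    c = call(maf=0.0005, hgmd=Hgmd.DM, clinvar=ClinVar.B)
    assert classify_variant(c).tier is Tier.EXCLUDED
    keep = Thresholds(benign_override=False)
    assert classify_variant(c, thr=keep).tier is Tier.STRONG_VUS


def test_clinvar_conflicting_not_pathogenic_but_vus_eligible():
    lof = call(consequence=Consequence.NONSENSE, maf=0.0002,
               clinvar=ClinVar.CONFLICTING)
    assert classify_variant(lof).tier is Tier.EXCLUDED  # not P, not absent
    ens = call(maf=0.0002, clinvar=ClinVar.CONFLICTING, cadd=30.0, mcap=0.5,
               tool_calls=tools(5))
    assert classify_variant(ens).tier is Tier.STRONG_VUS


def test_whitelist_pathogenic_at_any_maf():
    for maf in (None, 0.0001, 0.002, 0.3):
        c = call(gene="BBS1", chrom=BBS1_M309R["chrom"], pos=BBS1_M309R["pos"],
                 ref="T", alt="G", maf=maf, clinvar=ClinVar.LB)
        # whitelist outranks even a benign assertion by rule order
        assert classify_variant(c, default_whitelist()).tier is Tier.PATHOGENIC


def test_oracle_equivalence_small():
    wl = default_whitelist()
    wl_keys = {(e.gene, e.variant_key) for e in wl}
    thr = Thresholds()
    for c in random_calls(5000, seed=11):
        assert classify_variant(c, wl, thr).tier is oracle_tier(c, wl_keys, thr)


def test_partition_over_cohort(refcohort, refcohort_classified):
    tiered, counts = refcohort_classified
    assert len(tiered) == len(refcohort.calls)
    assert sum(counts.total.values()) == len(refcohort.calls)
    for tv in tiered:
        assert tv.tier in Tier


_TIER_RANK = {Tier.EXCLUDED: 0, Tier.STRONG_VUS: 1, Tier.NOVEL_LOF: 2,
              Tier.PATHOGENIC: 2}

_FUZZ = random_calls(2000, seed=23)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(idx=st.integers(0, 1999), factor=st.floats(0.0, 1.0))
def test_lowering_maf_never_demotes(idx, factor):
    c = _FUZZ[idx]
    before = classify_variant(c).tier
    rarer = c.with_(maf=None if c.maf is None else c.maf * factor)
    after = classify_variant(rarer).tier
    assert _TIER_RANK[after] >= _TIER_RANK[before]


@settings(max_examples=200, deadline=None, derandomize=True)
@given(idx=st.integers(0, 1999))
def test_adding_deleterious_vote_never_excludes_a_vus(idx):
    c = _FUZZ[idx]
    if classify_variant(c).tier is not Tier.STRONG_VUS:
        return
    boosted = dict(c.tool_calls)
    for t in PREDICTOR_TOOLS:
        if boosted[t] is not D:
            boosted[t] = D
            break
    after = classify_variant(c.with_(tool_calls=boosted)).tier
    assert after is not Tier.EXCLUDED


def test_classify_cohort_empty():
    tiered, counts = classify_cohort([])
    assert tiered == [] and sum(counts.total.values()) == 0
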