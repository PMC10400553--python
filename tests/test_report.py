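import math

import pytest

from cilioscreen.model import (
    AnnotatedCall,
    Consequence,
    Couple,
    PedigreeSet,
    Phase,
    Tier,
    TieredVariant,
    ValidationError,
)
from cilioscreen.report import (
    build_report,
    burden_stats,
    carrier_frequency,
    couples_at_risk,
    expected_carrier_frequency,
    infer_phase,
    recurrence_and_unique,
)
from cilioscreen.simulate import default_gene_panel, generate_phased_trios


def _tv(sample, gene, tier, pos=1000, consequence=Consequence.MISSENSE):
    call = AnnotatedCall(sample_id=sample, gene=gene, chrom="1", pos=pos,
                         ref="A", alt="G", consequence=consequence,
                         depth=100, alt_fraction=0.5)
    return TieredVariant(call, tier, ("X",) if tier is not Tier.EXCLUDED else ())


def test_carrier_frequency_basics():
    tiered = [_tv("a", "G1", Tier.PATHOGENIC), _tv("a", "G2", Tier.PATHOGENIC, pos=2000),
              _tv("b", "G1", Tier.STRONG_VUS)]
    n, cf = carrier_frequency(tiered, ["a", "b", "c", "d"], {Tier.PATHOGENIC})
    assert (n, cf) == (1, 0.25)
    n, cf = carrier_frequency(tiered, [], {Tier.PATHOGENIC})
    assert (n, cf) == (0, None)
    n, cf = carrier_frequency(tiered, ["c", "d"], {Tier.PATHOGENIC})
    assert (n, cf) == (0, 0.0)


@pytest.mark.parametrize(
    "child, expected",
    [
        ({"k1": True, "k2": True}, Phase.CIS),
        ({"k1": False, "k2": False}, Phase.CIS),
        ({"k1": True, "k2": False}, Phase.TRANS),
        ({"k1": True, "k2": None}, Phase.UNINFORMATIVE),
    ],
)
def test_infer_phase(child, expected):
    pc = infer_phase("p", "G1", "k1", "k2", {"k1", "k2"}, child)
    assert pc.phase is expected


def test_infer_phase_requires_both_variants_in_parent():
    with pytest.raises(ValidationError):
        infer_phase("p", "G1", "k1", "k2", {"k1"}, {"k1": True, "k2": True})


def test_phasing_recovers_planted_configuration():
    """On informative simulated trios the planted phase is always recovered."""
    for trio in generate_phased_trios(200, seed=5):
        pc = infer_phase(trio.parent_id, trio.gene, trio.variant_key_a,
                         trio.variant_key_b, trio.parent_variant_keys,
                         trio.child_genotypes)
        assert pc.phase.value == trio.true_phase
    # missing child genotypes are uninformative, never a wrong phase
    for trio in generate_phased_trios(100, seed=6, missing_fraction=1.0):
        pc = infer_phase(trio.parent_id, trio.gene, trio.variant_key_a,
                         trio.variant_key_b, trio.parent_variant_keys,
                         trio.child_genotypes)
        assert pc.phase is Phase.UNINFORMATIVE


def _pedigree():
    inds = ["a", "b", "c", "d", "e", "f"]
    couples = [Couple("a", "b", consanguineous=True), Couple("c", "d"),
               Couple("e", "f")]
    return PedigreeSet(inds, couples, [])


def test_couples_at_risk_same_gene_rule():
    ped = _pedigree()
    tiered = [
        _tv("a", "DYNC2H1", Tier.PATHOGENIC),
        _tv("b", "DYNC2H1", Tier.PATHOGENIC, pos=2000),
        _tv("c", "CEP290", Tier.PATHOGENIC),
        _tv("d", "BBS1", Tier.PATHOGENIC),      # different gene: no risk
    ]
    risk, frac = couples_at_risk(ped, tiered, {Tier.PATHOGENIC})
    assert len(risk) == 1 and risk[0]["genes"] == ["DYNC2H1"]
    assert frac == pytest.approx(1 / 3)
    assert risk[0]["consanguineous"] is True


def test_couples_at_risk_invariant_under_partner_order():
    tiered = [_tv("a", "G1", Tier.NOVEL_LOF), _tv("b", "G1", Tier.NOVEL_LOF, pos=2000)]
    ped1 = PedigreeSet(["a", "b"], [Couple("a", "b")], [])
    ped2 = PedigreeSet(["a", "b"], [Couple("b", "a")], [])
    r1, f1 = couples_at_risk(ped1, tiered, {Tier.NOVEL_LOF})
    r2, f2 = couples_at_risk(ped2, tiered, {Tier.NOVEL_LOF})
    assert len(r1) == len(r2) == 1 and f1 == f2


def test_recurrence_and_unique():
    tiered = (
        [_tv(f"s{i}", "G1", Tier.STRONG_VUS, pos=100 + i) for i in range(10)]
        + [_tv("x", "G1", Tier.STRONG_VUS, pos=500),
           _tv("y", "G1", Tier.STRONG_VUS, pos=500),
           _tv("z", "G1", Tier.STRONG_VUS, pos=500)]
    )
    n_obs, n_unique, rec = recurrence_and_unique(tiered, {Tier.STRONG_VUS})
    assert (n_obs, n_unique) == (13, 11)
    assert rec == {"1:500:A:G": 3}
    # all singletons
    n_obs, n_unique, rec = recurrence_and_unique(tiered[:10], {Tier.STRONG_VUS})
    assert (n_obs, n_unique, rec) == (10, 10, {})


def test_burden_stats_rounding():
    calls = [_tv(f"s{i % 4}", "G1", Tier.STRONG_VUS, pos=100 + i).call
             for i in range(10)]
    b = burden_stats(calls, [f"s{i}" for i in range(4)])
    assert b.mean_display == "2.50" and (b.min, b.max) == (2, 3)
    every3 = [_tv(f"s{i}", "G1", Tier.STRONG_VUS, pos=200 + 10 * i + j).call
              for i in range(5) for j in range(3)]
    b = burden_stats(every3, [f"s{i}" for i in range(5)])
    assert (b.mean_display, b.min, b.max) == ("3.00", 3, 3)


def test_expected_carrier_frequency_closed_form():
    assert expected_carrier_frequency(0.0) == 0.0
    assert expected_carrier_frequency(1e-4) == pytest.approx(0.0198, abs=1e-12)
    # prevalence 1e-5 -> carrier fraction ~1/159
    assert expected_carrier_frequency(1e-5) == pytest.approx(0.006305, abs=5e-7)
    with pytest.raises(ValidationError):
        expected_carrier_frequency(1.5)


def test_expected_carrier_frequency_vs_enumeration_and_monotone():
    """Exhaustive diploid genotype enumeration agrees to 1e-9; monotone in K."""
    prev = -1.0
    for k in [0.0, 1e-8, 1e-6, 1e-5, 1e-4, 1e-3, 0.01, 0.1, 0.25]:
        q = math.sqrt(k)
        alleles = [(q, True), (1 - q, False)]
        enumerated = sum(
            pa * pb
            for pa, a in alleles
            for pb, b in alleles
            if a != b  # exactly one disease allele = carrier
        )
        closed = expected_carrier_frequency(k)
        assert abs(closed - enumerated) <= 1e-9
        assert closed >= prev
        prev = closed


def test_build_report_cross_checks(refcohort, refcohort_classified):
    tiered, _ = refcohort_classified
    rep = build_report(tiered, refcohort.individuals, refcohort.pedigree)
    # tier totals sum to the call count
    assert sum(v["total"] for v in rep.tier_counts.values()) == len(refcohort.calls)
    # carrier frequency monotone in tier set
    cf = {k: v["frequency"] for k, v in rep.carriers.items()}
    assert cf["pathogenic"] <= cf["reportable"] <= cf["any_retained"]
    # independent brute-force recount of pathogenic carriers
    brute = len({tv.call.sample_id for tv in tiered if tv.tier is Tier.PATHOGENIC})
    assert rep.carriers["pathogenic"]["n_carriers"] == brute


def test_build_report_rejects_stray_samples(refcohort, refcohort_classified):
    tiered, _ = refcohort_classified
    with pytest.raises(ValidationError):
        build_report(tiered, refcohort.individuals[:10], refcohort.pedigree)


def test_per_gene_observed_vs_expected(refcohort, refcohort_classified):
    tiered, _ = refcohort_classified
    rep = build_report(tiered, refcohort.individuals, refcohort.pedigree,
                       panel=default_gene_panel())
    gene = rep.per_gene["CEP290"]
    assert gene["expected_carrier_frequency"] > 0
    assert gene["observed_over_expected"] == pytest.approx(
        gene["reportable"]["frequency"] / gene["expected_carrier_frequency"]
    )
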