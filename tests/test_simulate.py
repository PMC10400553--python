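import numpy as np
import pytest

from cilioscreen import io as csio
from cilioscreen.classify import classify_cohort, classify_variant
from cilioscreen.model import (
    PREDICTOR_TOOLS,
    Thresholds,
    Tier,
    ValidationError,
    Zygosity,
)
from cilioscreen.qc import preprocess_filter
from cilioscreen.simulate import (
    CohortSimParams,
    PANEL_GENES,
    default_gene_panel,
    default_whitelist,
    generate_cohort,
    generate_qc_training_set,
    generate_reference_cohort,
)


@pytest.fixture(scope="module")
def small_cohort():
    params = CohortSimParams(n_individuals=500, n_couples=240, n_trios=20, seed=7)
    return params, generate_cohort(params)


def test_same_seed_is_byte_identical(tmp_path, small_cohort):
    params, cohort = small_cohort
    again = generate_cohort(params)
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    csio.write_variant_table(cohort.calls, p1)
    csio.write_variant_table(again.calls, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert cohort.truth.equals(again.truth)


def test_zero_artifact_rate_passes_preprocessing_entirely():
    params = CohortSimParams(n_individuals=60, n_couples=25, n_trios=0,
                             artifact_rate=0.0, seed=1)
    cohort = generate_cohort(params)
    retained, excluded = preprocess_filter(cohort.calls)
    assert excluded == [] and len(retained) == len(cohort.calls)


def test_artifacts_violate_qc_cutoffs(small_cohort):
    _, cohort = small_cohort
    flagged = dict(zip(zip(cohort.truth.sample_id, cohort.truth.variant_key),
                       cohort.truth.is_artifact))
    thr = Thresholds()
    for call in cohort.calls:
        label = flagged.get((call.sample_id, call.variant_key))
        if label is None:  # trio child copies carry no truth row
            continue
        violates = call.alt_fraction < thr.alt_fraction_min or call.depth < thr.depth_min
        assert violates == label


def test_predictor_correlations_in_expected_range(small_cohort):
    """Pairwise Pearson correlations of the latent-model continuous scores
    stay inside [-0.2, 0.8] (the observed tool-correlation band, with
    sampling slack)."""
    _, cohort = small_cohort
    cols = [f"score_{t}" for t in PREDICTOR_TOOLS]
    corr = cohort.truth[cols].corr().to_numpy()
    off_diag = corr[~np.eye(len(cols), dtype=bool)]
    assert off_diag.min() >= -0.2 and off_diag.max() <= 0.8
    # the range is actually spanned: some near-independent, some strongly coupled
    assert off_diag.min() < 0.0 < 0.5 < off_diag.max()


def test_tier_mix_converges(small_cohort):
    params, cohort = small_cohort
    props = cohort.truth.truth_tier.value_counts(normalize=True)
    n = len(cohort.truth)
    for name, target in zip(("PATHOGENIC", "NOVEL_LOF", "STRONG_VUS", "BENIGN"),
                            params.tier_mix):
        se = np.sqrt(target * (1 - target) / n)
        assert abs(props.get(name, 0.0) - target) <= 4 * se + 1e-9


def test_calls_per_individual_within_expected_range(small_cohort):
    _, cohort = small_cohort
    counts = cohort.truth.groupby("sample_id").size()
    assert counts.min() >= 1 and counts.max() <= 24
    assert 7.0 <= counts.mean() <= 12.0


def test_children_obey_mendelian_transmission(small_cohort):
    _, cohort = small_cohort
    parent_keys = {
        sid: {c.variant_key for c in cohort.calls if c.sample_id == sid}
        for sid in cohort.individuals
    }
    for trio in cohort.pedigree.trios:
        child_calls = [c for c in cohort.calls if c.sample_id == trio.child_id]
        for call in child_calls:
            assert (call.variant_key in parent_keys[trio.father_id]
                    or call.variant_key in parent_keys[trio.mother_id])
    # homozygous parental alleles are always transmitted
    hom = {(c.sample_id, c.variant_key) for c in cohort.calls
           if c.zygosity is Zygosity.HOM and c.sample_id in parent_keys}
    child_keys = {
        t.child_id: {c.variant_key for c in cohort.calls if c.sample_id == t.child_id}
        for t in cohort.pedigree.trios
    }
    for trio in cohort.pedigree.trios:
        for parent in (trio.father_id, trio.mother_id):
            for sid, key in hom:
                if sid == parent:
                    assert key in child_keys[trio.child_id]


def test_infeasible_params_rejected():
    with pytest.raises(ValidationError, match="tier_mix"):
        CohortSimParams(tier_mix=(0.4, 0.3, 0.2, 0.1), rare_fraction=0.5)
    with pytest.raises(ValidationError):
        CohortSimParams(n_trios=300, n_couples=100)
    with pytest.raises(ValidationError):
        CohortSimParams(artifact_rate=1.5)


def test_default_panel_shape():
    panel = default_gene_panel()
    assert len(panel) == 118
    assert len({e.gene for e in panel}) == 118
    assert all(0 <= e.n_missense_plp <= e.n_total_plp for e in panel)


def test_qc_training_set_reproducible_and_labeled():
    a = generate_qc_training_set(50, 30, separation=3.0, seed=4)
    b = generate_qc_training_set(50, 30, separation=3.0, seed=4)
    assert a.equals(b)
    assert a.label.value_counts().to_dict() == {"TRUE_CALL": 50, "FALSE_CALL": 30}
    with pytest.raises(ValidationError):
        generate_qc_training_set(0, 10)


def test_fixture_exercises_every_rule_branch(refcohort, refcohort_classified):
    """Classification completeness: every retention criterion and every
    exclusion reason fires at least once on the deterministic fixture."""
    tiered, _ = refcohort_classified
    fired = {c for tv in tiered for c in tv.fired_criteria}
    assert {"WHITELIST", "PVS1", "PM2", "CLINVAR_P", "HGMD_DM", "NOVEL_LOF",
            "CLINVAR_VUS_LOF", "CLINVAR_LP_LIMITED", "HGMD_DM_ONLY",
            "ENSEMBLE"} <= fired
    reasons = {tv.exclusion_reason for tv in tiered if tv.tier is Tier.EXCLUDED}
    assert reasons == {"BENIGN_DB", "COMMON_AF", "NO_CRITERIA"}
    # and negatives exist: distractors fail each quantitative gate
    excluded = [tv.call for tv in tiered if tv.tier is Tier.EXCLUDED]
    assert any(c.cadd == 19.0 for c in excluded)          # CADD below 20
    assert any(c.mcap == 0.01 for c in excluded)          # M-CAP below 0.025
    assert any(
        sum(1 for v in c.tool_calls.values() if v.value == "DELETERIOUS") == 3
        for c in excluded
    )                                                     # 3 of 7 votes


def test_fixture_whitelist_distinct_from_plain_classification(refcohort):
    bbs1 = [c for c in refcohort.calls if c.gene == "BBS1" and c.maf == 0.002]
    assert len(bbs1) == 3
    without = classify_variant(bbs1[0], whitelist=())
    with_wl = classify_variant(bbs1[0], whitelist=default_whitelist())
    assert without.tier is Tier.EXCLUDED and with_wl.tier is Tier.PATHOGENIC


def test_fixture_genes_within_panel(refcohort):
    assert {c.gene for c in refcohort.calls} <= set(PANEL_GENES)
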