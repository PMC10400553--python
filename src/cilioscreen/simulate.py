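"""Synthetic cohorts for an NGS carrier-screening pipeline.

Real screening cohorts (WES of healthy parents, population birth cohorts)
cannot be redistributed, so every pipeline stage here is exercised on
synthetic data with the statistical structure the pipeline assumes:

* :func:`generate_cohort` samples an annotated cohort — per-individual
  call counts from a truncated negative binomial (range 1-24), correlated
  in-silico predictor calls from a latent deleteriousness variable,
  database labels with a configurable HGMD-vs-ClinVar conflict rate, QC
  artifacts violating the depth / alternate-fraction cut-offs, and
  Mendelian offspring genotypes for trio phasing.  Each call carries a
  hidden truth label.
* :func:`generate_reference_cohort` hand-constructs (no randomness) a
  395-individual cohort whose classification yields an exact, known
  accounting: 48 pathogenic calls (26 LOF / 22 missense-like) in 43
  carriers, 38 novel-LOF calls, 265 strong VUS (262 missense-like
  observations over 239 unique variants, 23 of them recurring in exactly
  two individuals), 197 VUS carriers, 2 of 21 consanguineous couples at
  risk for reportable variants and 7 of 156 non-consanguineous couples
  sharing VUS in one gene — with distractor calls violating each
  classification rule interleaved.
* :func:`generate_qc_training_set` draws labeled call-quality features
  from two class distributions with controllable separation.
* :func:`generate_phased_trios` plants cis/trans haplotype
  configurations and derives Mendelian child genotypes.

The gene panel, whitelist and per-gene knowledge table produced by
:func:`default_gene_panel` are synthetic stand-ins: gene symbols are real
ciliopathy genes, but counts, prevalences and coordinates are generated,
not curated from the literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    AnnotatedCall,
    ClinVar,
    Consequence,
    Couple,
    GenePanelEntry,
    Hgmd,
    PedigreeSet,
    PREDICTOR_TOOLS,
    SampleMetrics,
    ToolPrediction,
    Trio,
    ValidationError,
    WhitelistEntry,
    Zygosity,
)

# ---------------------------------------------------------------------------
# Default 118-gene ciliopathy panel

PANEL_GENES: tuple[str, ...] = (
    "AHI1", "ALMS1", "ANKS6", "ARL13B", "ARL6", "ARMC9", "B9D1", "B9D2",
    "BBIP1", "BBS1", "BBS2", "BBS4", "BBS5", "BBS7", "BBS9", "BBS10",
    "BBS12", "C8orf37", "CC2D2A", "CEP104", "CEP120", "CEP164", "CEP19",
    "CEP290", "CEP41", "CEP44", "CEP55", "CEP83", "CENPF", "CFAP410",
    "CFAP418", "CFAP52", "CILK1", "CPLANE1", "CSPP1", "DCDC2", "DYNC2H1",
    "DYNC2I1", "DYNC2I2", "DYNC2LI1", "EVC", "EVC2", "FAM149B1", "FUZ",
    "GLIS2", "GPR161", "HYLS1", "IFT27", "IFT43", "IFT52", "IFT57",
    "IFT80", "IFT81", "IFT122", "IFT140", "IFT172", "INPP5E", "INTU",
    "INVS", "IQCB1", "KIAA0556", "KIAA0586", "KIAA0753", "KIF14", "KIF7",
    "LZTFL1", "MAK", "MKKS", "MKS1", "NEK1", "NEK8", "NPHP1", "NPHP3",
    "NPHP4", "OFD1", "PDE6D", "PIBF1", "PKD1L1", "PKHD1", "PLK4", "POC1A",
    "POC1B", "RP1", "RPGR", "RPGRIP1L", "SCAPER", "SCLT1", "SDCCAG8",
    "SMO", "SUFU", "TBC1D32", "TCTN1", "TCTN2", "TCTN3", "TMEM107",
    "TMEM138", "TMEM216", "TMEM231", "TMEM237", "TMEM67", "TOGARAM1",
    "TRAF3IP1", "TTC21B", "TTC8", "TTLL5", "TXNDC15", "USH2A", "ADGRV1",
    "WDPCP", "WDR19", "WDR34", "WDR35", "WDR60", "WNT5A", "ZNF423",
    "CEP78", "CFAP53", "DZIP1L",
)
assert len(PANEL_GENES) == 118, len(PANEL_GENES)

_GENE_INDEX = {g: i for i, g in enumerate(PANEL_GENES)}

#: Genes whose patient disease alleles are predominantly missense
#: (high missense score) vs predominantly truncating (low score).
_MISSENSE_DRIVEN = {"INPP5E", "DYNC2H1", "BBS1", "USH2A", "TMEM67", "ADGRV1", "ALMS1"}
_TRUNCATING_DRIVEN = {"CEP290", "KIF7", "IFT172", "CPLANE1", "CC2D2A", "AHI1",
                      "KIAA0586", "NPHP1", "RPGRIP1L"}


def default_gene_panel() -> list[GenePanelEntry]:
    """Synthetic per-gene knowledge table for the default panel.

    Deterministic, formula-generated stand-in for a curated table of
    described P/LP allele counts, disease prevalences and patient
    variant-type spectra.  Genes known to be missense-driven or
    truncating-driven get matching spectra; the rest interpolate.
    """
    entries = []
    for i, gene in enumerate(PANEL_GENES):
        n_total = 20 + (i * 7) % 80
        if gene in _MISSENSE_DRIVEN:
            ms_frac = 0.45 + (i % 4) * 0.1
        elif gene in _TRUNCATING_DRIVEN:
            ms_frac = 0.02 + (i % 3) * 0.02
        else:
            ms_frac = ((i * 13) % 50) / 100.0
        n_missense = min(n_total, round(ms_frac * n_total))
        prevalence = 10.0 ** -(4 + (i % 3))  # 1e-4 .. 1e-6
        spectrum_missense = n_missense / n_total
        entries.append(GenePanelEntry(
            gene=gene,
            n_missense_plp=n_missense,
            n_total_plp=n_total,
            disease_prevalence=prevalence,
            spectrum_truncating=1.0 - spectrum_missense,
            spectrum_missense=spectrum_missense,
        ))
    return entries


#: Recurrent founder alleles kept at any population frequency.  Coordinates
#: are synthetic placeholders, used consistently by the fixture generator.
BBS1_M309R = dict(gene="BBS1", chrom="11", pos=66278121, ref="T", alt="G",
                  hgvs="NM_024649.4:c.1169T>G")
KIAA0586_DEL = dict(gene="KIAA0586", chrom="14", pos=58899357, ref="AG", alt="A",
                    hgvs="NM_001244189.1:c.428delG")


def default_whitelist() -> list[WhitelistEntry]:
    from .model import normalize_variant_key

    return [
        WhitelistEntry(
            gene=BBS1_M309R["gene"],
            variant_key=normalize_variant_key(
                BBS1_M309R["chrom"], BBS1_M309R["pos"],
                BBS1_M309R["ref"], BBS1_M309R["alt"]),
            hgvs=BBS1_M309R["hgvs"],
            rationale="recurrent p.M309R allele, established pathogenic despite AF > 0.1%",
        ),
        WhitelistEntry(
            gene=KIAA0586_DEL["gene"],
            variant_key=normalize_variant_key(
                KIAA0586_DEL["chrom"], KIAA0586_DEL["pos"],
                KIAA0586_DEL["ref"], KIAA0586_DEL["alt"]),
            hgvs=KIAA0586_DEL["hgvs"],
            rationale="recurrent c.428delG frameshift, established pathogenic despite AF > 0.1%",
        ),
    ]


# ---------------------------------------------------------------------------
# Shared construction helpers

_TOOLS_ALL_MISSING = {t: ToolPrediction.MISSING for t in PREDICTOR_TOOLS}


def _tools(n_deleterious: int, n_missing: int = 0) -> dict[str, ToolPrediction]:
    """First ``n_deleterious`` tools deleterious, last ``n_missing`` missing."""
    out = {}
    for i, t in enumerate(PREDICTOR_TOOLS):
        if i < n_deleterious:
            out[t] = ToolPrediction.DELETERIOUS
        elif i >= len(PREDICTOR_TOOLS) - n_missing:
            out[t] = ToolPrediction.MISSING
        else:
            out[t] = ToolPrediction.TOLERATED
    return out


def _gene_chrom(gene: str) -> str:
    return str(1 + _GENE_INDEX.get(gene, 0) % 22)


# ---------------------------------------------------------------------------
# Deterministic fixture with exact accounting

@dataclass
class ReferenceCohort:
    """Deterministic cohort whose classification accounting is known exactly."""

    calls: list[AnnotatedCall]
    pedigree: PedigreeSet
    metrics: list[SampleMetrics]
    whitelist: list[WhitelistEntry]
    individuals: list[str]

    # exact expected accounting, for reference by callers
    expected: dict = field(default_factory=dict)


def _sid(i: int) -> str:
    return f"S{i:03d}"


def generate_reference_cohort() -> ReferenceCohort:
    """Hand-constructed 395-individual cohort with exact tier accounting.

    Layout: individuals S001..S395; couples k = 1..177 are (S(2k-1), S(2k)),
    the first 21 consanguineous; S355..S395 are 41 single parents.  Every
    individual carries at least one distractor call so the cohort size is
    recoverable from the variant table.  See the module docstring for the
    exact expected counts.
    """
    calls: list[AnnotatedCall] = []
    pos_counter = [10_000]

    def new_pos() -> int:
        pos_counter[0] += 50
        return pos_counter[0]

    def add(sample: str, gene: str, consequence: Consequence, *,
            chrom: Optional[str] = None, pos: Optional[int] = None,
            ref: str = "A", alt: str = "G", **kw) -> AnnotatedCall:
        call = AnnotatedCall(
            sample_id=sample, gene=gene,
            chrom=chrom or _gene_chrom(gene), pos=pos or new_pos(),
            ref=ref, alt=alt, consequence=consequence,
            depth=kw.pop("depth", 180), alt_fraction=kw.pop("alt_fraction", 0.48),
            tool_calls=kw.pop("tool_calls", dict(_TOOLS_ALL_MISSING)),
            **kw,
        )
        calls.append(call)
        return call

    # --- pedigree -----------------------------------------------------
    adults = [_sid(i) for i in range(1, 396)]
    couples = [
        Couple(_sid(2 * k - 1), _sid(2 * k), consanguineous=k <= 21)
        for k in range(1, 178)
    ]
    children = [f"CH{k:03d}" for k in range(1, 178)]
    single_children = [f"CH{k:03d}" for k in range(178, 219)]
    trios = [
        Trio(c.partner_a, c.partner_b, ch) for c, ch in zip(couples, children)
    ]
    pedigree = PedigreeSet(
        individuals=adults + children + single_children,
        couples=couples,
        trios=trios,
        sex={**{_sid(2 * k - 1): "M" for k in range(1, 178)},
             **{_sid(2 * k): "F" for k in range(1, 178)}},
    )

    # --- pathogenic tier: 48 calls in 43 carriers (26 LOF, 22 missense-like)
    path_genes = ["ALMS1", "NPHP1", "BBS10", "MKKS", "CEP164", "WDR19",
                  "IFT140", "TMEM216", "PKHD1", "EVC", "TCTN2", "B9D1"]

    # risk couple 1 (consanguineous): both partners pathogenic missense in DYNC2H1
    for sid, maf in ((_sid(1), 0.0004), (_sid(2), 0.0003)):
        add(sid, "DYNC2H1", Consequence.MISSENSE, maf=maf,
            clinvar=ClinVar.P, hgmd=Hgmd.DM, cadd=28.0, mcap=0.2,
            tool_calls=_tools(6), vipur=0.75)
    # risk couple 2 (consanguineous): pathogenic LOF + novel LOF in CEP290
    add(_sid(3), "CEP290", Consequence.NONSENSE, maf=0.0002, clinvar=ClinVar.P,
        ref="C", alt="T", cadd=40.0)

    # whitelisted recurrent alleles, AF > 0.1%, three carriers each
    for sid in (_sid(57), _sid(59), _sid(61)):
        add(sid, "BBS1", Consequence.MISSENSE, chrom=BBS1_M309R["chrom"],
            pos=BBS1_M309R["pos"], ref=BBS1_M309R["ref"], alt=BBS1_M309R["alt"],
            hgvs=BBS1_M309R["hgvs"], maf=0.002, clinvar=ClinVar.P, hgmd=Hgmd.DM,
            cadd=24.0, mcap=0.1, tool_calls=_tools(5))
    for sid in (_sid(63), _sid(65), _sid(67)):
        add(sid, "KIAA0586", Consequence.FRAMESHIFT, chrom=KIAA0586_DEL["chrom"],
            pos=KIAA0586_DEL["pos"], ref=KIAA0586_DEL["ref"], alt=KIAA0586_DEL["alt"],
            hgvs=KIAA0586_DEL["hgvs"], maf=0.0015, clinvar=ClinVar.P, hgmd=Hgmd.DM)

    # 39 further pathogenic calls: 34 carriers S069..S135 (odd), the first
    # five carrying a second call.  Slots 0-21 LOF, 22-38 missense-like.
    lof_kinds = [Consequence.NONSENSE, Consequence.FRAMESHIFT,
                 Consequence.CANONICAL_SPLICE]
    for slot in range(39):
        if slot < 34:
            carrier_idx, gene = slot, path_genes[slot % len(path_genes)]
        else:
            carrier_idx = slot - 34
            gene = path_genes[(carrier_idx + 6) % len(path_genes)]
        sid = _sid(69 + 2 * carrier_idx)
        if slot < 22:
            csq = lof_kinds[slot % 3]
            route = slot % 3  # 0: ClinVar P, 1: HGMD DM, 2: both
            add(sid, gene, csq, maf=(None if slot % 4 == 0 else 0.0005),
                clinvar=ClinVar.P if route in (0, 2) else ClinVar.ABSENT,
                hgmd=Hgmd.DM if route in (1, 2) else Hgmd.ABSENT,
                ref="G", alt="GT" if csq is Consequence.FRAMESHIFT else "A")
        else:
            csq = (Consequence.NONCODING if slot in (22, 23)
                   else Consequence.INFRAME_INDEL if slot == 24
                   else Consequence.MISSENSE)
            add(sid, gene, csq, maf=0.0006, clinvar=ClinVar.P, hgmd=Hgmd.DM,
                clinvar_limited_evidence=False, cadd=26.0, mcap=0.15,
                tool_calls=_tools(5), vipur=0.72 if csq is Consequence.MISSENSE else None)

    # --- novel LOF tier: 38 calls in 37 carriers ----------------------
    nl_genes = ["SDCCAG8", "RPGRIP1L", "IQCB1", "NEK8", "ANKS6", "GLIS2",
                "INVS", "TTC21B", "WDR35", "IFT122"]
    add(_sid(4), "CEP290", Consequence.FRAMESHIFT, maf=None, ref="C", alt="CA")
    for j in range(36):
        sid = _sid(137 + 2 * j)
        gene = nl_genes[j % len(nl_genes)]
        csq = lof_kinds[j % 3]
        add(sid, gene, csq, maf=(None if j % 2 == 0 else 0.0001),
            ref="T", alt="TA" if csq is Consequence.FRAMESHIFT else "C")
        if j == 0:  # the single two-call novel-LOF carrier
            add(sid, nl_genes[5], Consequence.NONSENSE, maf=None, ref="G", alt="T")

    # --- strong VUS tier: 265 calls in 197 carriers -------------------
    vus_couple_genes = ["USH2A", "ADGRV1", "IFT81", "TMEM67", "CC2D2A",
                        "AHI1", "KIF7"]
    vus_genes = ["USH2A", "ADGRV1", "DYNC2H1", "CEP290", "KIF7", "IFT172",
                 "INPP5E", "CSPP1", "CEP120", "PIBF1", "ARMC9", "TOGARAM1",
                 "CC2D2A", "TMEM67", "AHI1", "CPLANE1", "HYLS1", "NEK1",
                 "KIF14", "SCLT1"]
    vipur_cycle = [0.85, 0.75, 0.6, 0.3, None]

    def vus_annotation(i: int, consequence: Consequence) -> dict:
        """Rotate through the strong-VUS retention routes."""
        route = i % 4
        kw: dict = {"maf": 0.0005 if i % 3 else None,
                    "vipur": vipur_cycle[i % len(vipur_cycle)]}
        if route in (0, 3):  # in-silico ensemble
            kw.update(cadd=22.0 + (i % 10), mcap=0.03 + (i % 5) * 0.05,
                      tool_calls=_tools(4 + i % 4),
                      clinvar=ClinVar.CONFLICTING if route == 3 else ClinVar.ABSENT)
        elif route == 1:  # HGMD DM / DM? without ClinVar P
            kw.update(hgmd=Hgmd.DM if i % 8 == 1 else Hgmd.DM_QUERY,
                      clinvar=[ClinVar.ABSENT, ClinVar.VUS,
                               ClinVar.CONFLICTING][i % 3] if consequence
                      is Consequence.MISSENSE else ClinVar.ABSENT,
                      cadd=18.0, mcap=0.02, tool_calls=_tools(2))
        else:  # route 2: limited-evidence database support
            if i % 8 == 2:
                kw.update(clinvar=ClinVar.P, hgmd=Hgmd.DM,
                          clinvar_limited_evidence=True)
            else:
                kw.update(clinvar=ClinVar.LP, clinvar_limited_evidence=True)
        return kw

    # 7 couple-shared recurrent VUS (couples 22..28, non-consanguineous)
    for j, gene in enumerate(vus_couple_genes):
        chrom, pos = _gene_chrom(gene), new_pos()
        for sid in (_sid(43 + 2 * j), _sid(44 + 2 * j)):
            add(sid, gene, Consequence.MISSENSE, chrom=chrom, pos=pos,
                ref="C", alt="A", maf=0.0004, cadd=27.0, mcap=0.08,
                tool_calls=_tools(5), vipur=0.8)

    # remaining 183 VUS carriers: even-indexed partners (minus the reserved
    # ones) plus 15 single parents; burden profile [5,4,3,3] + 57x2 + 122x1
    reserved_evens = {2, 4} | {44 + 2 * j for j in range(7)}
    even_pool = [_sid(i) for i in range(2, 355, 2) if i not in reserved_evens]
    vus_carriers = even_pool + [_sid(i) for i in range(355, 370)]
    assert len(vus_carriers) == 183
    burdens = [5, 4, 3, 3] + [2] * 57 + [1] * 122
    multi = [(c, b) for c, b in zip(vus_carriers, burdens) if b > 1]
    singles = [c for c, b in zip(vus_carriers, burdens) if b == 1]

    vi = 0  # rotating annotation index
    # multi-call carriers: unique singleton variants, distinct genes per carrier
    for ci, (carrier, burden) in enumerate(multi):
        for k in range(burden):
            gene = vus_genes[(ci + 3 * k) % len(vus_genes)]
            csq = (Consequence.INFRAME_INDEL if vi % 20 == 7
                   else Consequence.NONCODING if vi % 25 == 11
                   else Consequence.MISSENSE)
            add(carrier, gene, csq, ref="G", alt="C", **vus_annotation(vi, csq))
            vi += 1
    # 16 recurrent variants shared by pairs of single-call carriers
    for j in range(16):
        gene = vus_genes[(j * 5) % len(vus_genes)]
        chrom, pos = _gene_chrom(gene), new_pos()
        ann = vus_annotation(vi, Consequence.MISSENSE)
        vi += 1
        for carrier in (singles[2 * j], singles[2 * j + 1]):
            add(carrier, gene, Consequence.MISSENSE, chrom=chrom, pos=pos,
                ref="T", alt="G", **ann)
    # 3 LOF alleles that ClinVar itself calls VUS
    lof_vus_carriers = singles[32:35]
    for j, carrier in enumerate(lof_vus_carriers):
        add(carrier, "TCTN1", Consequence.NONSENSE, maf=0.0002,
            clinvar=ClinVar.VUS, hgmd=Hgmd.DM_QUERY if j == 0 else Hgmd.ABSENT,
            ref="C", alt="T")
    # remaining single-call carriers: unique singleton missense-like VUS
    for carrier in singles[35:]:
        csq = Consequence.MISSENSE
        gene = vus_genes[vi % len(vus_genes)]
        add(carrier, gene, csq, ref="A", alt="T", **vus_annotation(vi, csq))
        vi += 1

    # --- distractors: one excluded call per individual ----------------
    # Each violates a specific rule: common allele, database-benign,
    # failing CADD / M-CAP / vote count, common LOF, missing scores.
    for i in range(1, 396):
        sid = _sid(i)
        gene = PANEL_GENES[(i * 7) % len(PANEL_GENES)]
        kind = i % 8
        if kind == 0:
            add(sid, gene, Consequence.SYNONYMOUS, maf=0.05)
        elif kind == 1:
            add(sid, gene, Consequence.MISSENSE, maf=0.0004, cadd=19.0,
                mcap=0.5, tool_calls=_tools(7))          # fails CADD >= 20
        elif kind == 2:
            add(sid, gene, Consequence.MISSENSE, maf=0.0004, cadd=30.0,
                mcap=0.5, tool_calls=_tools(3))          # fails 4-of-7 votes
        elif kind == 3:
            add(sid, gene, Consequence.MISSENSE, maf=0.0004, clinvar=ClinVar.B,
                hgmd=Hgmd.DM, cadd=28.0, mcap=0.3,
                tool_calls=_tools(6))                    # DM contradicted by benign
        elif kind == 4:
            add(sid, gene, Consequence.MISSENSE, maf=0.0004, cadd=25.0,
                mcap=0.01, tool_calls=_tools(6))         # fails M-CAP >= 0.025
        elif kind == 5:
            add(sid, gene, Consequence.MISSENSE, maf=0.02, clinvar=ClinVar.LB)
        elif kind == 6:
            add(sid, gene, Consequence.NONSENSE, maf=0.005, ref="C", alt="T")
        else:
            add(sid, gene, Consequence.MISSENSE, maf=0.0004)  # no scores at all

    metrics = [SampleMetrics(sid, 286.9, 0.97) for sid in adults]

    expected = {
        "pathogenic_total": 48, "pathogenic_lof": 26, "pathogenic_missense_like": 22,
        "novel_lof_total": 38, "strong_vus_total": 265,
        "vus_missense_like_observations": 262, "vus_missense_like_unique": 239,
        "vus_recurrent_variants": 23,
        "carriers_pathogenic": 43, "carriers_reportable": 80,
        "carriers_strong_vus": 197,
        "couples_total": 177, "couples_consanguineous": 21,
        "couples_at_risk_reportable": 2, "couples_at_risk_strong_vus": 7,
    }
    return ReferenceCohort(
        calls=calls,
        pedigree=pedigree,
        metrics=metrics,
        whitelist=default_whitelist(),
        individuals=adults,
        expected=expected,
    )


# ---------------------------------------------------------------------------
# Sampled cohort generator

#: Per-tool loadings on the latent deleteriousness variable; pairwise
#: correlations of the continuous scores are products of loadings, spanning
#: a weakly negative to strongly positive range (FATHMM-style predictors
#: are known to anti-correlate with the rest).
_TOOL_LOADINGS = {
    "SIFT": 0.80, "Polyphen2": 0.75, "MutationTaster": 0.70,
    "MutationAssessor": 0.60, "PROVEAN": 0.55, "LRT": 0.50, "FATHMM": -0.15,
}

_TIER_NAMES = ("PATHOGENIC", "NOVEL_LOF", "STRONG_VUS", "BENIGN")


@dataclass
class CohortSimParams:
    """Knobs of the sampled cohort generator; defaults emulate a local
    clinical-exome screening cohort (~395 parents, ~287x coverage,
    ~9.3 retained calls per individual)."""

    n_individuals: int = 395
    n_couples: int = 176
    consanguineous_fraction: float = 21 / 176
    n_trios: int = 50
    panel: Sequence[GenePanelEntry] = field(default_factory=default_gene_panel)
    mean_calls_per_individual: float = 9.3
    max_calls_per_individual: int = 24
    rare_fraction: float = 0.92
    tier_mix: tuple[float, float, float, float] = (0.013, 0.010, 0.072, 0.905)
    latent_correlation: float = 1.0
    db_conflict_rate: float = 0.02
    mean_coverage: float = 287.0
    artifact_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("consanguineous_fraction", "rare_fraction",
                     "db_conflict_rate", "artifact_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if abs(sum(self.tier_mix) - 1.0) > 1e-9 or min(self.tier_mix) < 0:
            raise ValidationError("tier_mix must be non-negative and sum to 1")
        if self.n_trios > self.n_couples:
            raise ValidationError("n_trios cannot exceed n_couples")
        if 2 * self.n_couples > self.n_individuals:
            raise ValidationError("cohort too small for the requested couples")
        # all non-benign tiers require rare alleles
        if sum(self.tier_mix[:3]) > self.rare_fraction + 1e-9:
            raise ValidationError(
                "infeasible tier_mix: non-benign fraction exceeds rare_fraction"
            )


@dataclass
class SimulatedCohort:
    calls: list[AnnotatedCall]          # parents and trio children
    pedigree: PedigreeSet
    metrics: list[SampleMetrics]
    truth: pd.DataFrame                 # one row per parent call
    individuals: list[str]              # the screened parents


def generate_cohort(params: CohortSimParams = CohortSimParams()) -> SimulatedCohort:
    """Sample a synthetic annotated cohort; deterministic for a fixed seed."""
    rng = np.random.default_rng(params.seed)
    p = params

    parents = [f"SIM{i:04d}" for i in range(1, p.n_individuals + 1)]
    n_consang = round(p.consanguineous_fraction * p.n_couples)
    couples = [
        Couple(parents[2 * k], parents[2 * k + 1], consanguineous=k < n_consang)
        for k in range(p.n_couples)
    ]
    children = [f"SIMCH{k:04d}" for k in range(1, p.n_trios + 1)]
    trios = [Trio(c.partner_a, c.partner_b, ch)
             for c, ch in zip(couples[: p.n_trios], children)]
    pedigree = PedigreeSet(
        individuals=parents + children, couples=couples, trios=trios
    )

    loadings = {
        t: float(np.clip(p.latent_correlation * a, -0.95, 0.95))
        for t, a in _TOOL_LOADINGS.items()
    }
    genes = [e.gene for e in p.panel]
    nb_r = 5.0
    nb_p = nb_r / (nb_r + p.mean_calls_per_individual)
    benign_share = p.tier_mix[3]
    rare_benign = (
        (p.rare_fraction - sum(p.tier_mix[:3])) / benign_share
        if benign_share > 0 else 0.0
    )

    calls: list[AnnotatedCall] = []
    truth_rows: list[dict] = []
    pos_counter = [1_000_000]

    def new_pos() -> int:
        pos_counter[0] += 25
        return pos_counter[0]

    def sample_n_calls() -> int:
        for _ in range(100):
            n = rng.negative_binomial(nb_r, nb_p)
            if 1 <= n <= p.max_calls_per_individual:
                return int(n)
        return int(np.clip(round(p.mean_calls_per_individual), 1,
                           p.max_calls_per_individual))

    lof_kinds = (Consequence.NONSENSE, Consequence.FRAMESHIFT,
                 Consequence.CANONICAL_SPLICE)

    def make_call(sample: str) -> tuple[AnnotatedCall, dict]:
        tier = _TIER_NAMES[rng.choice(4, p=list(p.tier_mix))]
        gene = genes[rng.integers(len(genes))]
        z_mu = {"PATHOGENIC": 2.0, "NOVEL_LOF": 1.5,
                "STRONG_VUS": 2.0, "BENIGN": 0.0}[tier]
        z = rng.normal(z_mu, 1.0)
        cont = {
            t: loadings[t] * z + math.sqrt(max(0.0, 1 - loadings[t] ** 2)) * rng.normal()
            for t in PREDICTOR_TOOLS
        }
        tool_calls = {
            t: (ToolPrediction.MISSING if rng.random() < 0.05
                else ToolPrediction.DELETERIOUS if cont[t] > 1.0
                else ToolPrediction.TOLERATED)
            for t in PREDICTOR_TOOLS
        }

        maf_rare = float(10 ** rng.uniform(-6, -3.05))
        kw: dict = {"maf": maf_rare, "cadd": float(np.clip(rng.normal(12, 6), 0, 60)),
                    "mcap": float(np.clip(rng.normal(0.02, 0.02), 0, 1)),
                    "clinvar": ClinVar.ABSENT, "hgmd": Hgmd.ABSENT,
                    "clinvar_limited_evidence": False}
        csq = Consequence.MISSENSE

        if tier == "PATHOGENIC":
            route = rng.integers(3)
            if route < 2:
                csq = lof_kinds[rng.integers(3)]
                kw["clinvar"] = ClinVar.P if route == 0 else ClinVar.ABSENT
                kw["hgmd"] = Hgmd.DM if route >= 1 else Hgmd.ABSENT
                kw["cadd"] = float(rng.uniform(30, 50))
            else:
                kw.update(clinvar=ClinVar.P, hgmd=Hgmd.DM,
                          cadd=float(rng.uniform(22, 35)),
                          mcap=float(rng.uniform(0.05, 0.6)))
        elif tier == "NOVEL_LOF":
            csq = lof_kinds[rng.integers(3)]
            kw["maf"] = None if rng.random() < 0.5 else maf_rare
            kw["cadd"] = float(rng.uniform(30, 50))
        elif tier == "STRONG_VUS":
            route = rng.integers(10)
            if route < 1:  # LOF that ClinVar calls uncertain
                csq = lof_kinds[rng.integers(3)]
                kw["clinvar"] = ClinVar.VUS
            elif route < 3:  # HGMD DM / DM? support
                kw["hgmd"] = Hgmd.DM if rng.random() < 0.5 else Hgmd.DM_QUERY
                kw["clinvar"] = (ClinVar.CONFLICTING if rng.random() < 0.4
                                 else ClinVar.ABSENT)
            elif route < 4:  # ClinVar LP with limited evidence
                kw.update(clinvar=ClinVar.LP, clinvar_limited_evidence=True)
            else:  # in-silico ensemble
                kw["cadd"] = float(rng.uniform(20, 40))
                kw["mcap"] = float(rng.uniform(0.025, 0.7))
                n_del = sum(
                    1 for t in PREDICTOR_TOOLS
                    if tool_calls[t] is ToolPrediction.DELETERIOUS
                )
                if n_del < 4:  # enforce the planted ensemble pass
                    for t in sorted(cont, key=cont.get, reverse=True):
                        if tool_calls[t] is not ToolPrediction.DELETERIOUS:
                            tool_calls[t] = ToolPrediction.DELETERIOUS
                            n_del += 1
                        if n_del >= 4:
                            break
        else:  # BENIGN
            if rng.random() < rare_benign:
                if rng.random() < 0.6:  # rare but failing the ensemble
                    kw["cadd"] = float(rng.uniform(0, 19.5))
                    deleterious = [t for t in PREDICTOR_TOOLS
                                   if tool_calls[t] is ToolPrediction.DELETERIOUS]
                    for t in deleterious[3:]:
                        tool_calls[t] = ToolPrediction.TOLERATED
                else:  # rare with a benign database assertion
                    kw["clinvar"] = ClinVar.B if rng.random() < 0.6 else ClinVar.LB
                    if rng.random() < p.db_conflict_rate:
                        kw["hgmd"] = Hgmd.DM  # DM contradicted by a benign assertion
            else:  # common allele
                kw["maf"] = float(10 ** rng.uniform(-2.9, -0.7))
                if rng.random() < 0.5:
                    csq = Consequence.SYNONYMOUS

        is_artifact = bool(rng.random() < p.artifact_rate)
        if is_artifact:
            if rng.random() < 0.5:
                depth = int(rng.integers(0, 20))
                alt_fraction = float(rng.uniform(0.16, 0.6))
            else:
                depth = int(rng.integers(20, 200))
                alt_fraction = float(rng.uniform(0.01, 0.159))
        else:
            depth = int(max(20, rng.normal(p.mean_coverage, 0.15 * p.mean_coverage)))
            alt_fraction = float(np.clip(rng.normal(0.5, 0.07), 0.16, 0.95))
        zyg = Zygosity.HOM if rng.random() < 0.03 else Zygosity.HET
        if zyg is Zygosity.HOM and not is_artifact:
            alt_fraction = float(np.clip(rng.normal(0.97, 0.02), 0.9, 1.0))

        call = AnnotatedCall(
            sample_id=sample, gene=gene, chrom=_gene_chrom(gene), pos=new_pos(),
            ref="A", alt="C", consequence=csq,
            tool_calls=tool_calls, depth=depth, alt_fraction=alt_fraction,
            zygosity=zyg,
            vipur=(float(rng.uniform(0, 1)) if rng.random() < 0.7 else None),
            **kw,
        )
        truth = {
            "sample_id": sample, "variant_key": call.variant_key,
            "gene": gene, "truth_tier": tier, "is_artifact": is_artifact,
            **{f"score_{t}": cont[t] for t in PREDICTOR_TOOLS},
        }
        return call, truth

    calls_by_parent: dict[str, list[AnnotatedCall]] = {}
    for parent in parents:
        n = sample_n_calls()
        own = []
        for _ in range(n):
            call, truth = make_call(parent)
            own.append(call)
            truth_rows.append(truth)
        calls_by_parent[parent] = own
        calls.extend(own)

    # Mendelian offspring: each child inherits every parental HOM allele and
    # each HET allele with probability 1/2, from both parents independently.
    for trio in trios:
        for parent_id in (trio.father_id, trio.mother_id):
            for call in calls_by_parent[parent_id]:
                transmitted = call.zygosity is Zygosity.HOM or rng.random() < 0.5
                if transmitted:
                    calls.append(call.with_(
                        sample_id=trio.child_id,
                        zygosity=Zygosity.HET,
                        depth=int(max(20, rng.normal(p.mean_coverage,
                                                     0.15 * p.mean_coverage))),
                        alt_fraction=float(np.clip(rng.normal(0.5, 0.07), 0.16, 0.95)),
                    ))

    metrics = [
        SampleMetrics(
            sample_id=parent,
            mean_coverage=float(max(1.0, rng.normal(p.mean_coverage,
                                                    0.1 * p.mean_coverage))),
            fraction_exome_at_depth=float(np.clip(rng.normal(0.97, 0.02), 0.0, 1.0)),
        )
        for parent in parents
    ]
    truth = pd.DataFrame(truth_rows)
    return SimulatedCohort(calls, pedigree, metrics, truth, parents)


# ---------------------------------------------------------------------------
# QC training / scoring sets

_QC_FEATURES = ("depth", "alt_fraction", "strand_balance", "mean_base_quality")
# per-feature gap, in feature units, contributed per unit of `separation`
_QC_GAP = np.array([30.0, 0.05, 0.06, 1.0])
_QC_TRUE_MEAN = np.array([280.0, 0.50, 0.50, 36.0])
_QC_SD = np.array([60.0, 0.08, 0.05, 2.0])


def generate_qc_training_set(
    n_true: int, n_false: int, separation: float = 6.0, seed: int = 0
) -> pd.DataFrame:
    """Labeled call-quality features from two class distributions.

    True calls are drawn around deep, balanced, high-quality values;
    artifact calls around means shifted down by ``separation`` times a
    per-feature gap.  ``separation=0`` makes the classes identical (no
    classifier can beat the larger class prior); large separation makes
    them linearly separable.
    """
    if n_true <= 0 or n_false <= 0:
        raise ValidationError("n_true and n_false must be positive")
    rng = np.random.default_rng(seed)
    true_X = rng.normal(_QC_TRUE_MEAN, _QC_SD / 4, size=(n_true, 4))
    false_X = rng.normal(_QC_TRUE_MEAN - separation * _QC_GAP, _QC_SD / 4,
                         size=(n_false, 4))
    X = np.vstack([true_X, false_X])
    X[:, 0] = np.clip(X[:, 0], 0.0, None)          # depth >= 0
    X[:, 1] = np.clip(X[:, 1], 0.0, 1.0)           # fractions in [0, 1]
    X[:, 2] = np.clip(X[:, 2], 0.0, 1.0)
    df = pd.DataFrame(X, columns=list(_QC_FEATURES))
    df["label"] = ["TRUE_CALL"] * n_true + ["FALSE_CALL"] * n_false
    return df


# ---------------------------------------------------------------------------
# Planted-phase trios

@dataclass(frozen=True)
class PhasedTrioFixture:
    parent_id: str
    child_id: str
    gene: str
    variant_key_a: str
    variant_key_b: str
    true_phase: str                       # "CIS" or "TRANS"
    parent_variant_keys: tuple[str, ...]
    child_genotypes: dict                 # variant_key -> bool | None


def generate_phased_trios(
    n_trios: int = 50, seed: int = 0, missing_fraction: float = 0.0
) -> list[PhasedTrioFixture]:
    """Plant cis/trans variant pairs in parents and derive child genotypes.

    The parent carries two heterozygous variants in one gene on known
    haplotypes; the child inherits one of the two parental haplotypes at
    random (the other parent contributes reference alleles).
    ``missing_fraction`` blanks child genotypes to create uninformative
    trios.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_trios):
        gene = PANEL_GENES[int(rng.integers(len(PANEL_GENES)))]
        chrom = _gene_chrom(gene)
        base = 5_000_000 + 1000 * i
        key_a = f"{chrom}:{base}:A:G"
        key_b = f"{chrom}:{base + 500}:C:T"
        cis = bool(rng.random() < 0.5)
        hap1 = {key_a, key_b} if cis else {key_a}
        hap2 = set() if cis else {key_b}
        transmitted = hap1 if rng.random() < 0.5 else hap2
        genotypes: dict = {key_a: key_a in transmitted, key_b: key_b in transmitted}
        for key in (key_a, key_b):
            if rng.random() < missing_fraction:
                genotypes[key] = None
        out.append(PhasedTrioFixture(
            parent_id=f"TP{i:03d}", child_id=f"TC{i:03d}", gene=gene,
            variant_key_a=key_a, variant_key_b=key_b,
            true_phase="CIS" if cis else "TRANS",
            parent_variant_keys=(key_a, key_b),
            child_genotypes=genotypes,
        ))
    return out
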