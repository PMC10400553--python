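"""Core domain types for panel-based carrier screening.

The pipeline interprets annotated variant calls from healthy individuals
screened across a panel of recessive-disease genes (the default panel is a
ciliopathy panel).  Everything downstream — quality control, tier
assignment, prioritization and couple-risk reporting — consumes the types
defined here.

Conventions
-----------
* Coordinates are 1-based and fully closed, matching VCF ``POS``.
* ``variant_key`` is ``chrom:pos:ref:alt`` after parsimony trimming
  (shared suffix then shared prefix removed, position adjusted), so the
  same indel spelled two ways collapses to one key.
* A missing gnomAD allele frequency means the allele has never been
  observed in the population database and is treated as frequency 0
  (i.e. novel, automatically satisfying any rarity cut-off).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence


class Consequence(str, enum.Enum):
    """Predicted molecular consequence of a variant on its transcript."""

    MISSENSE = "MISSENSE"
    NONSENSE = "NONSENSE"
    FRAMESHIFT = "FRAMESHIFT"
    CANONICAL_SPLICE = "CANONICAL_SPLICE"
    INFRAME_INDEL = "INFRAME_INDEL"
    NONCODING = "NONCODING"
    SYNONYMOUS = "SYNONYMOUS"
    OTHER = "OTHER"


#: Consequence classes counted as predicted loss of function (PVS1-eligible).
LOF_CONSEQUENCES = frozenset(
    {Consequence.NONSENSE, Consequence.FRAMESHIFT, Consequence.CANONICAL_SPLICE}
)

#: Consequence classes grouped as "missense / non-coding / in-frame" in
#: cohort summaries (every coding-relevant non-truncating class).
MISSENSE_LIKE_CONSEQUENCES = frozenset(
    {Consequence.MISSENSE, Consequence.INFRAME_INDEL, Consequence.NONCODING}
)


class ToolPrediction(str, enum.Enum):
    DELETERIOUS = "DELETERIOUS"
    TOLERATED = "TOLERATED"
    MISSING = "MISSING"


#: The seven categorical in-silico predictors voted over (CADD and M-CAP are
#: handled separately as numeric scores because they partly rely on these).
PREDICTOR_TOOLS: tuple[str, ...] = (
    "SIFT",
    "Polyphen2",
    "LRT",
    "MutationAssessor",
    "MutationTaster",
    "FATHMM",
    "PROVEAN",
)


class ClinVar(str, enum.Enum):
    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"
    CONFLICTING = "CONFLICTING"
    ABSENT = "ABSENT"


class Hgmd(str, enum.Enum):
    DM = "DM"
    DM_QUERY = "DM_QUERY"
    OTHER = "OTHER"
    ABSENT = "ABSENT"


class Zygosity(str, enum.Enum):
    HET = "HET"
    HOM = "HOM"


class Tier(str, enum.Enum):
    """Interpretation tier assigned to a post-QC call.

    ``PATHOGENIC`` and ``NOVEL_LOF`` are reportable in a screening setting;
    ``STRONG_VUS`` is very rare and predicted deleterious but not
    reportable; ``EXCLUDED`` failed every retention rule.
    """

    PATHOGENIC = "PATHOGENIC"
    NOVEL_LOF = "NOVEL_LOF"
    STRONG_VUS = "STRONG_VUS"
    EXCLUDED = "EXCLUDED"


#: Tiers that would be reported to a screened couple.
REPORTABLE_TIERS = frozenset({Tier.PATHOGENIC, Tier.NOVEL_LOF})


class VipurCategory(str, enum.Enum):
    STRONG_DELETERIOUS = "STRONG_DELETERIOUS"
    DELETERIOUS = "DELETERIOUS"
    NEUTRAL = "NEUTRAL"
    UNSCORED = "UNSCORED"


class Phase(str, enum.Enum):
    CIS = "CIS"
    TRANS = "TRANS"
    UNINFORMATIVE = "UNINFORMATIVE"


class ValidationError(ValueError):
    """An input value violates a domain invariant."""


def _check_fraction(name: str, value: Optional[float]) -> None:
    if value is not None and not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")


def normalize_variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Return a parsimony-trimmed ``chrom:pos:ref:alt`` key.

    Shared trailing bases are removed first, then shared leading bases
    (keeping at least one base on each side), with ``pos`` advanced per
    leading base removed.  This left-aligns the common right-padded /
    left-padded indel spellings onto one canonical key.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass(frozen=True)
class AnnotatedCall:
    """One variant observed in one sample, with annotation and QC fields.

    ``maf`` is the gnomAD minor allele frequency; ``None`` means the allele
    is absent from gnomAD and is treated as 0 by rarity rules (see
    :attr:`maf_or_zero`).  ``tool_calls`` must contain exactly the seven
    predictors in :data:`PREDICTOR_TOOLS`.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Consequence
    maf: Optional[float] = None
    cadd: Optional[float] = None
    mcap: Optional[float] = None
    tool_calls: Mapping[str, ToolPrediction] = field(
        default_factory=lambda: {t: ToolPrediction.MISSING for t in PREDICTOR_TOOLS}
    )
    clinvar: ClinVar = ClinVar.ABSENT
    clinvar_limited_evidence: bool = False
    hgmd: Hgmd = Hgmd.ABSENT
    vipur: Optional[float] = None
    depth: int = 0
    alt_fraction: float = 0.0
    zygosity: Zygosity = Zygosity.HET
    hgvs: Optional[str] = None

    def __post_init__(self) -> None:
        _check_fraction("maf", self.maf)
        _check_fraction("mcap", self.mcap)
        _check_fraction("vipur", self.vipur)
        _check_fraction("alt_fraction", self.alt_fraction)
        if self.cadd is not None and self.cadd < 0:
            raise ValidationError(f"cadd must be >= 0, got {self.cadd!r}")
        if self.depth < 0:
            raise ValidationError(f"depth must be >= 0, got {self.depth!r}")
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos!r}")
        if set(self.tool_calls) != set(PREDICTOR_TOOLS):
            missing = set(PREDICTOR_TOOLS) - set(self.tool_calls)
            extra = set(self.tool_calls) - set(PREDICTOR_TOOLS)
            raise ValidationError(
                f"tool_calls must name exactly {PREDICTOR_TOOLS}; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )

    @property
    def variant_key(self) -> str:
        return normalize_variant_key(self.chrom, self.pos, self.ref, self.alt)

    @property
    def maf_or_zero(self) -> float:
        """gnomAD frequency with absence interpreted as 0 (novel allele)."""
        return 0.0 if self.maf is None else self.maf

    @property
    def is_lof(self) -> bool:
        """Predicted loss of function: nonsense, frameshift or canonical splice."""
        return self.consequence in LOF_CONSEQUENCES

    def with_(self, **changes) -> "AnnotatedCall":
        """Return a copy with ``changes`` applied (dataclasses.replace)."""
        return replace(self, **changes)


@dataclass(frozen=True)
class Thresholds:
    """Every numeric cut-off the pipeline uses, with screening defaults.

    ``maf_max``
        Rarity cut-off (gnomAD MAF <= 0.1%) for all retention rules.
    ``cadd_min`` / ``mcap_min`` / ``votes_min``
        Ensemble rule: CADD >= 20, M-CAP >= 0.025 and at least 4 of the 7
        categorical predictors calling deleterious.  CADD and M-CAP bounds
        are inclusive.
    ``alt_fraction_min`` / ``depth_min``
        Per-call QC minima (16% supporting reads, 20x depth), inclusive.
    ``exome_cov_fraction_min`` at ``exome_cov_depth``
        Sample gate: a sample with less than 85% of the exome covered at
        >= 20x is excluded entirely.
    ``ms_min`` / ``vipur_strong`` / ``vipur_deleterious``
        Prioritization: gene missense score must exceed 0.1 and VIPUR
        must exceed 0.7 (strict) for first-priority VUS; VIPUR > 0.5
        suggests deleteriousness.
    """

    maf_max: float = 0.001
    cadd_min: float = 20.0
    mcap_min: float = 0.025
    votes_min: int = 4
    alt_fraction_min: float = 0.16
    depth_min: int = 20
    exome_cov_fraction_min: float = 0.85
    exome_cov_depth: int = 20
    ms_min: float = 0.1
    vipur_strong: float = 0.7
    vipur_deleterious: float = 0.5
    benign_override: bool = True

    def __post_init__(self) -> None:
        for name in ("maf_max", "exome_cov_fraction_min", "alt_fraction_min",
                     "mcap_min", "ms_min", "vipur_strong", "vipur_deleterious"):
            _check_fraction(name, getattr(self, name))
        if self.votes_min not in range(0, 8):
            raise ValidationError(f"votes_min must be 0..7, got {self.votes_min}")
        if self.cadd_min < 0 or self.depth_min < 0 or self.exome_cov_depth < 0:
            raise ValidationError("thresholds must be non-negative")


@dataclass(frozen=True)
class WhitelistEntry:
    """A known disease allele kept regardless of population frequency.

    Some recurrent founder alleles (e.g. *BBS1* p.M309R, *KIAA0586*
    c.428delG) exceed the 0.1% rarity cut-off yet are firmly established
    pathogenic; the whitelist pins them to the pathogenic tier.
    """

    gene: str
    variant_key: str
    hgvs: Optional[str] = None
    rationale: str = ""


@dataclass(frozen=True)
class GenePanelEntry:
    """Per-gene knowledge consumed by prioritization.

    ``n_missense_plp`` (m) and ``n_total_plp`` (M) are counts of described
    pathogenic/likely-pathogenic disease alleles; their ratio m/M is the
    gene "missense score".  ``patient_spectrum`` gives the proportions of
    truncating vs missense-like alleles among described patient alleles.
    """

    gene: str
    n_missense_plp: int = 0
    n_total_plp: int = 0
    disease_prevalence: Optional[float] = None
    spectrum_truncating: Optional[float] = None
    spectrum_missense: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.n_missense_plp <= self.n_total_plp) and self.n_total_plp >= 0:
            raise ValidationError(
                f"{self.gene}: need 0 <= n_missense_plp <= n_total_plp, "
                f"got {self.n_missense_plp}/{self.n_total_plp}"
            )
        _check_fraction("disease_prevalence", self.disease_prevalence)
        if (self.spectrum_truncating is None) != (self.spectrum_missense is None):
            raise ValidationError(f"{self.gene}: spectrum must give both proportions")
        if self.spectrum_truncating is not None:
            _check_fraction("spectrum_truncating", self.spectrum_truncating)
            _check_fraction("spectrum_missense", self.spectrum_missense)
            if not math.isclose(
                self.spectrum_truncating + self.spectrum_missense, 1.0, abs_tol=1e-6
            ):
                raise ValidationError(f"{self.gene}: spectrum must sum to 1")


@dataclass(frozen=True)
class Couple:
    partner_a: str
    partner_b: str
    consanguineous: bool = False

    def members(self) -> tuple[str, str]:
        return (self.partner_a, self.partner_b)


@dataclass(frozen=True)
class Trio:
    father_id: str
    mother_id: str
    child_id: str


@dataclass
class PedigreeSet:
    """Individuals, couples and parent-child trios of a screened cohort."""

    individuals: list[str]
    couples: list[Couple]
    trios: list[Trio]
    sex: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.individuals)
        for c in self.couples:
            if c.partner_a not in known or c.partner_b not in known:
                raise ValidationError(f"couple {c} references unknown individual")
        for t in self.trios:
            for sid in (t.father_id, t.mother_id, t.child_id):
                if sid not in known:
                    raise ValidationError(f"trio {t} references unknown individual {sid}")
        seen = set()
        for c in self.couples:
            key = frozenset(c.members())
            if key in seen:
                raise ValidationError(f"couple {sorted(key)} declared twice")
            seen.add(key)

    @property
    def parents(self) -> list[str]:
        """Individuals appearing as a couple partner or trio parent."""
        ids: set[str] = set()
        for c in self.couples:
            ids.update(c.members())
        for t in self.trios:
            ids.update((t.father_id, t.mother_id))
        return sorted(ids)

    @property
    def n_consanguineous(self) -> int:
        return sum(1 for c in self.couples if c.consanguineous)


@dataclass(frozen=True)
class SampleMetrics:
    """Sample-level sequencing quality used by the sample gate."""

    sample_id: str
    mean_coverage: float
    fraction_exome_at_depth: float

    def __post_init__(self) -> None:
        _check_fraction("fraction_exome_at_depth", self.fraction_exome_at_depth)
        if self.mean_coverage < 0:
            raise ValidationError("mean_coverage must be >= 0")


@dataclass(frozen=True)
class TieredVariant:
    """An annotated call plus its tier and the audit trail of fired rules.

    ``fired_criteria`` is ordered by rule evaluation; it is empty only for
    EXCLUDED calls (the exclusion reason is kept separately).
    """

    call: AnnotatedCall
    tier: Tier
    fired_criteria: tuple[str, ...] = ()
    exclusion_reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tier is not Tier.EXCLUDED and not self.fired_criteria:
            raise ValidationError("non-excluded tier requires fired criteria")

    @property
    def reportable(self) -> bool:
        return self.tier in REPORTABLE_TIERS


@dataclass(frozen=True)
class PhaseCall:
    """Cis/trans configuration of two same-gene variants in one carrier."""

    sample_id: str
    gene: str
    variant_key_a: str
    variant_key_b: str
    phase: Phase


def unique_variant_keys(calls: Sequence[AnnotatedCall]) -> set[str]:
    return {c.variant_key for c in calls}
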