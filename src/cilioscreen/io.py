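"""Readers and writers for the pipeline's file formats.

Formats
-------
* Annotated variant table: UTF-8 TSV, one row per sample x variant, header
  row with exactly the :class:`~cilioscreen.model.AnnotatedCall` fields
  (tool predictions as one column per tool).  Missing optional values are
  empty cells.
* Pedigree: standard 6-column PED (family, individual, father, mother,
  sex, phenotype) with an optional 7th column flagging consanguineous
  unions, or a sidecar couples TSV.
* Gene panel: TSV with per-gene P/LP counts, prevalence and patient
  variant-type spectrum.
* Whitelist: TSV of known pathogenic alleles kept at any frequency.
* Cohort report: JSON (exact round-trip) or flat TSV of scalar metrics.

Optional VCF ingestion decomposes multi-allelic records into one call per
sample and alt allele, driven by a YAML key map from INFO/FORMAT keys to
call fields.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import yaml

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

PathLike = Union[str, Path]


class FormatError(ValueError):
    """The file does not conform to the expected schema."""


#: Column order of the annotated variant table.
VARIANT_TABLE_COLUMNS: tuple[str, ...] = (
    "sample_id", "gene", "chrom", "pos", "ref", "alt", "hgvs", "consequence",
    "maf", "cadd", "mcap", *PREDICTOR_TOOLS,
    "clinvar", "clinvar_limited_evidence", "hgmd", "vipur",
    "depth", "alt_fraction", "zygosity",
)


@dataclass(frozen=True)
class RejectedRow:
    row_number: int  # 1-based data row number (header not counted)
    reason: str


def _opt_float(value, row: int, name: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"row {row}: field {name}: {exc}") from exc


def _row_to_call(row: pd.Series, row_number: int) -> AnnotatedCall:
    def s(name: str) -> str:
        v = row[name]
        if pd.isna(v) or v == "":
            raise ValidationError(f"row {row_number}: field {name} is mandatory")
        return str(v)

    tool_calls = {}
    for tool in PREDICTOR_TOOLS:
        v = row[tool]
        tool_calls[tool] = (
            ToolPrediction.MISSING
            if (pd.isna(v) or v == "")
            else ToolPrediction(str(v))
        )
    limited = row["clinvar_limited_evidence"]
    limited = (not pd.isna(limited)) and str(limited).strip().lower() in {"1", "true", "yes"}
    clinvar = row["clinvar"]
    hgmd = row["hgmd"]
    hgvs = row["hgvs"]
    try:
        return AnnotatedCall(
            sample_id=s("sample_id"),
            gene=s("gene"),
            chrom=s("chrom"),
            pos=int(row["pos"]),
            ref=s("ref"),
            alt=s("alt"),
            consequence=Consequence(s("consequence")),
            maf=_opt_float(row["maf"], row_number, "maf"),
            cadd=_opt_float(row["cadd"], row_number, "cadd"),
            mcap=_opt_float(row["mcap"], row_number, "mcap"),
            tool_calls=tool_calls,
            clinvar=ClinVar.ABSENT if pd.isna(clinvar) or clinvar == "" else ClinVar(str(clinvar)),
            clinvar_limited_evidence=limited,
            hgmd=Hgmd.ABSENT if pd.isna(hgmd) or hgmd == "" else Hgmd(str(hgmd)),
            vipur=_opt_float(row["vipur"], row_number, "vipur"),
            depth=int(row["depth"]),
            alt_fraction=float(row["alt_fraction"]),
            zygosity=Zygosity(s("zygosity")),
            hgvs=None if pd.isna(hgvs) or hgvs == "" else str(hgvs),
        )
    except ValidationError as exc:
        raise ValidationError(f"row {row_number}: {exc}") from exc
    except ValueError as exc:
        raise ValidationError(f"row {row_number}: {exc}") from exc


def read_variant_table(
    path: PathLike,
    dialect: str = "tsv",
    errors: str = "raise",
    vcf_keymap: Optional[PathLike] = None,
) -> Union[list[AnnotatedCall], tuple[list[AnnotatedCall], list[RejectedRow]]]:
    """Read annotated calls from a TSV table or an annotated VCF.

    With ``errors="raise"`` (default) the first malformed row aborts the
    parse with its row number; with ``errors="collect"`` a pair
    ``(calls, rejected)`` is returned and every input row lands in exactly
    one of the two lists.
    """
    if dialect == "vcf":
        calls = read_vcf(path, keymap_path=vcf_keymap)
        return (calls, []) if errors == "collect" else calls
    if dialect != "tsv":
        raise ValueError(f"unknown dialect {dialect!r}")

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"variant table missing mandatory column(s): {missing}")

    calls: list[AnnotatedCall] = []
    rejected: list[RejectedRow] = []
    for i, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            calls.append(_row_to_call(row, i))
        except ValidationError as exc:
            if errors == "raise":
                raise
            rejected.append(RejectedRow(i, str(exc)))
    if errors == "collect":
        return calls, rejected
    return calls


def write_variant_table(calls: Iterable[AnnotatedCall], path: PathLike) -> None:
    rows = []
    for c in calls:
        row = {
            "sample_id": c.sample_id, "gene": c.gene, "chrom": c.chrom,
            "pos": c.pos, "ref": c.ref, "alt": c.alt,
            "hgvs": c.hgvs or "", "consequence": c.consequence.value,
            "maf": "" if c.maf is None else repr(c.maf),
            "cadd": "" if c.cadd is None else repr(c.cadd),
            "mcap": "" if c.mcap is None else repr(c.mcap),
            "clinvar": c.clinvar.value,
            "clinvar_limited_evidence": "1" if c.clinvar_limited_evidence else "0",
            "hgmd": c.hgmd.value,
            "vipur": "" if c.vipur is None else repr(c.vipur),
            "depth": c.depth, "alt_fraction": repr(c.alt_fraction),
            "zygosity": c.zygosity.value,
        }
        for tool in PREDICTOR_TOOLS:
            pred = c.tool_calls[tool]
            row[tool] = "" if pred is ToolPrediction.MISSING else pred.value
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(VARIANT_TABLE_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF ingestion

DEFAULT_VCF_KEYMAP = {
    "gene": "GENE",
    "consequence": "CSQ_CLASS",
    "maf": "GNOMAD_AF",
    "cadd": "CADD",
    "mcap": "MCAP",
    "clinvar": "CLNSIG",
    "clinvar_limited_evidence": "CLN_LIMITED",
    "hgmd": "HGMD",
    "vipur": "VIPUR",
    "tools": {t: t.upper() for t in PREDICTOR_TOOLS},
}


def read_vcf(path: PathLike, keymap_path: Optional[PathLike] = None) -> list[AnnotatedCall]:
    """Read an annotated VCF, one call per sample per alt allele.

    INFO keys are resolved through a YAML key map (defaults above); values
    for multi-allelic sites may be comma-separated per alt allele.  Depth
    and alt fraction come from FORMAT ``AD``/``DP`` when present.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    keymap = dict(DEFAULT_VCF_KEYMAP)
    if keymap_path is not None:
        with open(keymap_path) as fh:
            keymap.update(yaml.safe_load(fh) or {})

    def per_alt(value, alt_index: int, n_alts: int):
        if value is None:
            return None
        if isinstance(value, (tuple, list)):
            return value[alt_index] if alt_index < len(value) else None
        if isinstance(value, str) and n_alts > 1 and "," in value:
            parts = value.split(",")
            return parts[alt_index] if alt_index < len(parts) else None
        return value

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: list[AnnotatedCall] = []
    for record in vcf:
        n_alts = len(record.ALT)
        ad = record.format("AD")
        dp = record.format("DP")
        for ai, alt in enumerate(record.ALT):
            info = {
                f: per_alt(record.INFO.get(k), ai, n_alts)
                for f, k in keymap.items()
                if f != "tools"
            }
            tool_calls = {}
            for tool, key in keymap["tools"].items():
                raw = per_alt(record.INFO.get(key), ai, n_alts)
                tool_calls[tool] = (
                    ToolPrediction.MISSING if raw in (None, "", ".")
                    else ToolPrediction(str(raw))
                )
            for si, sample in enumerate(samples):
                gt = record.genotypes[si]
                alleles = [a for a in gt[:-1] if a is not None and a >= 0]
                n_alt_copies = sum(1 for a in alleles if a == ai + 1)
                if n_alt_copies == 0:
                    continue
                depth = int(dp[si][0]) if dp is not None else int(record.INFO.get("DP") or 0)
                if ad is not None:
                    alt_reads = int(ad[si][ai + 1])
                    total = max(int(sum(x for x in ad[si] if x >= 0)), 1)
                    alt_fraction = alt_reads / total
                else:
                    alt_fraction = 1.0 if n_alt_copies == 2 else 0.5
                cln = info.get("clinvar")
                hg = info.get("hgmd")
                calls.append(AnnotatedCall(
                    sample_id=sample,
                    gene=str(info.get("gene") or ""),
                    chrom=record.CHROM,
                    pos=record.POS,
                    ref=record.REF,
                    alt=alt,
                    consequence=Consequence(str(info.get("consequence") or "OTHER")),
                    maf=None if info.get("maf") in (None, "", ".") else float(info["maf"]),
                    cadd=None if info.get("cadd") in (None, "", ".") else float(info["cadd"]),
                    mcap=None if info.get("mcap") in (None, "", ".") else float(info["mcap"]),
                    tool_calls=tool_calls,
                    clinvar=ClinVar.ABSENT if cln in (None, "", ".") else ClinVar(str(cln)),
                    clinvar_limited_evidence=str(info.get("clinvar_limited_evidence") or "") in {"1", "true"},
                    hgmd=Hgmd.ABSENT if hg in (None, "", ".") else Hgmd(str(hg)),
                    vipur=None if info.get("vipur") in (None, "", ".") else float(info["vipur"]),
                    depth=depth,
                    alt_fraction=float(alt_fraction),
                    zygosity=Zygosity.HOM if n_alt_copies == 2 else Zygosity.HET,
                ))
    return calls


# ---------------------------------------------------------------------------
# Pedigree

def read_pedigree(
    path: PathLike, couples_sidecar: Optional[PathLike] = None
) -> PedigreeSet:
    """Read a PED file into a :class:`PedigreeSet`.

    Couples are the (father, mother) pairs sharing at least one child;
    the optional 7th PED column (or a sidecar TSV with columns
    ``partner_a, partner_b, consanguineous``) flags consanguineous unions
    and may declare additional childless couples.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"PED line has {len(parts)} columns, expected >= 6: {line!r}")
            rows.append(parts)

    individuals = [r[1] for r in rows]
    known = set(individuals)
    sex = {r[1]: {"1": "M", "2": "F"}.get(r[4], "U") for r in rows}
    consang_flag = {r[1]: (len(r) >= 7 and r[6] in {"1", "true", "yes"}) for r in rows}

    trios: list[Trio] = []
    couple_children: dict[tuple[str, str], list[str]] = {}
    for r in rows:
        child, father, mother = r[1], r[2], r[3]
        for parent in (father, mother):
            if parent != "0" and parent not in known:
                raise ValidationError(
                    f"individual {child} references unknown parent {parent}"
                )
        if father != "0" and mother != "0":
            trios.append(Trio(father, mother, child))
            couple_children.setdefault((father, mother), []).append(child)

    couples = [
        Couple(f, m, consanguineous=consang_flag.get(f, False) or consang_flag.get(m, False))
        for (f, m) in couple_children
    ]

    if couples_sidecar is not None:
        side = pd.read_csv(couples_sidecar, sep="\t", dtype=str)
        declared = {frozenset(c.members()) for c in couples}
        for _, row in side.iterrows():
            a, b = str(row["partner_a"]), str(row["partner_b"])
            cons = str(row.get("consanguineous", "0")).strip().lower() in {"1", "true", "yes"}
            key = frozenset((a, b))
            if key in declared:
                couples = [
                    Couple(c.partner_a, c.partner_b, cons) if frozenset(c.members()) == key else c
                    for c in couples
                ]
            else:
                couples.append(Couple(a, b, cons))
                declared.add(key)

    return PedigreeSet(individuals=individuals, couples=couples, trios=trios, sex=sex)


def write_pedigree(ped: PedigreeSet, path: PathLike) -> None:
    """Write a PedigreeSet as a 7-column PED (7th column = consanguinity)."""
    consang = {
        sid: c.consanguineous for c in ped.couples for sid in c.members()
    }
    child_of = {t.child_id: t for t in ped.trios}
    fam_of_couple = {frozenset(c.members()): f"F{i + 1:04d}" for i, c in enumerate(ped.couples)}
    with open(path, "w") as fh:
        for sid in ped.individuals:
            trio = child_of.get(sid)
            father = trio.father_id if trio else "0"
            mother = trio.mother_id if trio else "0"
            fam = "F0000"
            if trio:
                fam = fam_of_couple.get(frozenset((father, mother)), "F0000")
            else:
                for key, f in fam_of_couple.items():
                    if sid in key:
                        fam = f
                        break
            sex = {"M": "1", "F": "2"}.get(ped.sex.get(sid, "U"), "0")
            flag = "1" if consang.get(sid, False) else "0"
            fh.write(f"{fam}\t{sid}\t{father}\t{mother}\t{sex}\t0\t{flag}\n")


# ---------------------------------------------------------------------------
# Gene panel, whitelist, sample metrics

def read_gene_panel(path: PathLike) -> list[GenePanelEntry]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "n_missense_plp", "n_total_plp"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"gene panel missing column(s): {sorted(missing)}")
    entries = []
    for _, row in df.iterrows():
        def opt(name):
            if name not in df.columns or pd.isna(row[name]):
                return None
            return float(row[name])
        entries.append(GenePanelEntry(
            gene=str(row["gene"]),
            n_missense_plp=int(row["n_missense_plp"]),
            n_total_plp=int(row["n_total_plp"]),
            disease_prevalence=opt("prevalence"),
            spectrum_truncating=opt("spectrum_truncating"),
            spectrum_missense=opt("spectrum_missense"),
        ))
    return entries


def write_gene_panel(panel: Sequence[GenePanelEntry], path: PathLike) -> None:
    pd.DataFrame([
        {
            "gene": e.gene,
            "n_missense_plp": e.n_missense_plp,
            "n_total_plp": e.n_total_plp,
            "prevalence": e.disease_prevalence,
            "spectrum_truncating": e.spectrum_truncating,
            "spectrum_missense": e.spectrum_missense,
        }
        for e in panel
    ]).to_csv(path, sep="\t", index=False)


def read_whitelist(path: PathLike) -> list[WhitelistEntry]:
    entries = []
    seen = set()
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            e = WhitelistEntry(
                gene=row["gene"],
                variant_key=row["variant_key"],
                hgvs=row.get("hgvs") or None,
                rationale=row.get("rationale") or "",
            )
            key = (e.gene, e.variant_key)
            if key in seen:
                raise ValidationError(f"duplicate whitelist entry {key}")
            seen.add(key)
            entries.append(e)
    return entries


def write_whitelist(entries: Sequence[WhitelistEntry], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene", "variant_key", "hgvs", "rationale"])
        for e in entries:
            w.writerow([e.gene, e.variant_key, e.hgvs or "", e.rationale])


def read_sample_metrics(path: PathLike) -> list[SampleMetrics]:
    df = pd.read_csv(path, sep="\t")
    return [
        SampleMetrics(
            sample_id=str(r["sample_id"]),
            mean_coverage=float(r["mean_coverage"]),
            fraction_exome_at_depth=float(r["fraction_exome_at_depth"]),
        )
        for _, r in df.iterrows()
    ]


def write_sample_metrics(metrics: Sequence[SampleMetrics], path: PathLike) -> None:
    pd.DataFrame([
        {
            "sample_id": m.sample_id,
            "mean_coverage": m.mean_coverage,
            "fraction_exome_at_depth": m.fraction_exome_at_depth,
        }
        for m in metrics
    ]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Report serialization (the structure itself lives in cilioscreen.report)

def write_report(report, path: PathLike, format: str = "json") -> None:
    """Serialize a CohortReport; JSON round-trips exactly."""
    data = report.to_dict()
    if format == "json":
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
    elif format == "tsv":
        flat = _flatten("", data)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["metric", "value"])
            for k, v in flat:
                w.writerow([k, v])
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: PathLike):
    from .report import CohortReport

    with open(path) as fh:
        return CohortReport.from_dict(json.load(fh))


def _flatten(prefix: str, obj) -> list[tuple[str, object]]:
    out: list[tuple[str, object]] = []
    if isinstance(obj, dict):
        for k in sorted(obj):
            out.extend(_flatten(f"{prefix}{k}." if prefix else f"{k}.", obj[k])
                       if isinstance(obj[k], (dict, list))
                       else [(f"{prefix}{k}", obj[k])])
    elif isinstance(obj, list):
        for i, v in enumerate(obj):
            out.extend(_flatten(f"{prefix}{i}.", v) if isinstance(v, (dict, list))
                       else [(f"{prefix}{i}", v)])
    return out
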