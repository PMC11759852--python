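"""Variant catalog import, classification and truth-set validation.

This module turns ClinVar/gnomAD portal exports into uniform
:class:`VariantRecord` objects, assigns each record to one of the experiment
classes (VUS, PLP, BLB, POP_SYN, POP_MISSENSE, PTC_CTRL, OTHER), enumerates
premature-truncation (PTC) control SNVs inside a targeted interval, and
checks that the assembled catalog carries enough truth-set variants to
validate the assay:

* assay validation truth set — population synonymous variants (negative)
  vs. PTC stop-gains (positive);
* clinical truth set — ClinVar benign/likely-benign vs.
  pathogenic/likely-pathogenic missense variants.

Export dialects drift, so both parsers are keyed by a logical field map that
tolerates extra columns; the defaults match the portals' current downloads.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace

import pandas as pd

from .gene import GeneContext

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

CLASS_LABELS = ("VUS", "PLP", "BLB", "POP_MISSENSE", "POP_SYN", "PTC_CTRL", "OTHER")

#: default logical -> physical column names for a ClinVar per-gene TSV export
CLINVAR_FIELD_MAP = {
    "name": "Name",
    "significance": "Clinical significance (Last reviewed)",
    "location": "GRCh38Location",
    "spdi": "Canonical SPDI",
}

#: default logical -> physical column names for a gnomAD per-gene CSV export
GNOMAD_FIELD_MAP = {
    "chrom": "Chromosome",
    "pos": "Position",
    "ref": "Reference",
    "alt": "Alternate",
    "consequence": "VEP Annotation",
    "allele_count": "Allele Count",
}


class CatalogConfigError(ValueError):
    """A mapped column is missing from the export header."""


class CatalogParseError(ValueError):
    """A row cannot be parsed into the declared type."""


@dataclass
class VariantRecord:
    """One curated single-nucleotide variant.

    ``pos`` is 1-based on the plus strand of the target contig; ``ref`` and
    ``alt`` are plus-strand bases. ``class_label`` is a pure function of
    (source, consequence, significance_raw, allele_count, threshold) and is
    filled in by :func:`classify_variants`.
    """

    source: str  # clinvar | gnomad | designed
    contig: str
    pos: int
    ref: str
    alt: str
    consequence: str = "other"  # missense | synonymous | nonsense | other
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    significance_raw: str | None = None
    class_label: str = "OTHER"
    allele_count: int | None = None

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"ref/alt must be single bases, got {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.contig}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")
        if self.source == "gnomad" and self.allele_count is None:
            raise ValueError("gnomAD records require an allele count")

    @property
    def variant_id(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class Reject:
    row: int
    reason: str
    detail: str = ""


def write_rejects_csv(rejects: list[Reject], path) -> None:
    pd.DataFrame(
        [{"row": r.row, "reason": r.reason, "detail": r.detail} for r in rejects]
    ).to_csv(path, index=False)


# -- parsing ------------------------------------------------------------

_SPDI_RE = re.compile(r"^([^:]+):(\d+):([ACGTacgt]*):([ACGTacgt]*)$")
_HGVS_C_RE = re.compile(r"(c\.[^ )]+)")
_HGVS_P_RE = re.compile(r"\((p\.[^)]+)\)")


def _require_columns(df: pd.DataFrame, field_map: dict, logical: list[str], path) -> None:
    missing = [field_map[k] for k in logical if field_map[k] not in df.columns]
    if missing:
        raise CatalogConfigError(
            f"{path}: missing mapped column(s) {missing}; header has {list(df.columns)}"
        )


def _consequence_from_name(name: str) -> str:
    m = _HGVS_P_RE.search(name or "")
    if not m:
        return "missense"  # the export is pre-filtered to missense
    p = m.group(1)
    if "=" in p:
        return "synonymous"
    if "Ter" in p or "*" in p:
        return "nonsense"
    return "missense"


def parse_clinvar_export(
    path, field_map: dict | None = None
) -> tuple[list[VariantRecord], list[Reject]]:
    """Parse a ClinVar per-gene tabular (TSV) export.

    Returns (records, rejects). Only rows resolvable to a single-nucleotide
    substitution (via the canonical SPDI column) become records; everything
    else lands in the rejects list with a reason. The raw clinical
    significance string is preserved verbatim.
    """
    fmap = {**CLINVAR_FIELD_MAP, **(field_map or {})}
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except OSError as exc:
        raise OSError(f"cannot read ClinVar export {path}: {exc}") from exc
    _require_columns(df, fmap, ["name", "significance", "spdi"], path)

    records: list[VariantRecord] = []
    rejects: list[Reject] = []
    for i, row in df.iterrows():
        spdi = row.get(fmap["spdi"])
        name = row.get(fmap["name"]) or ""
        if not isinstance(spdi, str) or not (m := _SPDI_RE.match(spdi.strip())):
            rejects.append(Reject(int(i), "no_spdi", str(spdi)))
            continue
        contig, pos0, ref, alt = m.group(1), int(m.group(2)), m.group(3), m.group(4)
        if len(ref) != 1 or len(alt) != 1:
            rejects.append(Reject(int(i), "not_snv", spdi))
            continue
        hgvs_c = (m2.group(1) if (m2 := _HGVS_C_RE.search(name)) else None)
        hgvs_p = (m3.group(1) if (m3 := _HGVS_P_RE.search(name)) else None)
        records.append(
            VariantRecord(
                source="clinvar",
                contig=contig,
                pos=pos0 + 1,  # SPDI is 0-based
                ref=ref,
                alt=alt,
                consequence=_consequence_from_name(name),
                hgvs_c=hgvs_c,
                hgvs_p=hgvs_p,
                significance_raw=row.get(fmap["significance"]),
            )
        )
    return records, rejects


def _normalize_vep(term: str) -> str:
    t = (term or "").lower()
    if "missense" in t:
        return "missense"
    if "synonymous" in t:
        return "synonymous"
    if "stop_gained" in t or "stop gained" in t or "nonsense" in t:
        return "nonsense"
    return "other"


def parse_gnomad_export(
    path, field_map: dict | None = None
) -> tuple[list[VariantRecord], list[Reject]]:
    """Parse a gnomAD per-gene CSV export into records carrying allele counts."""
    fmap = {**GNOMAD_FIELD_MAP, **(field_map or {})}
    try:
        df = pd.read_csv(path, dtype=str)
    except OSError as exc:
        raise OSError(f"cannot read gnomAD export {path}: {exc}") from exc
    _require_columns(
        df, fmap, ["chrom", "pos", "ref", "alt", "consequence", "allele_count"], path
    )

    records: list[VariantRecord] = []
    rejects: list[Reject] = []
    for i, row in df.iterrows():
        ref, alt = str(row[fmap["ref"]]), str(row[fmap["alt"]])
        if len(ref) != 1 or len(alt) != 1 or ref.upper() not in VALID_BASES or alt.upper() not in VALID_BASES:
            rejects.append(Reject(int(i), "not_snv", f"{ref}>{alt}"))
            continue
        ac_raw = row[fmap["allele_count"]]
        try:
            ac = int(str(ac_raw))
        except (TypeError, ValueError):
            raise CatalogParseError(
                f"{path} row {i}: non-integer allele count {ac_raw!r}"
            ) from None
        records.append(
            VariantRecord(
                source="gnomad",
                contig=str(row[fmap["chrom"]]),
                pos=int(row[fmap["pos"]]),
                ref=ref,
                alt=alt,
                consequence=_normalize_vep(row[fmap["consequence"]]),
                allele_count=ac,
            )
        )
    return records, rejects


# -- classification -----------------------------------------------------

_PLP_TOKENS = {"pathogenic", "likely pathogenic"}
_BLB_TOKENS = {"benign", "likely benign"}


def _classify_significance(raw: str | None) -> str:
    """Map a ClinVar significance string to PLP/BLB/VUS/OTHER.

    Conservative on compounds: anything mentioning "conflicting", or mixing
    pathogenic/benign assertions with other terms, is OTHER.
    """
    if not raw:
        return "OTHER"
    s = re.sub(r"\(last reviewed.*?\)", "", raw.lower()).strip()
    if "conflicting" in s:
        return "OTHER"
    tokens = {t.strip() for part in s.split(",") for t in part.split("/") if t.strip()}
    if tokens and tokens <= _PLP_TOKENS:
        return "PLP"
    if tokens and tokens <= _BLB_TOKENS:
        return "BLB"
    if "uncertain significance" in tokens:
        return "VUS"
    return "OTHER"


def classify_one(rec: VariantRecord, ac_min: int) -> str:
    """Pure classification function; deterministic and case-insensitive."""
    if rec.source == "designed":
        return "PTC_CTRL" if rec.consequence == "nonsense" else "OTHER"
    if rec.source == "clinvar":
        if rec.consequence != "missense":
            return "OTHER"
        return _classify_significance(rec.significance_raw)
    if rec.source == "gnomad":
        if rec.allele_count is not None and rec.allele_count >= ac_min:
            if rec.consequence == "synonymous":
                return "POP_SYN"
            if rec.consequence == "missense":
                return "POP_MISSENSE"
        return "OTHER"
    return "OTHER"


def classify_variants(records: list[VariantRecord], ac_min: int = 5) -> list[VariantRecord]:
    """Return copies of ``records`` with ``class_label`` assigned.

    ``ac_min`` is the minimal gnomAD allele count for a variant to be used
    as a population control (inclusive boundary). Idempotent.
    """
    if ac_min < 1:
        raise ValueError(f"ac_min must be >= 1, got {ac_min}")
    return [replace(r, class_label=classify_one(r, ac_min)) for r in records]


# -- PTC control generation ---------------------------------------------


def generate_ptc_controls(
    ctx: GeneContext, interval: tuple[int, int]
) -> list[VariantRecord]:
    """Enumerate every SNV inside ``interval`` (0-based half-open, plus
    strand) whose edited codon becomes a stop in the transcript frame.

    The final codon of the last coding exon (the natural stop) is excluded.
    Returned ref/alt are plus-strand bases regardless of gene strand.
    """
    start, end = interval
    positions = [p for p in range(max(start, 0), min(end, len(ctx.sequence)))]
    coding = [p for p in positions if ctx.cds_index(p) is not None]
    if not coding:
        logger.warning("PTC interval (%d, %d) has no CDS overlap", start, end)
        return []
    out: list[VariantRecord] = []
    last_codon_start = ctx.cds_length - 3
    for p in coding:
        idx = ctx.cds_index(p)
        if idx >= last_codon_start:
            continue
        ref = ctx.sequence[p]
        for alt in "ACGT":
            if alt == ref:
                continue
            if ctx.consequence(p, alt) == "nonsense":
                out.append(
                    VariantRecord(
                        source="designed",
                        contig=ctx.contig_id,
                        pos=p + 1,
                        ref=ref,
                        alt=alt,
                        consequence="nonsense",
                        class_label="PTC_CTRL",
                    )
                )
    return out


# -- truth-set validation -----------------------------------------------


@dataclass
class TruthSetReport:
    """Tallies of truth-set classes and the pass/fail verdict."""

    n_syn: int
    n_ptc: int
    n_blb: int
    n_plp: int
    n_vus: int
    pass_: bool
    failures: list[str] = field(default_factory=list)

    @property
    def n_clinical(self) -> int:
        return self.n_blb + self.n_plp

    def to_dict(self) -> dict:
        return {
            "n_syn": self.n_syn,
            "n_ptc": self.n_ptc,
            "n_blb": self.n_blb,
            "n_plp": self.n_plp,
            "n_clinical": self.n_clinical,
            "n_vus": self.n_vus,
            "pass": self.pass_,
            "failures": list(self.failures),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        lines = [
            "Truth-set report",
            f"  synonymous (POP_SYN):        {self.n_syn}",
            f"  PTC controls (PTC_CTRL):     {self.n_ptc}",
            f"  clinical BLB:                {self.n_blb}",
            f"  clinical PLP:                {self.n_plp}",
            f"  clinical total:              {self.n_clinical}",
            f"  VUS:                         {self.n_vus}",
            f"  verdict: {'PASS' if self.pass_ else 'FAIL'}",
        ]
        lines += [f"    - {f}" for f in self.failures]
        return "\n".join(lines)


def validate_truth_sets(
    records: list[VariantRecord],
    min_syn: int = 20,
    min_ptc: int = 20,
    min_clinical: int = 25,
) -> TruthSetReport:
    """Check that the classified catalog supports both truth sets.

    Defaults reflect the recommended minimums of at least 20 synonymous and
    20 PTC assay-validation variants and 25 clinical (BLB+PLP) variants.
    """
    counts = {label: 0 for label in CLASS_LABELS}
    for r in records:
        counts[r.class_label] = counts.get(r.class_label, 0) + 1
    n_syn, n_ptc = counts["POP_SYN"], counts["PTC_CTRL"]
    n_blb, n_plp = counts["BLB"], counts["PLP"]
    failures = []
    if n_syn < min_syn:
        failures.append("insufficient_synonymous")
    if n_ptc < min_ptc:
        failures.append("insufficient_ptc")
    if n_blb + n_plp < min_clinical:
        failures.append("insufficient_clinical")
    return TruthSetReport(
        n_syn=n_syn,
        n_ptc=n_ptc,
        n_blb=n_blb,
        n_plp=n_plp,
        n_vus=counts["VUS"],
        pass_=not failures,
        failures=failures,
    )
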