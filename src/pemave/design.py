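"""epegRNA library design: spacers, editing windows, guides and oligos.

Geometry, briefly. SpCas9 binds a 20-nt protospacer next to an NGG PAM and
the prime-editor nickase cuts the PAM strand between protospacer bases 17
and 18 (3 nt 5' of the PAM). Reverse transcription extends the nicked
strand 3' of the nick using the pegRNA's RT template (RTT), so a variant is
reachable when it sits 1..max_edit_offset nt downstream of the nick on the
nicked strand. Each epegRNA is

    spacer + scaffold + RTT + PBS + tevopreQ1 motif

where the PBS anneals to the protospacer-strand bases immediately 5' of the
nick and the RTT encodes the intended substitution plus 3' homology.

Coordinates are 0-based half-open plus-strand throughout this module;
:class:`~pemave.catalogs.VariantRecord` positions are 1-based.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from . import constants as C
from .catalogs import VariantRecord
from .gene import GeneContext, revcomp

logger = logging.getLogger(__name__)

DESIGNABLE_CLASSES = ("VUS", "PLP", "BLB", "POP_SYN", "POP_MISSENSE", "PTC_CTRL")


class DesignRejection(ValueError):
    """A design cannot be produced for a stated reason."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass(frozen=True)
class DesignParams:
    """Tunable design parameters.

    The prime-editing geometry defaults (13-nt PBS, RTT = edit offset +
    10 nt of 3' homology, 30-nt maximum edit offset) follow common practice;
    the library cap of 60 and the 12-archetype minimum reflect the typical
    40-60 epegRNA library size and the recommended minimum number of
    archetypal epegRNAs to screen. The PE3 nicking-guide offset window of
    40-90 bp (preferring 60) brackets widely used reference designs.
    """

    pbs_len: int = 13
    rtt_3p_homology: int = 10
    max_edit_offset: int = 30
    library_cap: int = 60
    min_archetypes: int = 12
    ngrna_offset_range: tuple[int, int] = (40, 90)
    ngrna_offset_preferred: int = 60
    bsai_sites: tuple[str, ...] = C.BSAI_SITES
    scaffold_seq: str = C.SCAFFOLD_SEQ
    motif_seq: str = C.TEVOPREQ1_SEQ
    pool_tail_left: str = C.POOL_TAIL_LEFT
    pool_tail_right: str = C.POOL_TAIL_RIGHT

    def __post_init__(self) -> None:
        if not (8 <= self.pbs_len <= 17):
            raise ValueError(f"pbs_len must be in [8, 17], got {self.pbs_len}")
        if self.max_edit_offset < self.rtt_3p_homology:
            raise ValueError("max_edit_offset must be >= rtt_3p_homology")


@dataclass(frozen=True)
class SpacerSite:
    """A 20-nt protospacer adjacent to an NGG PAM.

    ``protospacer_start`` is the 0-based plus-strand coordinate of the
    leftmost protospacer base; ``nick_pos`` is the 0-based plus-strand
    coordinate of the first base 3' of the nick on the protospacer strand
    (edit offset +1), i.e. the nick falls between protospacer bases 17 and
    18, 3 nt 5' of the PAM.
    """

    strand: str
    protospacer: str
    pam: str
    protospacer_start: int
    nick_pos: int

    @property
    def site_id(self) -> str:
        return f"nick{self.nick_pos}{self.strand}"

    def edit_offset(self, pos: int) -> int:
        """1-based offset of plus-strand position ``pos`` downstream of the
        nick on the nicked strand (<= 0 means 5' of the nick)."""
        if self.strand == "+":
            return pos - self.nick_pos + 1
        return self.nick_pos - pos + 1

    def edit_interval(self, max_edit_offset: int) -> tuple[int, int]:
        """Plus-strand half-open interval reachable at offsets 1..max."""
        if self.strand == "+":
            return (self.nick_pos, self.nick_pos + max_edit_offset)
        return (self.nick_pos - max_edit_offset + 1, self.nick_pos + 1)


def enumerate_spacers(ctx: GeneContext, region: tuple[int, int]) -> list[SpacerSite]:
    """All NGG spacers (both strands) whose nick falls inside ``region``.

    ``region`` is 0-based half-open on the plus strand. Output is sorted by
    (nick_pos, strand) for reproducibility.
    """
    seq = ctx.sequence
    start, end = region
    if not (0 <= start <= end <= len(seq)):
        raise ValueError(f"region ({start}, {end}) outside sequence of length {len(seq)}")
    sites: list[SpacerSite] = []
    # plus strand: protospacer [p, p+20), PAM [p+20, p+23), nick base p+17
    for p in range(0, len(seq) - 23 + 1):
        if seq[p + 21] == "G" and seq[p + 22] == "G":
            nick = p + 17
            if start <= nick < end:
                sites.append(
                    SpacerSite("+", seq[p : p + 20], seq[p + 20 : p + 23], p, nick)
                )
    # minus strand: plus-strand CCN at [q, q+3), protospacer [q+3, q+23),
    # nick base (plus coords) q+5
    for q in range(0, len(seq) - 23 + 1):
        if seq[q] == "C" and seq[q + 1] == "C":
            nick = q + 5
            if start <= nick < end:
                sites.append(
                    SpacerSite(
                        "-",
                        revcomp(seq[q + 3 : q + 23]),
                        revcomp(seq[q : q + 3]),
                        q + 3,
                        nick,
                    )
                )
    sites.sort(key=lambda s: (s.nick_pos, s.strand))
    return sites


@dataclass
class EditingWindow:
    """One spacer plus the classified variants its RTT can reach."""

    spacer: SpacerSite
    edit_interval: tuple[int, int]
    variants: list[VariantRecord] = field(default_factory=list)

    @property
    def window_id(self) -> str:
        return self.spacer.site_id

    @property
    def tallies(self) -> Counter:
        return Counter(v.class_label for v in self.variants)


def build_windows(
    spacers: list[SpacerSite],
    variants: list[VariantRecord],
    params: DesignParams,
) -> list[EditingWindow]:
    """One window per spacer, holding every designable variant whose
    position lies within edit offsets 1..max_edit_offset of the nick."""
    windows = []
    eligible = [v for v in variants if v.class_label in DESIGNABLE_CLASSES]
    for sp in spacers:
        lo, hi = sp.edit_interval(params.max_edit_offset)
        inside = [v for v in eligible if lo <= v.pos - 1 < hi]
        inside.sort(key=lambda v: (v.pos, v.alt))
        windows.append(EditingWindow(spacer=sp, edit_interval=(lo, hi), variants=inside))
    return windows


_STRATEGY_CLASSES = {
    "vus": ("VUS",),
    "controls": ("PLP", "BLB"),
}


def _strategy_score(window: EditingWindow, strategy: str, covered: set[str]) -> int:
    classes = _STRATEGY_CLASSES[strategy]
    return sum(
        1
        for v in window.variants
        if v.class_label in classes and v.variant_id not in covered
    )


def _truncation_key(strategy: str):
    """Priority used when truncating a window's library to library_cap:
    strategy classes, then clinical controls, then POP/PTC controls, then
    the rest; position (then alt) breaks ties."""
    groups = {
        "vus": [("VUS",), ("PLP", "BLB"), ("POP_SYN", "POP_MISSENSE", "PTC_CTRL")],
        "controls": [("PLP", "BLB"), ("VUS",), ("POP_SYN", "POP_MISSENSE", "PTC_CTRL")],
    }[strategy]

    def key(v: VariantRecord):
        for rank, grp in enumerate(groups):
            if v.class_label in grp:
                return (rank, v.pos, v.alt)
        return (len(groups), v.pos, v.alt)

    return key


def select_windows(
    windows: list[EditingWindow],
    strategy: str,
    n_target: int,
    params: DesignParams,
) -> list[EditingWindow]:
    """Greedy window selection under one of the two design strategies.

    ``strategy="vus"`` maximizes newly covered VUS per pick (densest-VUS
    regions first); ``strategy="controls"`` maximizes newly covered clinical
    PLP/BLB controls. Ties break by the other strategy's score, then by the
    leftmost nick. Each selected window's variant list is truncated to
    ``params.library_cap`` by class priority.
    """
    if strategy not in _STRATEGY_CLASSES:
        raise ValueError(f"strategy must be one of {sorted(_STRATEGY_CLASSES)}")
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    other = "controls" if strategy == "vus" else "vus"
    covered: set[str] = set()
    remaining = list(windows)
    selected: list[EditingWindow] = []
    seen_spacers: set[str] = set()
    while remaining and len(selected) < n_target:
        best = min(
            remaining,
            key=lambda w: (
                -_strategy_score(w, strategy, covered),
                -_strategy_score(w, other, covered),
                w.spacer.nick_pos,
                w.spacer.strand,
            ),
        )
        remaining.remove(best)
        if best.spacer.protospacer in seen_spacers:
            continue
        seen_spacers.add(best.spacer.protospacer)
        kept = sorted(best.variants, key=_truncation_key(strategy))[: params.library_cap]
        kept.sort(key=lambda v: (v.pos, v.alt))
        selected.append(replace_window(best, kept))
        covered.update(v.variant_id for v in best.variants)
    if len(selected) < n_target:
        logger.warning(
            "only %d candidate windows available (requested %d)",
            len(selected),
            n_target,
        )
    return selected


def replace_window(window: EditingWindow, variants: list[VariantRecord]) -> EditingWindow:
    return EditingWindow(
        spacer=window.spacer, edit_interval=window.edit_interval, variants=variants
    )


# -- epegRNA construction -----------------------------------------------


@dataclass
class EpegRNADesign:
    """A fully assembled epegRNA for one variant plus its pool oligo."""

    window_id: str
    spacer: SpacerSite
    variant: VariantRecord
    spacer_seq: str
    scaffold_seq: str
    rtt_seq: str
    pbs_seq: str
    motif_seq: str
    flags: frozenset[str] = frozenset()

    @property
    def full_seq(self) -> str:
        return self.spacer_seq + self.scaffold_seq + self.rtt_seq + self.pbs_seq + self.motif_seq

    @property
    def design_id(self) -> str:
        return f"{self.variant.variant_id}@{self.window_id}"

    def pool_oligo_seq(self, params: DesignParams) -> str:
        return params.pool_tail_left + self.full_seq + params.pool_tail_right


_HOMOPOLYMER_RE = re.compile(r"(.)\1{4,}")


def design_epegrna(
    window: EditingWindow,
    variant: VariantRecord,
    params: DesignParams,
    ctx: GeneContext = None,
) -> EpegRNADesign:
    """Construct the epegRNA installing ``variant`` from ``window``'s spacer.

    The RTT is the reverse complement of the edited nicked-strand segment
    from the nick through (variant offset + rtt_3p_homology); the PBS is the
    reverse complement of the pbs_len protospacer-strand bases 5' of the
    nick. A leading G is prepended to the spacer for U6 expression when the
    protospacer does not already start with one. Problematic motifs
    (internal BsaI sites, >=5-nt homopolymers in the variable segment) are
    flagged, never silently repaired. Variants 5' of the nick (the PBS/seed
    side, unreachable by the RTT) raise :class:`DesignRejection`.
    """
    if ctx is None:
        raise TypeError("design_epegrna requires the GeneContext (ctx=...)")
    sp = window.spacer
    seq = ctx.sequence
    pos0 = variant.pos - 1
    off = sp.edit_offset(pos0)
    lo, hi = window.edit_interval
    if not (lo <= pos0 < hi):
        if off < 1:
            raise DesignRejection(
                "rtt_cannot_cover",
                f"{variant.variant_id} lies {1 - off} nt 5' of the nick (PBS/seed side)",
            )
        raise ValueError(
            f"variant {variant.variant_id} outside edit interval {window.edit_interval}"
        )
    if seq[pos0] != variant.ref:
        raise DesignRejection(
            "ref_mismatch",
            f"{variant.variant_id}: genome has {seq[pos0]} at {variant.pos}",
        )
    rtt_len = off + params.rtt_3p_homology
    nick = sp.nick_pos
    if sp.strand == "+":
        if nick + rtt_len > len(seq) or nick - params.pbs_len < 0:
            raise DesignRejection("sequence_edge", variant.variant_id)
        seg = seq[nick : nick + rtt_len]
        seg = seg[: off - 1] + variant.alt + seg[off:]
        rtt = revcomp(seg)
        pbs = revcomp(seq[nick - params.pbs_len : nick])
    else:
        if nick - rtt_len + 1 < 0 or nick + 1 + params.pbs_len > len(seq):
            raise DesignRejection("sequence_edge", variant.variant_id)
        # Plus-strand segment covered by the flap; the RTT read 5'->3' on the
        # pegRNA equals this segment with the substitution applied.
        seg = seq[nick - rtt_len + 1 : nick + 1]
        i = pos0 - (nick - rtt_len + 1)
        rtt = seg[:i] + variant.alt + seg[i + 1 :]
        pbs = seq[nick + 1 : nick + 1 + params.pbs_len]
    spacer_seq = sp.protospacer if sp.protospacer.startswith("G") else "G" + sp.protospacer
    variable = spacer_seq + rtt + pbs
    full = spacer_seq + params.scaffold_seq + rtt + pbs + params.motif_seq
    flags = set()
    if any(site in full for site in params.bsai_sites):
        flags.add("internal_bsai")
    if _HOMOPOLYMER_RE.search(variable):
        flags.add("homopolymer_ge5")
    return EpegRNADesign(
        window_id=window.window_id,
        spacer=sp,
        variant=variant,
        spacer_seq=spacer_seq,
        scaffold_seq=params.scaffold_seq,
        rtt_seq=rtt,
        pbs_seq=pbs,
        motif_seq=params.motif_seq,
        flags=frozenset(flags),
    )


def synthesize_flap(design: EpegRNADesign) -> str:
    """Plus-strand sequence the design's 3' flap installs over its footprint.

    For a plus-strand spacer the flap (nicked-strand 5'->3') is
    revcomp(RTT) and replaces [nick, nick+len) directly; for a minus-strand
    spacer the flap lands on the minus strand, so the plus-strand
    replacement is the RTT itself.
    """
    if design.spacer.strand == "+":
        return revcomp(design.rtt_seq)
    return design.rtt_seq


def flap_footprint(design: EpegRNADesign) -> tuple[int, int]:
    sp = design.spacer
    rtt_len = len(design.rtt_seq)
    if sp.strand == "+":
        return (sp.nick_pos, sp.nick_pos + rtt_len)
    return (sp.nick_pos - rtt_len + 1, sp.nick_pos + 1)


def design_to_dict(design: EpegRNADesign) -> dict:
    """JSON-serializable form of a design (inverse of design_from_dict)."""
    v, sp = design.variant, design.spacer
    return {
        "window_id": design.window_id,
        "variant": {
            "source": v.source,
            "contig": v.contig,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "consequence": v.consequence,
            "class_label": v.class_label,
            "allele_count": v.allele_count,
        },
        "spacer": {
            "strand": sp.strand,
            "protospacer": sp.protospacer,
            "pam": sp.pam,
            "protospacer_start": sp.protospacer_start,
            "nick_pos": sp.nick_pos,
        },
        "spacer_seq": design.spacer_seq,
        "scaffold_seq": design.scaffold_seq,
        "rtt_seq": design.rtt_seq,
        "pbs_seq": design.pbs_seq,
        "motif_seq": design.motif_seq,
        "flags": sorted(design.flags),
    }


def design_from_dict(d: dict) -> EpegRNADesign:
    return EpegRNADesign(
        window_id=d["window_id"],
        spacer=SpacerSite(**d["spacer"]),
        variant=VariantRecord(**d["variant"]),
        spacer_seq=d["spacer_seq"],
        scaffold_seq=d["scaffold_seq"],
        rtt_seq=d["rtt_seq"],
        pbs_seq=d["pbs_seq"],
        motif_seq=d["motif_seq"],
        flags=frozenset(d["flags"]),
    )


# -- nicking gRNAs ------------------------------------------------------


@dataclass(frozen=True)
class NickingGRNA:
    """PE3 nicking guide targeting the strand opposite the pegRNA nick."""

    spacer_seq: str
    strand: str
    nick_pos: int
    nick_offset: int
    top_oligo: str
    bottom_oligo: str


def nicking_oligos(spacer: str) -> tuple[str, str]:
    """Sticky-ended oligo pair for BsmBI/BbsI-style guide cloning.

    Top: 5'-CACCG-spacer-3' (the extra G is dropped when the spacer already
    starts with G); bottom: 5'-AAAC-revcomp(spacer)-C-3' (no trailing C in
    the native-G case). Annealing leaves CACC/AAAC 4-nt 5' overhangs.
    """
    if spacer.startswith("G"):
        return "CACC" + spacer, "AAAC" + revcomp(spacer)
    return "CACCG" + spacer, "AAAC" + revcomp(spacer) + "C"


def design_nicking(
    window: EditingWindow, ctx: GeneContext, params: DesignParams
) -> NickingGRNA:
    """Pick the PE3 nicking guide for a window.

    Candidates are opposite-strand NGG spacers whose nick-to-nick distance
    falls in ``params.ngrna_offset_range``; the winner is the candidate
    whose |offset| is closest to the preferred 60 bp (ties: smaller
    |offset|, then leftmost nick).
    """
    peg = window.spacer
    want_strand = "-" if peg.strand == "+" else "+"
    lo_r, hi_r = params.ngrna_offset_range
    scan = (
        max(0, peg.nick_pos - hi_r - 30),
        min(len(ctx.sequence), peg.nick_pos + hi_r + 30),
    )
    candidates = []
    for site in enumerate_spacers(ctx, scan):
        if site.strand != want_strand:
            continue
        offset = site.nick_pos - peg.nick_pos
        if lo_r <= abs(offset) <= hi_r:
            candidates.append((site, offset))
    if not candidates:
        raise DesignRejection("no_pe3_nick", window.window_id)
    pref = params.ngrna_offset_preferred
    site, offset = min(
        candidates,
        key=lambda so: (abs(abs(so[1]) - pref), abs(so[1]), so[0].nick_pos),
    )
    top, bottom = nicking_oligos(site.protospacer)
    return NickingGRNA(
        spacer_seq=site.protospacer,
        strand=site.strand,
        nick_pos=site.nick_pos,
        nick_offset=offset,
        top_oligo=top,
        bottom_oligo=bottom,
    )


# -- order sheets -------------------------------------------------------


@dataclass
class OrderSheets:
    """All oligo sheets for one design run (one DataFrame per oligo class)."""

    archetypes: pd.DataFrame
    opool: pd.DataFrame
    opool_rejects: pd.DataFrame
    pool_primers: pd.DataFrame
    nicking: pd.DataFrame
    ampseq_constants: pd.DataFrame

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name in (
            "archetypes",
            "opool",
            "opool_rejects",
            "pool_primers",
            "nicking",
            "ampseq_constants",
        ):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)


def emit_order_sheets(
    designs: list[EpegRNADesign],
    ngrnas: dict[str, NickingGRNA],
    params: DesignParams,
) -> OrderSheets:
    """Emit every sheet needed to order a library.

    oPool entries are the epegRNA cores flanked by the constant pool tails;
    designs flagged ``internal_bsai`` would be destroyed during Golden Gate
    assembly, so they are diverted to a rejects sheet. One archetypal
    epegRNA per window (the design whose edit sits closest to the nick) is
    emitted as annealable duplex parts. The amplicon-sequencing constants
    sheet carries the verbatim tevopreqPCR1 primer pair.
    """
    if not designs:
        raise ValueError("nothing to emit: empty design list")
    designs = sorted(designs, key=lambda d: (d.window_id, d.variant.pos, d.variant.alt))

    opool_rows, reject_rows = [], []
    for d in designs:
        row = {
            "name": d.design_id,
            "window": d.window_id,
            "sequence": d.pool_oligo_seq(params),
            "flags": ";".join(sorted(d.flags)),
        }
        (reject_rows if "internal_bsai" in d.flags else opool_rows).append(row)

    arch_rows = []
    by_window: dict[str, list[EpegRNADesign]] = {}
    for d in designs:
        by_window.setdefault(d.window_id, []).append(d)
    for window_id in sorted(by_window):
        arch = min(
            by_window[window_id],
            key=lambda d: (d.spacer.edit_offset(d.variant.pos - 1), d.variant.pos, d.variant.alt),
        )
        ext = arch.rtt_seq + arch.pbs_seq
        arch_rows.append(
            {
                "window": window_id,
                "variant": arch.variant.variant_id,
                "spacer_top": "CACC" + arch.spacer_seq,
                "spacer_bottom": "AAAC" + revcomp(arch.spacer_seq),
                "extension_top": ext,
                "extension_bottom": revcomp(ext),
                "scaffold_phosphorylated": params.scaffold_seq,
            }
        )

    nick_rows = [
        {
            "window": window_id,
            "spacer": ng.spacer_seq,
            "nick_offset": ng.nick_offset,
            "top_oligo": ng.top_oligo,
            "bottom_oligo": ng.bottom_oligo,
        }
        for window_id, ng in sorted(ngrnas.items())
    ]

    primer_rows = [
        {"name": "poolAmp_F", "sequence": params.pool_tail_left},
        {"name": "poolAmp_R", "sequence": revcomp(params.pool_tail_right)},
    ]
    ampseq_rows = [
        {"name": "tevopreqPCR1_ampSeqF", "sequence": C.TEVOPREQ_PCR1_AMPSEQ_F},
        {"name": "tevopreqPCR1_ampSeqR", "sequence": C.TEVOPREQ_PCR1_AMPSEQ_R},
        {"name": "illumina_tail_F", "sequence": C.ILLUMINA_TAIL_F},
        {"name": "illumina_tail_R", "sequence": C.ILLUMINA_TAIL_R},
    ]
    return OrderSheets(
        archetypes=pd.DataFrame(arch_rows),
        opool=pd.DataFrame(opool_rows, columns=["name", "window", "sequence", "flags"]),
        opool_rejects=pd.DataFrame(
            reject_rows, columns=["name", "window", "sequence", "flags"]
        ),
        pool_primers=pd.DataFrame(primer_rows),
        nicking=pd.DataFrame(
            nick_rows,
            columns=["window", "spacer", "nick_offset", "top_oligo", "bottom_oligo"],
        ),
        ampseq_constants=pd.DataFrame(ampseq_rows),
    )


def golden_gate_roundtrip(pool_oligo: str) -> str:
    """In-silico PCR (pool primers = tails) + BsaI digestion + ligation into
    the modeled acceptor. Returns the reconstructed top strand around the
    insert; raises if either BsaI site is absent."""
    li = pool_oligo.find("GGTCTC")
    ri = pool_oligo.rfind("GAGACC")
    if li < 0 or ri < 0 or ri <= li:
        raise ValueError("pool oligo lacks flanking BsaI sites")
    insert_top = pool_oligo[li + 7 : ri - 1 - 4]  # CACC + core
    right_overhang = pool_oligo[ri - 1 - 4 : ri - 1]
    if not insert_top.startswith(C.GG_LEFT_OVERHANG) or right_overhang != C.GG_RIGHT_OVERHANG:
        raise ValueError("unexpected Golden Gate overhangs")
    return C.ACCEPTOR_UPSTREAM + insert_top + right_overhang + C.ACCEPTOR_DOWNSTREAM


# -- amplicon and editing QC --------------------------------------------


@dataclass(frozen=True)
class AmpliconValidation:
    ok: bool
    reason: str | None
    length: int | None
    interval: tuple[int, int] | None


def _unique_site(seq: str, primer: str) -> tuple[str, int] | None:
    """Return (strand, plus-strand start) if the primer maps exactly once
    over both strands, else None."""
    fwd = [m.start() for m in re.finditer(re.escape(primer), seq)]
    rev = [m.start() for m in re.finditer(re.escape(revcomp(primer)), seq)]
    hits = [("+", p) for p in fwd] + [("-", p) for p in rev]
    if len(hits) != 1:
        return None
    return hits[0]


def validate_amplicon(
    fwd_primer: str,
    rev_primer: str,
    ctx: GeneContext,
    max_len: int = 250,
    edit_interval: tuple[int, int] | None = None,
) -> AmpliconValidation:
    """Check a candidate amplicon-sequencing primer pair.

    Accepts iff both primers map uniquely on opposite strands, converge,
    the amplicon is shorter than ``max_len`` (strict, per the <250 bp
    constraint), and neither primer overlaps ``edit_interval``.
    """
    seq = ctx.sequence
    fwd_primer, rev_primer = fwd_primer.upper(), rev_primer.upper()
    a = _unique_site(seq, fwd_primer)
    b = _unique_site(seq, rev_primer)
    if a is None or b is None:
        n_a = seq.count(fwd_primer) + seq.count(revcomp(fwd_primer))
        n_b = seq.count(rev_primer) + seq.count(revcomp(rev_primer))
        reason = "primer_not_found" if 0 in (n_a, n_b) else "primer_multimaps"
        return AmpliconValidation(False, reason, None, None)
    if {a[0], b[0]} != {"+", "-"}:
        return AmpliconValidation(False, "not_convergent", None, None)
    (plus_strand, plus_start) = a if a[0] == "+" else b
    plus_primer = fwd_primer if a[0] == "+" else rev_primer
    (minus_strand, minus_start) = b if b[0] == "-" else a
    minus_primer = rev_primer if b[0] == "-" else fwd_primer
    start = plus_start
    end = minus_start + len(minus_primer)
    if end <= start:
        return AmpliconValidation(False, "not_convergent", None, None)
    length = end - start
    if length >= max_len:
        return AmpliconValidation(False, "amplicon_too_long", length, (start, end))
    if edit_interval is not None:
        lo, hi = edit_interval
        for p_start, p_len in (
            (plus_start, len(plus_primer)),
            (minus_start, len(minus_primer)),
        ):
            if p_start < hi and lo < p_start + p_len:
                return AmpliconValidation(
                    False, "primer_overlaps_target", length, (start, end)
                )
    return AmpliconValidation(True, None, length, (start, end))


@dataclass(frozen=True)
class EditingQC:
    fraction_pct: float
    threshold_pct: float
    passed: bool


def qc_editing_fraction(
    edited: int, unedited: int, threshold_pct: float = 15.0
) -> EditingQC:
    """Archetype editing-efficiency check: pass iff edited/(edited+unedited)
    exceeds ``threshold_pct`` percent (strict > )."""
    if edited < 0 or unedited < 0:
        raise ValueError("counts must be non-negative")
    total = edited + unedited
    if total == 0:
        raise ValueError("editing fraction undefined: zero total reads")
    frac = 100.0 * edited / total
    return EditingQC(fraction_pct=frac, threshold_pct=threshold_pct, passed=frac > threshold_pct)


# -- library convenience ------------------------------------------------


@dataclass
class LibraryDesign:
    """Selected windows with their designed epegRNAs and nicking guides."""

    windows: list[EditingWindow]
    designs: dict[str, list[EpegRNADesign]]  # window_id -> designs
    ngrnas: dict[str, NickingGRNA]
    rejects: list[dict]

    @property
    def all_designs(self) -> list[EpegRNADesign]:
        return [d for w in self.windows for d in self.designs.get(w.window_id, [])]


def design_library(
    ctx: GeneContext,
    records: list[VariantRecord],
    params: DesignParams | None = None,
    strategy: str = "vus",
    n_target: int | None = None,
    region: tuple[int, int] | None = None,
) -> LibraryDesign:
    """End-to-end design: enumerate spacers over the CDS (or ``region``),
    build and select windows, and design every epegRNA and nicking guide.

    ``n_target`` defaults to ``params.min_archetypes`` so a default run
    yields one archetypal epegRNA per selected window, the recommended
    minimum to screen.
    """
    params = params or DesignParams()
    if n_target is None:
        n_target = params.min_archetypes
    if region is None:
        cds_span = (min(s for s, _ in ctx.cds), max(e for _, e in ctx.cds))
        region = cds_span
    spacers = enumerate_spacers(ctx, region)
    windows = build_windows(spacers, records, params)
    selected = select_windows(windows, strategy, n_target, params)
    designs: dict[str, list[EpegRNADesign]] = {}
    ngrnas: dict[str, NickingGRNA] = {}
    rejects: list[dict] = []
    for w in selected:
        lst = []
        for v in w.variants:
            try:
                lst.append(design_epegrna(w, v, params, ctx=ctx))
            except DesignRejection as exc:
                rejects.append(
                    {"window": w.window_id, "variant": v.variant_id, "reason": exc.reason}
                )
        designs[w.window_id] = lst
        try:
            ngrnas[w.window_id] = design_nicking(w, ctx, params)
        except DesignRejection as exc:
            rejects.append({"window": w.window_id, "variant": "", "reason": exc.reason})
    return LibraryDesign(windows=selected, designs=designs, ngrnas=ngrnas, rejects=rejects)
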