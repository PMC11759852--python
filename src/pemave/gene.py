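"""Gene/transcript model anchoring all genomic coordinates.

A :class:`GeneContext` couples a contig sequence with a single transcript
model (exons + CDS, either strand) and answers the two questions every other
stage asks: "what is the coding index of this genomic position?" and "what is
the protein-level consequence of this single-base substitution?".

Coordinates are 0-based half-open internally; file formats and variant
records use 1-based positions.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; '*' for stop."""
    return str(Seq(codon).translate())


@dataclass(frozen=True)
class GeneContext:
    """Target contig plus transcript model for one gene.

    Parameters
    ----------
    contig_id : str
        Name of the contig the sequence represents.
    sequence : str
        Full contig sequence (stored uppercase).
    gene_symbol, transcript_id : str
        Identity of the modeled gene/transcript.
    strand : {"+", "-"}
        Coding strand of the transcript.
    exons : tuple of (start, end)
        0-based half-open exon intervals, ascending and disjoint.
    cds : tuple of (start, end)
        0-based half-open coding intervals (subset of the exons);
        concatenated length must be divisible by 3.
    """

    contig_id: str
    sequence: str
    gene_symbol: str
    transcript_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "exons", tuple(tuple(iv) for iv in self.exons))
        object.__setattr__(self, "cds", tuple(tuple(iv) for iv in self.cds))
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for name, ivs in (("exons", self.exons), ("cds", self.cds)):
            prev_end = -1
            for s, e in ivs:
                if not (0 <= s < e <= len(self.sequence)):
                    raise ValueError(f"{name} interval ({s}, {e}) out of bounds")
                if s < prev_end:
                    raise ValueError(f"{name} intervals must be sorted and disjoint")
                prev_end = e
        cds_len = sum(e - s for s, e in self.cds)
        if cds_len % 3 != 0:
            raise ValueError(f"CDS length {cds_len} not divisible by 3")

    # -- coding-coordinate machinery ------------------------------------

    @functools.cached_property
    def _coding_positions(self) -> tuple[int, ...]:
        """Genomic positions of coding bases in transcript (5'->3') order."""
        pos: list[int] = []
        for s, e in self.cds:
            pos.extend(range(s, e))
        if self.strand == "-":
            pos.reverse()
        return tuple(pos)

    @functools.cached_property
    def _coding_index(self) -> dict[int, int]:
        return {p: i for i, p in enumerate(self._coding_positions)}

    @property
    def cds_length(self) -> int:
        return len(self._coding_positions)

    def cds_index(self, pos: int) -> int | None:
        """0-based index of genomic position ``pos`` within the coding
        sequence, or None if non-coding."""
        return self._coding_index.get(pos)

    def coding_base(self, pos: int) -> str:
        base = self.sequence[pos]
        return base if self.strand == "+" else base.translate(_COMPLEMENT)

    def spliced_cds(self, overrides: dict[int, str] | None = None) -> str:
        """Coding sequence 5'->3', optionally with plus-strand base
        substitutions applied at the given genomic positions."""
        seq = self.sequence
        if overrides:
            chars = list(seq)
            for p, b in overrides.items():
                chars[p] = b
            seq = "".join(chars)
        parts = [seq[s:e] for s, e in self.cds]
        cds = "".join(parts)
        return cds if self.strand == "+" else revcomp(cds)

    def codon_at(self, cds_idx: int, overrides: dict[int, str] | None = None) -> str:
        """Codon (coding-strand) containing coding index ``cds_idx``."""
        start = (cds_idx // 3) * 3
        bases = []
        for i in range(start, start + 3):
            p = self._coding_positions[i]
            b = self.sequence[p]
            if overrides and p in overrides:
                b = overrides[p]
            bases.append(b if self.strand == "+" else b.translate(_COMPLEMENT))
        return "".join(bases)

    def consequence(self, pos: int, alt: str) -> str:
        """Consequence of the plus-strand SNV ``pos``(0-based) ref>``alt``.

        Returns one of ``missense``, ``synonymous``, ``nonsense`` or
        ``other`` (non-coding position, stop-loss, or ref==alt).
        """
        idx = self.cds_index(pos)
        if idx is None:
            return "other"
        if self.sequence[pos] == alt.upper():
            return "other"
        wt = self.codon_at(idx)
        mut = self.codon_at(idx, overrides={pos: alt.upper()})
        if wt in STOP_CODONS:
            return "other"
        if mut in STOP_CODONS:
            return "nonsense"
        return "synonymous" if translate_codon(wt) == translate_codon(mut) else "missense"


# -- file loaders -------------------------------------------------------


def load_fasta(path) -> tuple[str, str]:
    """Read the first record of a FASTA file -> (id, sequence)."""
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return rec.id, str(rec.seq).upper()


def load_exon_table(path) -> tuple[str, tuple, tuple]:
    """Parse a simple tab-separated transcript model.

    Expected columns: ``feature`` (exon|CDS), ``start`` (1-based), ``end``
    (inclusive), ``strand``. Returns (strand, exons, cds) with 0-based
    half-open intervals.
    """
    import csv

    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    strand = "+"
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            iv = (int(row["start"]) - 1, int(row["end"]))
            strand = row.get("strand", "+") or "+"
            feat = row["feature"].strip().lower()
            if feat == "exon":
                exons.append(iv)
            elif feat == "cds":
                cds.append(iv)
    return strand, tuple(sorted(exons)), tuple(sorted(cds))


def load_gff3(path, transcript_id: str | None = None) -> tuple[str, tuple, tuple]:
    """Minimal GFF3 reader: collects exon/CDS features, optionally filtered
    to lines whose attributes mention ``transcript_id``."""
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    strand = "+"
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            _, _, feat, start, end, _, strd, _, attrs = parts[:9]
            if transcript_id and transcript_id not in attrs:
                continue
            iv = (int(start) - 1, int(end))
            if feat.lower() == "exon":
                exons.append(iv)
                strand = strd
            elif feat.upper() == "CDS":
                cds.append(iv)
                strand = strd
    return strand, tuple(sorted(exons)), tuple(sorted(cds))


def load_gene_context(
    fasta_path,
    model_path,
    gene_symbol: str = "GENE",
    transcript_id: str = "TX1",
) -> GeneContext:
    """Assemble a :class:`GeneContext` from a FASTA and a transcript model
    (GFF3 if the file extension says so, else the 4-column exon TSV)."""
    contig_id, seq = load_fasta(fasta_path)
    if str(model_path).endswith((".gff", ".gff3")):
        strand, exons, cds = load_gff3(model_path, transcript_id=None)
    else:
        strand, exons, cds = load_exon_table(model_path)
    return GeneContext(
        contig_id=contig_id,
        sequence=seq,
        gene_symbol=gene_symbol,
        transcript_id=transcript_id,
        strand=strand,
        exons=exons,
        cds=cds,
    )
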