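"""Variant-identifying k-mer dictionaries and dictionary-restricted counting.

Each designed variant is assigned one k-mer (default k=25, odd so no k-mer
is its own reverse complement) centered on the edited base, together with
the matching wild-type k-mer from the reference. Amplicon FASTQs are then
quantified by counting, at every read offset, windows equal to a dictionary
k-mer (or its reverse complement in canonical mode) — the dictionary-
restricted counting mode of Jellyfish. Windows containing N never match.

The counter encodes reads 2-bit and rolls a 64-bit k-mer code across each
read, so counting is vectorized over all reads of a file; a naive
sliding-window scan is kept in the test suite as the independent oracle.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import EpegRNADesign
from .gene import GeneContext, revcomp

logger = logging.getLogger(__name__)


class KmerCollisionError(ValueError):
    pass


class FastqFormatError(ValueError):
    pass


@dataclass(frozen=True)
class KmerEntry:
    """One dictionary entry: a variant k-mer or its wild-type counterpart."""

    name: str
    kmer: str
    window_id: str

    @property
    def is_wt(self) -> bool:
        return self.name.startswith("WT_")


def build_dictionary(
    designs: list[EpegRNADesign], ctx: GeneContext, k: int = 25
) -> list[KmerEntry]:
    """Build the variant/WT k-mer dictionary for a set of designs.

    The variant k-mer is the k-window centered on the edited base of the
    edited sequence (shifted minimally at a sequence edge); the WT k-mer is
    the same window on the reference. Identical WT windows are collapsed to
    one ``WT_<window>`` entry. Uniqueness — no entry equal to another entry
    or to the reverse complement of another entry — is enforced; collisions
    abort the build naming the offending variants.
    """
    if k % 2 == 0 or k < 3:
        raise ValueError(f"k must be odd and >= 3, got {k}")
    seq = ctx.sequence
    if len(seq) < k:
        raise ValueError("target sequence shorter than k")
    entries: list[KmerEntry] = []
    wt_seen: dict[str, str] = {}  # kmer -> entry name
    wt_per_window: dict[str, int] = {}
    half = k // 2
    done_variants: set[str] = set()
    for d in sorted(designs, key=lambda d: (d.window_id, d.variant.pos, d.variant.alt)):
        # a variant designed from several overlapping windows is counted once
        if d.variant.variant_id in done_variants:
            continue
        done_variants.add(d.variant.variant_id)
        pos0 = d.variant.pos - 1
        start = min(max(pos0 - half, 0), len(seq) - k)
        wt_kmer = seq[start : start + k]
        var_kmer = (
            wt_kmer[: pos0 - start] + d.variant.alt + wt_kmer[pos0 - start + 1 :]
        )
        entries.append(KmerEntry(d.variant.variant_id, var_kmer, d.window_id))
        if wt_kmer not in wt_seen:
            n = wt_per_window.get(d.window_id, 0)
            name = f"WT_{d.window_id}" if n == 0 else f"WT_{d.window_id}.{n}"
            wt_per_window[d.window_id] = n + 1
            wt_seen[wt_kmer] = name
            entries.append(KmerEntry(name, wt_kmer, d.window_id))

    by_kmer: dict[str, str] = {}
    collisions: list[tuple[str, str]] = []
    for e in entries:
        for key in (e.kmer, revcomp(e.kmer)):
            if key in by_kmer and by_kmer[key] != e.name:
                collisions.append((by_kmer[key], e.name))
            else:
                by_kmer.setdefault(key, e.name)
    if collisions:
        pairs = ", ".join(f"{a} <-> {b}" for a, b in sorted(set(collisions)))
        raise KmerCollisionError(f"indistinguishable k-mers: {pairs}")
    return entries


def write_dictionary_fasta(entries: list[KmerEntry], path) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f">{e.name} window={e.window_id}\n{e.kmer}\n")


def read_dictionary_fasta(path) -> list[KmerEntry]:
    entries = []
    name, window, seqparts = None, "", []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    entries.append(KmerEntry(name, "".join(seqparts), window))
                fields = line[1:].split()
                name = fields[0]
                window = next(
                    (f.split("=", 1)[1] for f in fields[1:] if f.startswith("window=")),
                    "",
                )
                seqparts = []
            else:
                seqparts.append(line.strip().upper())
    if name is not None:
        entries.append(KmerEntry(name, "".join(seqparts), window))
    ks = {len(e.kmer) for e in entries}
    if len(ks) > 1:
        raise ValueError(f"dictionary mixes k-mer lengths {sorted(ks)}")
    return entries


# -- FASTQ reading ------------------------------------------------------


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq_seqs(path):
    """Yield read sequences from a (optionally gzipped) FASTQ file,
    validating the 4-line record structure."""
    with _open_text(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not header.startswith("@") or not plus.startswith("+") or not qual:
                raise FastqFormatError(f"{path}: malformed FASTQ record {idx}")
            seq = seq.strip()
            if len(qual.strip()) != len(seq):
                raise FastqFormatError(f"{path}: malformed FASTQ record {idx}")
            yield seq
            idx += 1


# -- counting -----------------------------------------------------------

_ENCODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _ENCODE[b] = i
    _ENCODE[b + 32] = i  # lowercase


def _encode_kmer(kmer: str) -> int:
    code = 0
    for ch in kmer.upper():
        v = _ENCODE[ord(ch)]
        if v > 3:
            raise ValueError(f"non-ACGT base in k-mer {kmer!r}")
        code = (code << 2) | int(v)
    return code


def _lookup_tables(entries: list[KmerEntry], canonical: bool):
    codes, idxs = [], []
    for i, e in enumerate(entries):
        codes.append(_encode_kmer(e.kmer))
        idxs.append(i)
        if canonical:
            rc = revcomp(e.kmer)
            if rc != e.kmer:
                codes.append(_encode_kmer(rc))
                idxs.append(i)
    codes = np.asarray(codes, dtype=np.int64)
    idxs = np.asarray(idxs, dtype=np.int64)
    order = np.argsort(codes)
    return codes[order], idxs[order]


@dataclass
class FileCounts:
    """Dictionary-restricted counts for one FASTQ file."""

    path: str
    counts: dict[str, int]
    total_reads: int


def count_kmers(
    fastq_paths,
    entries: list[KmerEntry],
    canonical: bool = True,
) -> list[FileCounts]:
    """Count dictionary k-mers in one or more FASTQ files.

    Occurrences are counted at every read offset (Jellyfish semantics); in
    canonical mode a window matches an entry if it equals the entry's k-mer
    or its reverse complement. Returns one :class:`FileCounts` per file.
    """
    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    if not entries:
        raise ValueError("empty dictionary")
    k = len(entries[0].kmer)
    if any(len(e.kmer) != k for e in entries):
        raise ValueError("dictionary mixes k-mer lengths")
    sorted_codes, code_idx = _lookup_tables(entries, canonical)

    results = []
    for path in fastq_paths:
        per_entry = np.zeros(len(entries), dtype=np.int64)
        total = 0
        # group reads by length so each batch is a rectangular byte matrix
        by_len: dict[int, list[bytes]] = {}
        for seq in iter_fastq_seqs(path):
            total += 1
            by_len.setdefault(len(seq), []).append(seq.encode())
        for L, reads in by_len.items():
            if L < k:
                continue
            mat = _ENCODE[
                np.frombuffer(b"".join(reads), dtype=np.uint8).reshape(len(reads), L)
            ]
            per_entry += _count_matrix(mat, k, sorted_codes, code_idx, len(entries))
        results.append(
            FileCounts(
                path=str(path),
                counts={e.name: int(c) for e, c in zip(entries, per_entry)},
                total_reads=total,
            )
        )
    return results


def _count_matrix(mat, k, sorted_codes, code_idx, n_entries):
    """Roll k-mer codes across a (reads x L) base-code matrix and tally
    matches against the sorted dictionary codes.

    Works column-by-column so peak memory stays at a few read-count-sized
    vectors regardless of read length.
    """
    n, L = mat.shape
    n_win = L - k + 1
    has_invalid = bool((mat > 3).any())
    if has_invalid:
        base = np.where(mat > 3, np.uint8(0), mat)
        # windows containing any invalid base are masked via a cumsum trick
        bad_cs = np.zeros((n, L + 1), dtype=np.int32)
        np.cumsum(mat > 3, axis=1, out=bad_cs[:, 1:])
    else:
        base = mat

    mask = (1 << (2 * (k - 1))) - 1
    code = np.zeros(n, dtype=np.int64)
    for j in range(k):
        code = (code << 2) | base[:, j]
    counts = np.zeros(n_entries, dtype=np.int64)
    top = len(sorted_codes) - 1
    for j in range(n_win):
        if j > 0:
            code = ((code & mask) << 2) | base[:, j + k - 1]
        pos = np.searchsorted(sorted_codes, code)
        np.minimum(pos, top, out=pos)
        hit = sorted_codes[pos] == code
        if has_invalid:
            hit &= (bad_cs[:, j + k] - bad_cs[:, j]) == 0
        if hit.any():
            counts += np.bincount(code_idx[pos[hit]], minlength=n_entries)
    return counts


# -- table assembly and annotation --------------------------------------


@dataclass
class SampleFiles:
    """One sequencing sample: condition, replicate and its mate files."""

    sample_id: str
    condition: str  # control | selected
    replicate: int
    r1: str | Path
    r2: str | Path | None = None


@dataclass
class CountTable:
    """Variant-level counts in the analysis layout: one row per dictionary
    entry, one ``counts_<condition>_rep<N>`` column per sample, plus the
    per-sample sequencing depth."""

    df: pd.DataFrame  # index: variant name; columns: counts_{cond}_rep{N}
    totals: dict[str, int]  # column name -> total reads
    dropped_kmers: int = 0

    def column(self, condition: str, replicate: int) -> str:
        return f"counts_{condition}_rep{replicate}"

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "variant", out.index)
        out.to_csv(path, index=False)
        totals_path = str(path) + ".totals.json"
        import json

        with open(totals_path, "w") as fh:
            json.dump(self.totals, fh, indent=2, sort_keys=True)

    @classmethod
    def from_csv(cls, path) -> "CountTable":
        df = pd.read_csv(path)
        df = df.set_index("variant")
        import json, os

        totals_path = str(path) + ".totals.json"
        if os.path.exists(totals_path):
            with open(totals_path) as fh:
                totals = {k: int(v) for k, v in json.load(fh).items()}
        else:
            logger.warning(
                "%s: no totals sidecar; using column sums as sequencing depth", path
            )
            totals = {c: int(df[c].sum()) for c in df.columns}
        return cls(df=df, totals=totals)


def counts_to_table(
    samples: list[SampleFiles],
    entries: list[KmerEntry],
    canonical: bool = True,
) -> CountTable:
    """Count each sample's mate files and merge into a variant count table.

    Mate counts are summed (R1 + R2) and the sample total is the summed
    read count of both files; a missing mate triggers a warning and the
    sample proceeds single-end. Entries absent from every read keep a zero
    row.
    """
    names = [e.name for e in entries]
    data: dict[str, list[int]] = {}
    totals: dict[str, int] = {}
    for s in samples:
        files = [s.r1]
        if s.r2 is not None:
            files.append(s.r2)
        else:
            logger.warning("sample %s missing mate file; proceeding single-end", s.sample_id)
        per_file = count_kmers(files, entries, canonical=canonical)
        col = f"counts_{s.condition}_rep{s.replicate}"
        merged = np.zeros(len(names), dtype=np.int64)
        total = 0
        for fc in per_file:
            merged += np.array([fc.counts[n] for n in names], dtype=np.int64)
            total += fc.total_reads
        data[col] = merged.tolist()
        totals[col] = total
    df = pd.DataFrame(data, index=pd.Index(names, name="variant"))
    return CountTable(df=df, totals=totals)


def annotate_kmer_counts(
    kmer_counts: pd.DataFrame,
    entries: list[KmerEntry],
    revcomp_merge: bool = False,
) -> tuple[pd.DataFrame, int]:
    """Annotate a raw (kmer, count) table with variant names.

    ``revcomp_merge=True`` additionally matches the reverse complement of
    each input k-mer against the dictionary (for dumps produced on the
    opposite strand). Unknown k-mers are dropped; their number is returned.
    """
    lookup = {e.kmer: e.name for e in entries}
    rows, dropped = [], 0
    for _, row in kmer_counts.iterrows():
        kmer = str(row["kmer"]).upper()
        name = lookup.get(kmer)
        if name is None and revcomp_merge:
            name = lookup.get(revcomp(kmer))
        if name is None:
            dropped += 1
            continue
        rows.append({"variant": name, "count": int(row["count"])})
    out = pd.DataFrame(rows, columns=["variant", "count"])
    if not out.empty:
        out = out.groupby("variant", as_index=False)["count"].sum()
    return out, dropped


# -- depth QC -----------------------------------------------------------


def depth_qc(table: CountTable, min_reads: int = 200_000) -> pd.DataFrame:
    """Flag samples below the minimum sequencing depth (default 200,000
    reads per amplicon library; the boundary itself passes)."""
    rows = []
    for col, total in sorted(table.totals.items()):
        rows.append(
            {
                "sample": col,
                "total_reads": total,
                "min_reads": min_reads,
                "shortfall": max(0, min_reads - total),
                "pass": total >= min_reads,
            }
        )
    return pd.DataFrame(rows)
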