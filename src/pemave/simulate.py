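"""Synthetic study generator: gene, variant catalogs, pools and reads.

The generator emulates the full input side of a curated prime-editing MAVE
so the pipeline can be exercised and validated end to end:

* a synthetic gene (4 exons, clean ORF) with two variant hotspots placed
  immediately downstream of planted NGG PAMs so each hotspot is exactly one
  editing window;
* ClinVar-style TSV and gnomAD-style CSV catalogs whose SNVs carry true
  consequences (computed from the synthetic transcript model) and class
  labels via significance strings / allele counts;
* per-variant editing outcomes — all-or-none dropout (default 33%, the
  aggregate dropout rate typically observed), right-skewed editing
  efficiency (Beta(2,6), mean 0.25), and multiplicative class fitness under
  depletion-type selection (loss-of-function classes at 0.2);
* paired-end 2x150 amplicon reads drawn multinomially from the pool allele
  fractions with uniform per-base substitution error.

Hotspot codons come from a fixed stop-codon-adjacent pool so that the
catalogs always satisfy the truth-set minimums (>=20 synonymous, >=20 PTC,
>=25 clinical) at the default class counts.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqUtils import seq3

from .design import EpegRNADesign
from .gene import GeneContext, STOP_CODONS, revcomp, translate_codon

SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

# 10 codons per hotspot; position 1 (0-based) is pinned to TGG, whose GG
# provides the NGG PAM that makes the hotspot one editing window. The pool
# is rich in stop-adjacent and 4-fold-degenerate codons so every hotspot
# yields 18 synonymous and 18 stop-gain SNVs.
_HOTSPOT_POOL = ("TCA", "TCA", "TCA", "TCA", "TAC", "TTA", "GAA", "TAT", "AAG")
HOTSPOT_CODONS = 10
HOTSPOT_LEN = 3 * HOTSPOT_CODONS


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic experiment.

    Defaults encode the conditions the pipeline is validated under:
    ~33% all-or-none variant dropout, Beta(2,6) editing efficiency,
    neutral fitness 1.0 with loss-of-function (PTC/PLP) fitness 0.2 under
    depletion selection, 3 biological replicates, 300,000 reads per
    amplicon library at 2x150 bp with 0.1% per-base error.
    """

    seed: int = 0
    gene_len: int = 3000
    n_exons: int = 4
    n_per_class: dict = field(
        default_factory=lambda: {
            "VUS": 40,
            "PLP": 15,
            "BLB": 15,
            "POP_SYN": 25,
            "POP_MISSENSE": 10,
        }
    )
    min_ptc: int = 20
    ac_min: int = 5
    editing_eff_beta: tuple[float, float] = (2.0, 6.0)
    dropout_prob: float = 0.33
    fitness: dict = field(
        default_factory=lambda: {"PTC_CTRL": 0.2, "PLP": 0.2}
    )  # classes absent from the map are neutral (1.0)
    edited_cell_fraction: float = 0.3
    depth: int = 300_000  # total reads per sample (R1 + R2)
    read_len: int = 150
    error_rate: float = 0.001
    replicates: int = 3
    amplicon_len: int = 240
    gene_symbol: str = "SYNGENE1"
    contig_id: str = "synth_contig_1"

    def __post_init__(self) -> None:
        for name, p in (
            ("dropout_prob", self.dropout_prob),
            ("error_rate", self.error_rate),
            ("edited_cell_fraction", self.edited_cell_fraction),
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def class_fitness(self, label: str) -> float:
        return float(self.fitness.get(label, 1.0))


# -- locus generation ---------------------------------------------------


@dataclass
class SyntheticLocus:
    """Everything :func:`make_synthetic_locus` produced."""

    ctx: GeneContext
    clinvar: pd.DataFrame
    gnomad: pd.DataFrame
    hotspots: list[tuple[int, int]]

    def write(self, outdir) -> dict[str, Path]:
        """Write FASTA / exon TSV / ClinVar TSV / gnomAD CSV; deterministic
        bytes for a fixed configuration."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "gene.fasta",
            "exons": out / "exons.tsv",
            "clinvar": out / "clinvar.tsv",
            "gnomad": out / "gnomad.csv",
        }
        with open(paths["fasta"], "w") as fh:
            fh.write(f">{self.ctx.contig_id}\n")
            seq = self.ctx.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
        with open(paths["exons"], "w") as fh:
            fh.write("feature\tstart\tend\tstrand\n")
            for s, e in self.ctx.exons:
                fh.write(f"exon\t{s + 1}\t{e}\t{self.ctx.strand}\n")
            for s, e in self.ctx.cds:
                fh.write(f"CDS\t{s + 1}\t{e}\t{self.ctx.strand}\n")
        self.clinvar.to_csv(paths["clinvar"], sep="\t", index=False)
        self.gnomad.to_csv(paths["gnomad"], index=False)
        return paths


def _split_counts(total: int, n_bins: int) -> list[int]:
    base, extra = divmod(total, n_bins)
    return [base + (1 if i < extra else 0) for i in range(n_bins)]


def make_synthetic_locus(config: SimulationConfig) -> SyntheticLocus:
    """Generate the synthetic gene and its variant catalogs.

    The CDS translates without internal stops; each hotspot sits 1 nt
    downstream of a planted spacer nick so a single editing window covers
    all of its variants. All catalog SNV ref bases match the genome and all
    rows parse through the catalog module with zero rejects.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA11E1E]))
    flank = max(100, config.gene_len // 20)
    n_ex = config.n_exons
    # exon lengths: multiples of 3 so every exon starts on a codon boundary
    avail = config.gene_len - 2 * flank
    exon_total = (avail // 2) // 3 * 3
    exon_lens = [v // 3 * 3 for v in _split_counts(exon_total, n_ex)]
    intron_total = avail - sum(exon_lens)
    intron_lens = _split_counts(intron_total, n_ex - 1)

    exons = []
    pos = flank
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        pos += el
        if i < n_ex - 1:
            pos += intron_lens[i]
    seq_len = pos + flank

    bases = np.array(list("ACGT"))
    chars = rng.choice(bases, size=seq_len).tolist()
    # fill coding positions codon-wise with sense codons
    codons = rng.choice(np.array(SENSE_CODONS), size=sum(exon_lens) // 3)
    cds_positions = [p for s, e in exons for p in range(s, e)]
    flat = "".join(codons)
    for p, b in zip(cds_positions, flat):
        chars[p] = b

    # hotspots: middle exons if available, else the first exons
    hotspot_exons = [min(1, n_ex - 1), min(2, n_ex - 1)]
    if hotspot_exons[0] == hotspot_exons[1]:
        raise ValueError("need at least 2 exons for 2 hotspots")
    hotspots: list[tuple[int, int]] = []
    for ex_i in hotspot_exons:
        s, e = exons[ex_i]
        if e - s < HOTSPOT_LEN + 120:
            raise ValueError(f"exon {ex_i} too short for a hotspot")
        h = s + ((e - s) // 2 // 3) * 3 - HOTSPOT_LEN // 2
        h = s + ((h - s) // 3) * 3  # codon aligned within exon
        pool = list(_HOTSPOT_POOL)
        rng.shuffle(pool)
        codons_h = [pool[0], "TGG"] + pool[1:]
        for ci, codon in enumerate(codons_h):
            for bi, b in enumerate(codon):
                chars[h + 3 * ci + bi] = b
        hotspots.append((h, h + HOTSPOT_LEN))

    sequence = "".join(chars)
    ctx = GeneContext(
        contig_id=config.contig_id,
        sequence=sequence,
        gene_symbol=config.gene_symbol,
        transcript_id=f"NM_{config.gene_symbol}.1",
        strand="+",
        exons=tuple(exons),
        cds=tuple(exons),
    )

    # candidate SNVs per hotspot, by true consequence
    per_hotspot: list[dict[str, list[tuple[int, str]]]] = []
    n_stop_total = 0
    for (hs, he) in hotspots:
        cand = {"synonymous": [], "missense": [], "nonsense": []}
        for p in range(hs, he):
            for alt in "ACGT":
                if alt == sequence[p]:
                    continue
                cons = ctx.consequence(p, alt)
                if cons in cand:
                    cand[cons].append((p, alt))
        n_stop_total += len(cand["nonsense"])
        per_hotspot.append(cand)
    if n_stop_total < config.min_ptc:
        raise RuntimeError(
            f"hotspots yield only {n_stop_total} PTC opportunities (<{config.min_ptc})"
        )

    # assign catalog classes, split evenly across hotspots
    clinvar_rows, gnomad_rows = [], []
    class_split = {
        label: _split_counts(n, len(hotspots)) for label, n in config.n_per_class.items()
    }
    sig_pool = {
        "VUS": ["Uncertain significance"],
        "PLP": ["Pathogenic", "Likely pathogenic", "Pathogenic/Likely pathogenic"],
        "BLB": ["Benign", "Likely benign", "Benign/Likely benign"],
    }
    for hi, cand in enumerate(per_hotspot):
        syn = list(cand["synonymous"])
        mis = list(cand["missense"])
        rng.shuffle(syn)
        rng.shuffle(mis)
        need_syn = class_split.get("POP_SYN", [0, 0])[hi]
        need_mis = sum(
            class_split[lbl][hi] for lbl in ("VUS", "PLP", "BLB", "POP_MISSENSE")
        )
        if len(syn) < need_syn or len(mis) < need_mis:
            raise RuntimeError(
                f"hotspot {hi}: insufficient candidates "
                f"(syn {len(syn)}/{need_syn}, mis {len(mis)}/{need_mis})"
            )
        take_syn = syn[:need_syn]
        i = 0
        for label in ("VUS", "PLP", "BLB", "POP_MISSENSE"):
            for _ in range(class_split[label][hi]):
                p, alt = mis[i]
                i += 1
                if label == "POP_MISSENSE":
                    gnomad_rows.append(
                        _gnomad_row(ctx, p, alt, "missense_variant", config, rng)
                    )
                else:
                    sig = str(rng.choice(sig_pool[label]))
                    if rng.random() < 0.5:
                        sig += "(Last reviewed: Jan 2, 2024)"
                    clinvar_rows.append(_clinvar_row(ctx, p, alt, sig))
        for p, alt in take_syn:
            gnomad_rows.append(
                _gnomad_row(ctx, p, alt, "synonymous_variant", config, rng)
            )
        # a couple of below-threshold gnomAD rows to exercise the AC filter
        for p, alt in mis[i : i + 2]:
            gnomad_rows.append(
                _gnomad_row(
                    ctx, p, alt, "missense_variant", config, rng,
                    allele_count=int(rng.integers(1, config.ac_min)),
                )
            )

    clinvar = pd.DataFrame(
        clinvar_rows,
        columns=[
            "Name",
            "Gene(s)",
            "Protein change",
            "Condition(s)",
            "Clinical significance (Last reviewed)",
            "Review status",
            "Chromosome",
            "GRCh38Location",
            "Canonical SPDI",
        ],
    ).sort_values("GRCh38Location", kind="stable").reset_index(drop=True)
    gnomad = pd.DataFrame(
        gnomad_rows,
        columns=[
            "Chromosome",
            "Position",
            "rsIDs",
            "Reference",
            "Alternate",
            "VEP Annotation",
            "HGVS Consequence",
            "Allele Count",
            "Allele Number",
            "Allele Frequency",
        ],
    ).sort_values(["Position", "Alternate"], kind="stable").reset_index(drop=True)
    return SyntheticLocus(ctx=ctx, clinvar=clinvar, gnomad=gnomad, hotspots=hotspots)


def _hgvs_parts(ctx: GeneContext, p: int, alt: str) -> tuple[str, str]:
    idx = ctx.cds_index(p)
    wt_codon = ctx.codon_at(idx)
    mut_codon = ctx.codon_at(idx, overrides={p: alt})
    aa_wt = translate_codon(wt_codon)
    aa_mut = translate_codon(mut_codon)
    aa_pos = idx // 3 + 1
    cref = ctx.coding_base(p)
    calt = alt if ctx.strand == "+" else revcomp(alt)
    hgvs_c = f"c.{idx + 1}{cref}>{calt}"
    if aa_mut == "*":
        hgvs_p = f"p.{seq3(aa_wt)}{aa_pos}Ter"
    elif aa_wt == aa_mut:
        hgvs_p = f"p.{seq3(aa_wt)}{aa_pos}="
    else:
        hgvs_p = f"p.{seq3(aa_wt)}{aa_pos}{seq3(aa_mut)}"
    return hgvs_c, hgvs_p


def _clinvar_row(ctx: GeneContext, p: int, alt: str, sig: str) -> dict:
    hgvs_c, hgvs_p = _hgvs_parts(ctx, p, alt)
    ref = ctx.sequence[p]
    return {
        "Name": f"{ctx.transcript_id}({ctx.gene_symbol}):{hgvs_c} ({hgvs_p})",
        "Gene(s)": ctx.gene_symbol,
        "Protein change": hgvs_p.replace("p.", ""),
        "Condition(s)": "Synthetic condition",
        "Clinical significance (Last reviewed)": sig,
        "Review status": "criteria provided, single submitter",
        "Chromosome": ctx.contig_id,
        "GRCh38Location": p + 1,
        "Canonical SPDI": f"{ctx.contig_id}:{p}:{ref}:{alt}",
    }


def _gnomad_row(
    ctx: GeneContext,
    p: int,
    alt: str,
    vep: str,
    config: SimulationConfig,
    rng,
    allele_count: int | None = None,
) -> dict:
    hgvs_c, hgvs_p = _hgvs_parts(ctx, p, alt)
    ac = (
        allele_count
        if allele_count is not None
        else int(config.ac_min + rng.poisson(20))
    )
    an = 150_000
    return {
        "Chromosome": ctx.contig_id,
        "Position": p + 1,
        "rsIDs": "",
        "Reference": ctx.sequence[p],
        "Alternate": alt,
        "VEP Annotation": vep,
        "HGVS Consequence": hgvs_c,
        "Allele Count": ac,
        "Allele Number": an,
        "Allele Frequency": round(ac / an, 8),
    }


# -- pool simulation ----------------------------------------------------


@dataclass
class PoolSim:
    """True allele fractions for one epegRNA library.

    ``fractions[(condition, replicate)]`` maps variant id (or "WT") to its
    cell fraction; dropout and editing efficiency are drawn once per variant
    (a dropped variant is absent everywhere), so replicate-to-replicate
    variation comes from sequencing sampling alone.
    """

    variant_ids: list[str]
    dropped: dict[str, bool]
    editing_eff: dict[str, float]
    fractions: dict[tuple[str, int], dict[str, float]]

    @property
    def dropout_fraction(self) -> float:
        if not self.variant_ids:
            return 0.0
        return sum(self.dropped[v] for v in self.variant_ids) / len(self.variant_ids)


def simulate_pools(
    config: SimulationConfig,
    designs: list[EpegRNADesign],
    rng: np.random.Generator | None = None,
) -> PoolSim:
    """Simulate control/selected pool compositions for one library.

    Each designed variant is independently dropped with ``dropout_prob``;
    survivors receive a control-pool fraction proportional to their Beta
    editing-efficiency draw within the edited cell compartment
    (``edited_cell_fraction`` of the pool; the remainder is unedited WT).
    Selection multiplies fractions by class fitness and renormalizes.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x90015]))
    variants = []
    seen = set()
    for d in designs:
        vid = d.variant.variant_id
        if vid not in seen:
            seen.add(vid)
            variants.append(d.variant)
    ids = [v.variant_id for v in variants]
    dropped_arr = rng.random(len(ids)) < config.dropout_prob
    a, b = config.editing_eff_beta
    eff_arr = rng.beta(a, b, size=len(ids))
    eff_arr = np.where(dropped_arr, 0.0, eff_arr)

    total_eff = float(eff_arr.sum())
    ctrl = {}
    if total_eff > 0:
        for vid, eff in zip(ids, eff_arr):
            ctrl[vid] = config.edited_cell_fraction * float(eff) / total_eff
        ctrl["WT"] = 1.0 - config.edited_cell_fraction
    else:
        ctrl = {vid: 0.0 for vid in ids}
        ctrl["WT"] = 1.0

    fit = {v.variant_id: config.class_fitness(v.class_label) for v in variants}
    fit["WT"] = 1.0
    weights = {vid: f * fit[vid] for vid, f in ctrl.items()}
    wsum = sum(weights.values())
    sel = {vid: w / wsum for vid, w in weights.items()}

    fractions = {}
    for rep in range(1, config.replicates + 1):
        fractions[("control", rep)] = dict(ctrl)
        fractions[("selected", rep)] = dict(sel)
    return PoolSim(
        variant_ids=ids,
        dropped={vid: bool(d) for vid, d in zip(ids, dropped_arr)},
        editing_eff={vid: float(e) for vid, e in zip(ids, eff_arr)},
        fractions=fractions,
    )


# -- FASTQ emission -----------------------------------------------------

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def amplicon_window(
    ctx: GeneContext, edit_interval: tuple[int, int], amplicon_len: int
) -> tuple[int, int]:
    """Amplicon interval centered on the editing window, clamped to the
    contig. Under 2x150 sequencing of a <250 bp amplicon both mates cover
    the edited bases."""
    lo, hi = edit_interval
    center = (lo + hi) // 2
    start = max(0, min(center - amplicon_len // 2, len(ctx.sequence) - amplicon_len))
    return (start, start + amplicon_len)


def write_fastq_pair(
    fractions: dict[str, float],
    variant_positions: dict[str, tuple[int, str]],
    ctx: GeneContext,
    amp_interval: tuple[int, int],
    config: SimulationConfig,
    r1_path,
    r2_path,
    rng: np.random.Generator,
) -> int:
    """Draw paired reads from allele fractions and write gzipped FASTQs.

    ``variant_positions`` maps variant id -> (0-based plus-strand position,
    alt base); alleles absent from it (WT) use the reference amplicon.
    Returns the number of read pairs written.
    """
    a0, a1 = amp_interval
    ref_amp = ctx.sequence[a0:a1]
    n_pairs = config.depth // 2
    names = sorted(fractions)
    probs = np.array([fractions[n] for n in names], dtype=float)
    if probs.sum() <= 0:
        probs = np.zeros(len(names))
        probs[names.index("WT")] = 1.0 if "WT" in names else 0.0
    probs = probs / probs.sum()
    counts = rng.multinomial(n_pairs, probs)

    L = min(config.read_len, len(ref_amp))
    blocks_r1, blocks_r2 = [], []
    for name, m in zip(names, counts):
        if m == 0:
            continue
        if name == "WT" or name not in variant_positions:
            amp = ref_amp
        else:
            p, alt = variant_positions[name]
            i = p - a0
            amp = ref_amp[:i] + alt + ref_amp[i + 1 :]
        r1 = _CODE[np.frombuffer(amp[:L].encode(), dtype=np.uint8)]
        r2 = _CODE[np.frombuffer(revcomp(amp)[:L].encode(), dtype=np.uint8)]
        blocks_r1.append(np.tile(r1, (m, 1)))
        blocks_r2.append(np.tile(r2, (m, 1)))
    if blocks_r1:
        mat1 = np.vstack(blocks_r1)
        mat2 = np.vstack(blocks_r2)
        for mat in (mat1, mat2):
            if config.error_rate > 0:
                # binomial error count + uniform positions instead of a dense
                # Bernoulli mask (equivalent at per-base rates << 1)
                n_cells = mat.size
                n_err = rng.binomial(n_cells, config.error_rate)
                if n_err:
                    flat = mat.reshape(-1)
                    idx = rng.integers(0, n_cells, size=n_err)
                    flat[idx] = (flat[idx] + rng.integers(1, 4, size=n_err)) % 4
    else:
        mat1 = np.zeros((0, L), dtype=np.uint8)
        mat2 = np.zeros((0, L), dtype=np.uint8)

    for path, mat, mate in ((r1_path, mat1, 1), (r2_path, mat2, 2)):
        ascii_mat = _DECODE[mat]
        qual = b"I" * L
        records = [
            b"@sim_%d/%d\n%s\n+\n%s" % (i, mate, ascii_mat[i].tobytes(), qual)
            for i in range(mat.shape[0])
        ]
        payload = b"\n".join(records) + (b"\n" if records else b"")
        with gzip.open(path, "wb", compresslevel=1) as fh:
            fh.write(payload)
    return int(mat1.shape[0])
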