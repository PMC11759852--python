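# Methods

This note records the models, conventions and design choices behind
`pemave`, in the order the pipeline runs.

## Coordinates and sequence conventions

All public records (variant catalogs, emitted files) use 1-based positions
and plus-strand ref/alt bases; everything internal is 0-based half-open on
the plus strand. All emitted sequences are uppercase DNA. Tie-breaks are
lexicographic and documented at each operation, so identical inputs and
parameters produce byte-identical outputs (order sheets, FASTQs, catalogs).

## Variant curation

ClinVar and gnomAD export schemas drift, so both parsers are keyed by a
logical field map with defaults matching the portals' current downloads;
extra columns are ignored and a missing mapped column is a configuration
error naming the column. ClinVar rows are resolved to SNVs through the
canonical SPDI column (0-based, converted on input); anything else —
indels, MNVs, rows without SPDI — goes to a rejects table with a reason.

Classification is a pure function of (source, consequence, significance,
allele count, threshold):

* ClinVar missense → PLP when every significance token is
  pathogenic/likely pathogenic, BLB when every token is benign/likely
  benign, VUS for "uncertain significance"; anything mentioning
  "conflicting", and compound strings such as "Likely benign, other", are
  conservatively OTHER — controls should be unambiguous.
* gnomAD records with allele count ≥ `ac_min` become population controls
  (POP_SYN / POP_MISSENSE); below the threshold they are OTHER. The
  default `ac_min = 5` sits at the top of the 3–5 range appropriate for
  dominant-disease genes; recessive genes (where a common pathogenic allele
  can reach very high counts) need a much larger value, so it is a plain
  parameter.

PTC controls are generated, not imported: every SNV in the targeted
interval whose codon (in transcript frame, either strand) becomes
TAA/TAG/TGA, excluding the natural terminal codon. Truth-set sufficiency
uses minimums of 20 synonymous, 20 PTC and 25 clinical (BLB+PLP) variants,
the last being the lower end of the recommended 25–30 range.

## Prime-editing design geometry

SpCas9 nicks the PAM strand between protospacer bases 17 and 18 (3 nt 5′ of
the NGG PAM). Edit offsets are counted from the nick (+1 = first base 3′ of
the nick on the nicked strand). Defaults, all configurable via
`DesignParams`:

| parameter | default | rationale |
|---|---|---|
| `pbs_len` | 13 nt | common PBS length; valid range 8–17 |
| `rtt_3p_homology` | 10 nt | 3′ homology appended beyond the edit |
| `max_edit_offset` | 30 nt | practical RTT reach for efficient editing |
| `library_cap` | 60 | typical library of 40–60 unique epegRNAs |
| `min_archetypes` | 12 | recommended minimum of archetypal epegRNAs to screen |
| `ngrna_offset_range` | 40–90 bp, prefer 60 | brackets widely used PE3 reference designs |

The RTT is the reverse complement of the edited nicked-strand segment from
the nick through (edit offset + homology); the PBS is the reverse
complement of the `pbs_len` protospacer-strand bases 5′ of the nick. A
leading G is prepended to spacers not starting with G (U6 transcription);
nothing else is ever silently changed — internal BsaI sites and long
homopolymers are flagged, and flagged-BsaI designs are diverted from the
oPool sheet to a rejects sheet. The homopolymer flag is evaluated on the
variable segment (spacer+RTT+PBS): the constant scaffold itself contains an
A₅ run, so flagging the full sequence would mark every design and carry no
information. No PAM-disrupting silent co-edits are introduced: they would
change the assayed allele.

Window selection is greedy: each pick maximizes the chosen strategy's score
on not-yet-covered variants (`vus`: VUS count; `controls`: PLP+BLB count),
with ties broken by the other strategy's score, then the leftmost nick.
Selected windows are truncated to `library_cap` variants by class priority
(strategy classes, then clinical controls, then population/PTC controls,
then the rest, position last).

The scaffold and tevopreQ1 motif are the standard published sequences from
the prime-editing literature, shipped as configurable constants. The oPool
tails, Golden Gate overhangs (CACC/GCTT) and the modeled acceptor are
package-defined constants as well: the tails carry the BsaI sites
positioned so that in-silico PCR with the pool primers, BsaI digestion and
ligation into the modeled acceptor reconstruct each epegRNA exactly — a
round-trip the test suite enforces for every emitted design. Users cloning
into a different acceptor replace these constants.

Amplicon validation enforces unique, convergent, opposite-strand exact
primer matches, amplicon length strictly below 250 bp (read-depth
efficiency for 2×150 sequencing), and no primer overlap with the edited
interval (indel detectability). Editing QC passes strictly above 15%
edited reads; depth QC requires at least 200,000 reads per amplicon library
(boundary passes).

## k-mer quantification

Each designed variant gets one k-mer (default k=25; odd k only, so no
k-mer equals its own reverse complement) centered on the edited base, with
the same reference window as its wild-type counterpart; WT windows shared
by nearby variants are collapsed into one entry. Global uniqueness across
entries and their reverse complements is enforced at build time; a genuine
collision (two variants indistinguishable at every window) aborts the build
naming both.

Counting is dictionary-restricted: every read offset is tested against the
dictionary (canonical mode also matches reverse complements), N bases break
matches, and quality scores are ignored. Occurrences are counted at every
offset, matching Jellyfish semantics. The implementation 2-bit-encodes
reads and rolls a 64-bit k-mer code column-wise over the read matrix; a
naive two-strand sliding-window scan serves as the independent oracle in
the tests. R1/R2 counts are summed per sample and the sample depth is the
summed read count of both mates — downstream scores are ratios of
frequencies, so they are invariant to this merge choice. A sample with a
missing mate proceeds single-end with a warning.

## Enrichment scoring

Scores follow the Enrich2 conventions: natural-log ratio of 0.5-pseudocount
allele frequencies (selected vs. unselected), with per-replicate variance
`1/(c_sel+½) + 1/(c_ctrl+½)`. Replicates are combined with the closed-form
DerSimonian–Laird random-effects estimator (τ² truncated at zero; a single
replicate collapses to its own score and sampling SE). DL was chosen over
likelihood-based τ² for determinism and having a closed form.

Variants below 0.1% allele frequency in unselected samples are excluded
before scoring (strictly below; the boundary value is retained). The
default mode excludes on any control replicate (conservative); an
all-replicates mode is available. Raising the threshold can only exclude
more variants, never fewer.

Cross-library normalization centers each library's β on the median of its
scored synonymous+BLB variants (≥3 anchors required, else the library is
left unnormalized with a warning); an optional second step divides by the
magnitude of the PTC median so complete loss of function maps to −1.
Truth-set separation is summarized per class (n, median, IQR) plus two
rank-based AUROCs oriented for depletion selection: P(neutral score >
loss-of-function score) for POP_SYN vs PTC_CTRL and BLB vs PLP; a
comparison with an empty class is reported as not computable.

The scored CSV is the input count table plus exactly two appended columns
(beta, SE), blank for filtered rows. Sample depths travel in a JSON sidecar
next to the counts CSV; if it is absent, column sums are used as depth with
a warning.

## Synthetic data generator

The generator emulates the study conditions the pipeline assumes:

* **Gene**: 3 kb contig, 4 fully coding exons (codon-aligned boundaries),
  ORF free of internal stops.
* **Hotspots**: two 10-codon windows in the middle exons, each placed
  immediately 3′ of a planted spacer nick (a TGG codon pinned at hotspot
  codon 2 supplies the NGG PAM), so one editing window covers each hotspot
  exactly. Hotspot codons come from a fixed stop-adjacent,
  degeneracy-rich pool (4×TCA, TGG, TAC, TTA, GAA, TAT, AAG, shuffled),
  which guarantees 18 synonymous and 18 stop-gain SNV opportunities per
  hotspot — enough to satisfy the truth-set minimums at the default class
  counts (40 VUS, 15 PLP, 15 BLB, 25 POP_SYN, 10 POP_MISSENSE, PTC ≥ 20)
  deterministically rather than in expectation.
* **Editing outcomes**: each designed variant is independently dropped
  with probability 0.33 (all-or-none, absent from every replicate and
  condition), matching the aggregate dropout rate typically observed.
  Survivors draw editing efficiency from Beta(2,6) (right-skewed, mean
  0.25 — only qualitative variability is documented in practice, so any
  positive right-skewed distribution works; it is configurable). Control
  pools allocate 30% of cells to edited alleles in proportion to
  efficiency; selection multiplies fractions by class fitness (default
  0.2 for PTC/PLP, 1.0 otherwise — a depletion-type selection) and
  renormalizes against the unedited WT remainder.
* **Reads**: 2×150 bp pairs from a 240 bp amplicon centered on each
  window, allele drawn multinomially per pair, uniform per-base
  substitution error 0.001 (error count drawn binomially with uniform
  positions — equivalent at rates ≪ 1). Both mates cover every variant
  k-mer window by construction. Default depth is 300,000 reads per sample
  across 3 replicates.

What the generator does *not* emulate: position-dependent Illumina error
profiles and quality-score structure, PCR duplicates and jackpotting,
per-replicate transfection variability (replicate noise is sequencing
sampling only, so fitted τ² is near zero by design), FACS gating, and
polyclonal/impure edits. Passing tests therefore demonstrate correctness of
the algorithms under the stated statistical model, not robustness to every
artifact of real sequencing data.

## Problem sizes and numerical choices

The end-to-end validation runs the default simulation (two libraries of 60
epegRNAs, 3 replicates × 2 conditions × 300,000 reads) through design,
dictionary, counting and scoring, and checks AUROC(synonymous vs PTC) >
0.95; dropout calibration averages 20 independent seeds (~120 designed
variants each). Counter-vs-oracle equivalence uses 100 random FASTQs;
random-effects correctness uses closed forms plus 1000 random fixtures
against an independent DL implementation. All randomness flows from
explicit integer seeds through `numpy.random.Generator`; no global RNG
state is touched.

Degenerate inputs are defined errors, not silent results: zero total reads
(AF and editing QC), empty design lists (order sheets), empty replicate
sets (random effects), even k (dictionary), malformed FASTQ records
(counter, with record index).

## Known limitations

* Screening-primer design is out of scope (an external primer-design tool
  is the right instrument); amplicon validation checks a user-supplied
  pair instead.
* HGVS parsing is limited to SNV resolution via SPDI; inframe indels are
  rejected rather than designed.
* The k-mer counter is dictionary-restricted by design; it is not a
  general-purpose k-mer counter and holds per-file read batches in memory
  grouped by read length.
* Mixture-model classification of scores (assigning functional classes to
  unknown variants) and formal clinical-evidence calibration are outside
  the package; the separation report stops at class summaries and AUROC.
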