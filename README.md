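# pemave

Design, quantify and score curated prime-editing MAVE libraries.

Multiplexed assays of variant effect (MAVEs) measure the functional impact
of many genetic variants at once: a library of variants is installed in a
cell pool, the pool is put through a selection that depends on the gene's
function, and deep amplicon sequencing of selected vs. unselected cells
reveals which variants were enriched or depleted. Curated-locus prime
editing builds such libraries with engineered prime-editing guide RNAs
(epegRNAs), targeting the regions of a gene densest in ClinVar variants of
uncertain significance (VUS) rather than saturating every codon.

`pemave` is the computational side of that workflow, for lab scientists and
analysts running curated prime-editing MAVEs:

* **Catalog curation** — parse ClinVar TSV and gnomAD CSV per-gene exports,
  classify variants (VUS / PLP / BLB / population synonymous & missense),
  enumerate premature-truncation (PTC) control SNVs, and check truth-set
  sufficiency (≥20 synonymous, ≥20 PTC, ≥25 clinical controls).
* **Library design** — enumerate NGG spacers, rank editing windows under a
  VUS-density or control-maximizing strategy, assemble each epegRNA
  (spacer + scaffold + RT template + primer-binding site + tevopreQ1 motif),
  pick PE3 nicking guides, and emit every cloning oligo: archetype duplexes,
  BsaI-ready oPool entries, nicking-guide sticky-end oligos, and the
  constant amplicon-sequencing primers.
* **Quantification** — build a variant-identifying k-mer dictionary
  (default k=25, centered on each edit) and count it in paired-end amplicon
  FASTQs by dictionary-restricted canonical k-mer counting, with
  sequencing-depth QC (≥200,000 reads per library).
* **Scoring** — convert counts to allele frequencies, drop variants below
  0.1% unselected allele frequency, compute per-replicate log-enrichment
  scores and combine them per variant with a DerSimonian–Laird
  random-effects model into a functional score beta ± SE; center scores
  across libraries on the synonymous/benign median and report truth-set
  separation (rank AUROC).
* **Simulation** — generate a complete synthetic study (gene, catalogs,
  editing outcomes with ~33% variant dropout, paired 2×150 bp reads) for
  testing and calibration.

## The score model

For variant *i* in replicate *r*, with counts *c* and sequencing depths *N*
in selected and control (unselected) pools:

```
s_ir = ln((c_sel + 1/2) / N_sel) − ln((c_ctrl + 1/2) / N_ctrl)
v_ir = 1/(c_sel + 1/2) + 1/(c_ctrl + 1/2)
```

Replicates are combined with the closed-form DerSimonian–Laird estimator:
with fixed-effect weights `w = 1/v`, heterogeneity `Q = Σ w (s − μ_FE)²`,

```
τ² = max(0, (Q − (R−1)) / (Σw − Σw²/Σw))
β  = Σ w* s / Σ w*,   SE = sqrt(1/Σ w*),   w* = 1/(v + τ²)
```

Under a depletion-type selection, loss-of-function variants (PTC controls,
pathogenic missense) end up with strongly negative β while synonymous and
benign variants sit near 0.

## Worked example

Run the whole synthetic study through the pipeline in a few lines:

```python
from pemave import SimulationConfig, run_end_to_end

result = run_end_to_end(SimulationConfig(seed=1, depth=60000))
print(result.truth_report.to_text())
print(result.separation.to_markdown())
```

which prints:

```
Truth-set report
  synonymous (POP_SYN):        25
  PTC controls (PTC_CTRL):     36
  clinical BLB:                15
  clinical PLP:                15
  clinical total:              30
  VUS:                         40
  verdict: PASS

# Truth-set separation

 class_label  n  median    iqr
         BLB  9  0.0005 0.0568
       OTHER 53  0.0162 0.0423
         PLP 11 -1.4611 0.1878
POP_MISSENSE  4  0.0096 0.1021
     POP_SYN 14 -0.0031 0.0835
    PTC_CTRL 20 -1.4106 0.1496
         VUS 30  0.0498 0.1191

AUROC synonymous vs PTC: 1.0
AUROC BLB vs PLP: 1.0

synonymous and PTC variants are well separated; BLB scores sit clearly above PLP scores.
```

Reading this: the generated catalogs satisfy both truth sets; after
sequencing, counting and scoring, PTC and pathogenic controls are depleted
(median β ≈ −1.4 ≈ ln of the simulated 0.2 fitness) while neutral classes
center on 0, and both truth-set comparisons separate perfectly (AUROC 1.0).
`OTHER` rows are the wild-type dictionary k-mers, which are counted but
never enter truth-set summaries. Some designed variants are missing from
the scored table — they were either dropped by the simulated ~33% editing
dropout or excluded by the 0.1% unselected-allele-frequency filter.

The same stages are available as a CLI
(`pemave simulate | design | dict | count | score | qc`), each writing a run
manifest beside its outputs; see `pemave --help`.

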