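"""Sequence constants shared across the design and order-sheet stages.

The scaffold and tevopreQ1 motif are the standard published SpCas9 sgRNA
scaffold and the stabilizing 3' structured motif used by engineered pegRNAs;
both are configurable through :class:`~pemave.design.DesignParams` for users
whose acceptor plasmid differs.
"""

# SpCas9 sgRNA scaffold (spacer..scaffold..RTT orientation, DNA alphabet).
SCAFFOLD_SEQ = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC"
)

# tevopreQ1 structured motif appended 3' of the PBS in engineered pegRNAs.
TEVOPREQ1_SEQ = "CGCGGTTCTATCTAGTTACGCGTTAAACCAACTAGAA"

# BsaI recognition site and its reverse complement; any occurrence inside an
# epegRNA core would be cut during Golden Gate assembly, so designs carrying
# one are flagged and kept off the oPool sheet.
BSAI_SITES = ("GGTCTC", "GAGACC")

# Constant flanks placed around each epegRNA core in the synthesized oligo
# pool. Each tail carries a primer landing plus a BsaI site oriented so that
# digestion releases CACC + core (top strand) with an AAGC-compatible 4-nt
# overhang on the bottom strand at the 3' end: PCR with the pool primers,
# BsaI digestion and ligation into the modeled acceptor reconstruct the core
# exactly.
POOL_TAIL_LEFT = "TTCTAGAGCGGTCTCACACC"  # ...GGTCTC-A-[CACC
POOL_TAIL_RIGHT = "GCTTAGAGACCGCATACGAT"  # GCTT]-A-GAGACC...

# Golden Gate overhangs produced by the tails above.
GG_LEFT_OVERHANG = "CACC"
GG_RIGHT_OVERHANG = "GCTT"

# Minimal model of the BsaI-digested acceptor plasmid around the insertion
# site (top strand, immediately flanking the two overhangs).
ACCEPTOR_UPSTREAM = "TGGAAAGGACGA"
ACCEPTOR_DOWNSTREAM = "TTTTTTGGATCC"

# Illumina Nextera-style adaptor tails prepended to locus-specific amplicon
# sequencing primers for multiplexed barcoding.
ILLUMINA_TAIL_F = "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG"
ILLUMINA_TAIL_R = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"

# Constant primers for amplicon sequencing of epegRNA plasmid pools cloned
# into the U6-tevopreQ1 acceptor (adaptor tail + plasmid landing).
TEVOPREQ_PCR1_AMPSEQ_F = (
    "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAGATATATCTTGTGGAAAGGACGAAAC"
)
TEVOPREQ_PCR1_AMPSEQ_R = "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAGTACCTCGAGCGGCCCA"
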