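"""Design-core checks: spacers, windows, epegRNAs, oligos, QC gates."""

import re

import pytest
from hypothesis import given, strategies as st

from pemave import constants as C
from pemave.catalogs import VariantRecord
from pemave.design import (
    DesignParams,
    DesignRejection,
    EditingWindow,
    build_windows,
    design_epegrna,
    design_nicking,
    emit_order_sheets,
    enumerate_spacers,
    golden_gate_roundtrip,
    nicking_oligos,
    qc_editing_fraction,
    select_windows,
    synthesize_flap,
    flap_footprint,
    validate_amplicon,
)
from pemave.gene import GeneContext, revcomp

dna = st.text(alphabet="ACGT", min_size=30, max_size=80)


def _ctx(seq, strand="+"):
    n = len(seq) - len(seq) % 3
    return GeneContext("c", seq, "G", "T", strand, ((0, n),), ((0, n),))


def naive_spacers(seq, region):
    """Exhaustive oracle over both strands."""
    found = []
    for p in range(len(seq) - 22):
        if seq[p + 21 : p + 23] == "GG" and region[0] <= p + 17 < region[1]:
            found.append(("+", seq[p : p + 20], p + 17))
    rc = revcomp(seq)
    L = len(seq)
    for p in range(len(rc) - 22):
        if rc[p + 21 : p + 23] == "GG":
            # map minus-strand nick back to plus coordinates
            nick_plus = L - 1 - (p + 17)
            if region[0] <= nick_plus < region[1]:
                found.append(("-", rc[p : p + 20], nick_plus))
    return sorted(found, key=lambda t: (t[2], t[0]))


class TestEnumerateSpacers:
    def test_single_plus_site(self):
        seq = "T" * 21 + "AGG" + "T" * 6  # protospacer T*20, PAM AGG
        ctx = _ctx(seq)
        sites = enumerate_spacers(ctx, (0, len(seq)))
        assert len(sites) == 1
        (s,) = sites
        assert s.strand == "+" and s.pam == "AGG"
        assert s.nick_pos == s.protospacer_start + 17
        # nick is 3 nt 5' of the PAM
        assert s.protospacer_start + 20 - s.nick_pos == 3

    def test_poly_a_has_no_sites(self):
        ctx = _ctx("A" * 60)
        assert enumerate_spacers(ctx, (0, 60)) == []

    def test_out_of_bounds_region(self):
        ctx = _ctx("A" * 30)
        with pytest.raises(ValueError, match="outside"):
            enumerate_spacers(ctx, (0, 31))

    @given(dna)
    def test_matches_exhaustive_oracle(self, seq):
        ctx = _ctx(seq)
        got = [
            (s.strand, s.protospacer, s.nick_pos)
            for s in enumerate_spacers(ctx, (0, len(seq)))
        ]
        assert got == naive_spacers(seq, (0, len(seq)))

    @given(dna)
    def test_strand_symmetry(self, seq):
        """A sequence and its reverse complement yield mirrored site lists."""
        fwd = enumerate_spacers(_ctx(seq), (0, len(seq)))
        rev = enumerate_spacers(_ctx(revcomp(seq)), (0, len(seq)))
        L = len(seq)
        mirrored = sorted(
            (("-" if s.strand == "+" else "+"), s.protospacer, L - 1 - s.nick_pos)
            for s in rev
        )
        assert mirrored == sorted((s.strand, s.protospacer, s.nick_pos) for s in fwd)


def _variant(ctx, pos0, alt=None, label="VUS"):
    ref = ctx.sequence[pos0]
    if alt is None:
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
    v = VariantRecord(
        source="clinvar", contig=ctx.contig_id, pos=pos0 + 1, ref=ref, alt=alt,
        consequence="missense",
    )
    v.class_label = label
    return v


@pytest.fixture(scope="module")
def window_ctx():
    # one engineered plus-strand spacer at nick 22 with a long downstream
    # runway for edits and room 5' for the PBS
    seq = (
        "ACATA"  # pad
        + "TACAGTCATCATGCATACAT"  # protospacer (no GG/CC)
        + "AGG"  # PAM
        + "TACGATCGATACGATTCAGATCATGCATCAGTACATACGAT"  # downstream runway
    )
    ctx = _ctx(seq)
    sites = [
        s
        for s in enumerate_spacers(ctx, (0, len(seq)))
        if s.strand == "+" and s.nick_pos == 22
    ]
    assert len(sites) == 1
    return ctx, sites[0]


class TestWindows:
    def test_offset_boundaries(self, window_ctx):
        ctx, sp = window_ctx
        params = DesignParams(max_edit_offset=10)
        inside = _variant(ctx, sp.nick_pos + 9)  # offset 10
        outside = _variant(ctx, sp.nick_pos + 10)  # offset 11
        windows = build_windows([sp], [inside, outside], params)
        (w,) = windows
        ids = [v.variant_id for v in w.variants]
        assert inside.variant_id in ids and outside.variant_id not in ids

    def test_tallies(self, window_ctx):
        ctx, sp = window_ctx
        params = DesignParams()
        vs = [_variant(ctx, sp.nick_pos + i, label="VUS") for i in range(3)]
        vs += [_variant(ctx, sp.nick_pos + 3 + i, label="PLP") for i in range(2)]
        (w,) = build_windows([sp], vs, params)
        assert dict(w.tallies) == {"VUS": 3, "PLP": 2}

    def test_empty_window_retained(self, window_ctx):
        ctx, sp = window_ctx
        (w,) = build_windows([sp], [], DesignParams())
        assert w.variants == []


class TestSelectWindows:
    def _mkwin(self, nick, variants):
        from pemave.design import SpacerSite

        sp = SpacerSite("+", "A" * 20, "AGG", nick - 17, nick)
        return EditingWindow(spacer=sp, edit_interval=(nick, nick + 30), variants=variants)

    def _vars(self, n, label, start=0):
        out = []
        for i in range(n):
            v = VariantRecord(
                source="clinvar", contig="c", pos=start + i + 1, ref="A", alt="G"
            )
            v.class_label = label
            out.append(v)
        return out

    def test_vus_strategy_argmax(self):
        w1 = self._mkwin(100, self._vars(5, "VUS"))
        w2 = self._mkwin(200, self._vars(2, "VUS", 50) + self._vars(4, "PLP", 60))
        picked = select_windows([w1, w2], "vus", 1, DesignParams())
        assert picked[0].spacer.nick_pos == 100

    def test_controls_strategy_argmax(self):
        w1 = self._mkwin(100, self._vars(5, "VUS"))
        w2 = self._mkwin(200, self._vars(2, "VUS", 50) + self._vars(4, "PLP", 60))
        picked = select_windows([w1, w2], "controls", 1, DesignParams())
        assert picked[0].spacer.nick_pos == 200

    def test_library_cap(self):
        w = self._mkwin(100, self._vars(150, "VUS"))
        picked = select_windows([w], "vus", 1, DesignParams())
        assert len(picked[0].variants) == 60

    def test_fewer_windows_than_target_returns_all(self):
        w = self._mkwin(100, self._vars(3, "VUS"))
        picked = select_windows([w], "vus", 5, DesignParams())
        assert len(picked) == 1

    def test_strategy_dominance_on_synthetic_library(self, synthetic_study):
        """VUS coverage under strategy=vus is never below strategy=controls."""
        from pemave.design import design_library

        locus, records = synthetic_study
        cov = {}
        for strategy in ("vus", "controls"):
            lib = design_library(locus.ctx, records, strategy=strategy, n_target=2)
            cov[strategy] = len(
                {
                    v.variant_id
                    for w in lib.windows
                    for v in w.variants
                    if v.class_label == "VUS"
                }
            )
        assert cov["vus"] >= cov["controls"]


def check_flap(design, ctx):
    """Flap-reconstruction oracle: applying the flap to the reference must
    change exactly the variant base."""
    lo, hi = flap_footprint(design)
    edited = ctx.sequence[:lo] + synthesize_flap(design) + ctx.sequence[hi:]
    assert len(edited) == len(ctx.sequence)
    diffs = [i for i in range(len(edited)) if edited[i] != ctx.sequence[i]]
    assert diffs == [design.variant.pos - 1]
    assert edited[design.variant.pos - 1] == design.variant.alt


class TestEpegRNA:
    def test_rtt_length_rule(self, window_ctx):
        ctx, sp = window_ctx
        params = DesignParams()
        (w,) = build_windows([sp], [_variant(ctx, sp.nick_pos)], params)  # offset 1
        d = design_epegrna(w, w.variants[0], params, ctx=ctx)
        assert len(d.rtt_seq) == 1 + params.rtt_3p_homology
        assert len(d.pbs_seq) == params.pbs_len

    def test_full_seq_composition_and_flap(self, window_ctx):
        ctx, sp = window_ctx
        params = DesignParams()
        for off in (1, 5, 13):
            (w,) = build_windows([sp], [_variant(ctx, sp.nick_pos + off - 1)], params)
            d = design_epegrna(w, w.variants[0], params, ctx=ctx)
            assert d.full_seq == (
                d.spacer_seq + params.scaffold_seq + d.rtt_seq + d.pbs_seq + params.motif_seq
            )
            # PBS is revcomp of the pbs_len bases 5' of the nick on the
            # protospacer strand
            assert d.pbs_seq == revcomp(
                ctx.sequence[sp.nick_pos - params.pbs_len : sp.nick_pos]
            )
            check_flap(d, ctx)

    def test_five_prime_g_rule(self, window_ctx):
        ctx, sp = window_ctx
        params = DesignParams()
        (w,) = build_windows([sp], [_variant(ctx, sp.nick_pos)], params)
        d = design_epegrna(w, w.variants[0], params, ctx=ctx)
        if sp.protospacer.startswith("G"):
            assert d.spacer_seq == sp.protospacer
        else:
            assert d.spacer_seq == "G" + sp.protospacer

    def test_seed_side_variant_rejected(self, window_ctx):
        ctx, sp = window_ctx
        params = DesignParams()
        w = EditingWindow(sp, sp.edit_interval(params.max_edit_offset), [])
        bad = _variant(ctx, sp.nick_pos - 3)  # 5' of the nick
        with pytest.raises(DesignRejection, match="rtt_cannot_cover"):
            design_epegrna(w, bad, params, ctx=ctx)

    def test_internal_bsai_flag(self, window_ctx):
        ctx, sp = window_ctx
        # plant GGTCTC into the scaffold constant so the full sequence
        # carries a BsaI site
        params = DesignParams(scaffold_seq="GGTCTC" + C.SCAFFOLD_SEQ[6:])
        (w,) = build_windows([sp], [_variant(ctx, sp.nick_pos)], params)
        d = design_epegrna(w, w.variants[0], params, ctx=ctx)
        assert "internal_bsai" in d.flags

    def test_minus_strand_designs_flap_correctly(self, synthetic_study):
        """Minus-strand spacers produce valid flaps too (synthetic locus
        hotspots carry minus-strand spacers among candidates)."""
        locus, records = synthetic_study
        ctx = locus.ctx
        params = DesignParams()
        spacers = [
            s
            for s in enumerate_spacers(ctx, locus.hotspots[0])
            if s.strand == "-"
        ]
        if not spacers:
            pytest.skip("no minus-strand spacer over hotspot for this seed")
        windows = build_windows(spacers, records, params)
        done = 0
        for w in windows:
            for v in w.variants[:3]:
                d = design_epegrna(w, v, params, ctx=ctx)
                check_flap(d, ctx)
                done += 1
        assert done > 0


class TestNicking:
    def test_prefix_rule_non_g(self):
        top, bottom = nicking_oligos("ATGCATGCATGCATGCATGC")
        assert top == "CACCGATGCATGCATGCATGCATGC"
        assert bottom == "AAAC" + revcomp("ATGCATGCATGCATGCATGC") + "C"

    def test_prefix_rule_native_g(self):
        top, bottom = nicking_oligos("GTGCATGCATGCATGCATGC")
        assert top == "CACC" + "GTGCATGCATGCATGCATGC"
        assert bottom == "AAAC" + revcomp("GTGCATGCATGCATGCATGC")

    @pytest.mark.parametrize("spacer", ["ATGCATGCATGCATGCATGC", "GTGCATGCATGCATGCATGC"])
    def test_duplex_assembly_overhangs(self, spacer):
        """Annealing top and bottom yields 4-nt 5' overhangs CACC and AAAC."""
        top, bottom = nicking_oligos(spacer)
        assert top.startswith("CACC") and bottom.startswith("AAAC")
        # the double-stranded core: top minus its overhang pairs exactly with
        # bottom minus its overhang
        assert revcomp(bottom[4:]) == top[4:]

    def test_selection_prefers_60(self, synthetic_library, synthetic_study):
        locus, _ = synthetic_study
        params = DesignParams()
        for w in synthetic_library.windows:
            ng = design_nicking(w, locus.ctx, params)
            assert ng.strand != w.spacer.strand
            assert 40 <= abs(ng.nick_offset) <= 90
            # no better candidate exists
            others = [
                abs(s.nick_pos - w.spacer.nick_pos)
                for s in enumerate_spacers(
                    locus.ctx,
                    (w.spacer.nick_pos - 120, w.spacer.nick_pos + 120),
                )
                if s.strand == ng.strand
                and 40 <= abs(s.nick_pos - w.spacer.nick_pos) <= 90
            ]
            assert abs(abs(ng.nick_offset) - 60) == min(abs(o - 60) for o in others)

    def test_no_candidate_raises(self):
        from pemave.design import SpacerSite

        ctx = _ctx("A" * 120)  # poly-A: no opposite-strand NGG anywhere
        sp = SpacerSite("+", "A" * 20, "AGG", 0, 17)
        (w,) = build_windows([sp], [], DesignParams())
        with pytest.raises(DesignRejection, match="no_pe3_nick"):
            design_nicking(w, ctx, DesignParams())


@pytest.fixture(scope="module")
def sheets(synthetic_library):
    return emit_order_sheets(
        synthetic_library.all_designs, synthetic_library.ngrnas, DesignParams()
    )


class TestOrderSheets:
    def test_contains_verbatim_ampseq_primers(self, sheets):
        seqs = dict(zip(sheets.ampseq_constants["name"], sheets.ampseq_constants["sequence"]))
        assert seqs["tevopreqPCR1_ampSeqF"] == (
            "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAGATATATCTTGTGGAAAGGACGAAAC"
        )
        assert seqs["tevopreqPCR1_ampSeqR"] == (
            "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAGTACCTCGAGCGGCCCA"
        )
        assert seqs["illumina_tail_F"] == "TCGTCGGCAGCGTCAGATGTGTATAAGAGACAG"
        assert seqs["illumina_tail_R"] == "GTCTCGTGGGCTCGGAGATGTGTATAAGAGACAG"

    def test_row_counts(self, sheets, synthetic_library):
        n_designs = len(synthetic_library.all_designs)
        assert len(sheets.opool) + len(sheets.opool_rejects) == n_designs
        assert len(sheets.pool_primers) == 2
        assert len(sheets.archetypes) == len(synthetic_library.windows)

    def test_bsai_designs_diverted(self, sheets):
        assert all("internal_bsai" not in f for f in sheets.opool["flags"])
        for f in sheets.opool_rejects["flags"]:
            assert "internal_bsai" in f

    def test_empty_designs_error(self):
        with pytest.raises(ValueError, match="nothing to emit"):
            emit_order_sheets([], {}, DesignParams())

    def test_golden_gate_roundtrip(self, sheets, synthetic_library):
        """PCR + BsaI digestion + ligation reconstructs full_seq."""
        params = DesignParams()
        by_id = {d.design_id: d for d in synthetic_library.all_designs}
        for _, row in sheets.opool.iterrows():
            product = golden_gate_roundtrip(row["sequence"])
            full = by_id[row["name"]].full_seq
            assert product.count(full) == 1
            assert ("CACC" + full + "GCTT") in product

    def test_byte_identical_reruns(self, synthetic_library, tmp_path):
        params = DesignParams()
        out1, out2 = tmp_path / "a", tmp_path / "b"
        for out in (out1, out2):
            emit_order_sheets(
                synthetic_library.all_designs, synthetic_library.ngrnas, params
            ).write(out)
        for name in ("opool", "archetypes", "nicking", "pool_primers"):
            assert (out1 / f"{name}.csv").read_bytes() == (out2 / f"{name}.csv").read_bytes()


@pytest.fixture(scope="module")
def amp_ctx(synthetic_study):
    return synthetic_study[0].ctx


class TestAmpliconValidation:
    def test_length_boundary(self, amp_ctx):
        seq = amp_ctx.sequence
        fwd = seq[100:120]
        ok = validate_amplicon(fwd, revcomp(seq[329:349]), amp_ctx)  # 249 bp
        too_long = validate_amplicon(fwd, revcomp(seq[330:350]), amp_ctx)  # 250 bp
        assert ok.ok and ok.length == 249
        assert not too_long.ok and too_long.reason == "amplicon_too_long"

    def test_primer_overlapping_target(self, amp_ctx):
        seq = amp_ctx.sequence
        res = validate_amplicon(
            seq[100:120],
            revcomp(seq[300:320]),
            amp_ctx,
            edit_interval=(110, 140),
        )
        assert not res.ok and res.reason == "primer_overlaps_target"

    def test_same_primer_twice_not_convergent(self, amp_ctx):
        seq = amp_ctx.sequence
        p = seq[100:120]
        res = validate_amplicon(p, p, amp_ctx)
        assert not res.ok and res.reason == "not_convergent"

    def test_unmapped_primer(self, amp_ctx):
        res = validate_amplicon("N" * 20, amp_ctx.sequence[300:320], amp_ctx)
        assert not res.ok and res.reason == "primer_not_found"


class TestEditingQC:
    @pytest.mark.parametrize(
        "edited,total,expected",
        [(16, 100, True), (15, 100, False), (0, 100, False)],
    )
    def test_strict_boundary(self, edited, total, expected):
        res = qc_editing_fraction(edited, total - edited)
        assert res.passed is expected
        assert res.fraction_pct == pytest.approx(100 * edited / total)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError, match="zero total"):
            qc_editing_fraction(0, 0)
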