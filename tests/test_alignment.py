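"""Alignment parsing, coordinate maps, variant calling and export."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from ftindelscan.alignment import (
    AlignmentFormatError,
    AlignmentInputError,
    ReferenceAnchor,
    build_coord_map,
    call_variants,
    compare_homolog_positions,
    export_variants,
    polymorphic_region_set,
    read_alignment,
    span_length,
    tss_relative,
    unaligned_ends,
    write_alignment,
)
from conftest import make_alignment, random_gapped_alignment


class TestReadAlignment:
    def test_identity_pair(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\n" + "ACGT" * 25 + "\n>b\n" + "ACGT" * 25 + "\n")
        aln = read_alignment(p)
        assert aln.length == 100 and aln.ref_id == "a"

    def test_round_trip_preserves_gaps(self, tmp_path):
        aln = make_alignment({"r": "ACGTACGTAC", "c1": "ACG-----AC", "c2": "ACGTACGTAC"})
        p = tmp_path / "x.fasta"
        write_alignment(aln, p)
        back = read_alignment(p, ref_id="r")
        assert back.sequences == aln.sequences

    def test_single_sequence_rejected(self, tmp_path):
        p = tmp_path / "one.fasta"
        p.write_text(">only\nACGT\n")
        with pytest.raises(AlignmentInputError):
            read_alignment(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(AlignmentInputError):
            read_alignment(p)

    def test_ragged_lengths_rejected(self):
        with pytest.raises(AlignmentFormatError):
            make_alignment({"a": "ACGT", "b": "ACG"})

    def test_ambiguity_codes_other_than_n_rejected(self):
        with pytest.raises(AlignmentInputError):
            make_alignment({"a": "ACRT", "b": "ACGT"})


class TestCoordMap:
    def test_gapless_reference_is_identity(self):
        aln = make_alignment({"r": "ACGTAC", "c": "A-GTAC"})
        cmap = build_coord_map(aln)
        for i in range(1, 7):
            assert cmap.ref_pos(i) == i and cmap.col(i) == i

    def test_ref_gap_shifts_positions(self):
        # reference gap at columns 5-7: column 8 carries ref position 5
        aln = make_alignment({"r": "ACGT---ACGT", "c": "ACGTTTTACGT"})
        cmap = build_coord_map(aln)
        assert cmap.ref_pos(8) == 5
        assert cmap.col(5) == 8
        assert cmap.is_ref_gap(6)

    @given(st.integers(0, 2**31))
    @settings(max_examples=30, deadline=None)
    def test_bijection_on_non_gap_columns(self, seed):
        aln = random_gapped_alignment(np.random.default_rng(seed), n_cols=60)
        cmap = build_coord_map(aln)
        for col in range(1, aln.length + 1):
            if not cmap.is_ref_gap(col):
                assert cmap.col(cmap.ref_pos(col)) == col
        for pos in range(1, cmap.ref_length + 1):
            assert cmap.ref_pos(cmap.col(pos)) == pos


class TestTssFrame:
    def test_zero_at_tss(self, fta1_anchor):
        assert tss_relative(fta1_anchor.tss_genomic, fta1_anchor) == 0

    def test_forward_upstream_is_negative(self, fta1_anchor):
        assert tss_relative(14_992_627, fta1_anchor) == -4161

    def test_reverse_upstream_is_larger_coordinate(self, fta2_anchor):
        assert tss_relative(12_758_413, fta2_anchor) == -100

    @given(st.integers(1, 10**8), st.integers(1, 10**8))
    def test_strand_antisymmetry(self, tss, pos):
        fwd = ReferenceAnchor("g", "c", tss, "forward")
        rev = ReferenceAnchor("g", "c", tss, "reverse_complement")
        assert tss_relative(pos, fwd) == -tss_relative(pos, rev)

    @given(st.integers(-10**6, 10**6), st.integers(-10**6, 10**6))
    def test_span_symmetric_and_inclusive(self, a, b):
        assert span_length(a, b) == span_length(b, a)
        assert span_length(a, a) == 1
        assert span_length(a, b) == abs(a - b) + 1


class TestCallVariants:
    def test_identical_sequences_no_variants(self):
        aln = make_alignment({"r": "ACGTACGT", "c": "ACGTACGT"})
        assert call_variants(aln) == ([], [])

    def test_single_deletion_called(self):
        ref = "A" * 20 + "C" * 90 + "G" * 20
        contig = "A" * 20 + "-" * 90 + "G" * 20
        aln = make_alignment({"r": ref, "c": contig})
        indels, snps = call_variants(aln)
        assert snps == []
        (v,) = indels
        assert (v.kind, v.ref_start, v.ref_end, v.length) == ("deletion", 21, 110, 90)
        assert v.carriers == frozenset({"c"})

    def test_shared_gap_run_merges_carriers(self):
        ref = "ACGTACGTACGTACGTACGT"
        d = "ACGT--------ACGTACGT"
        aln = make_alignment({"r": ref, "c1": d, "c2": d})
        indels, _ = call_variants(aln)
        (v,) = indels
        assert v.carriers == frozenset({"c1", "c2"})

    def test_partially_overlapping_runs_stay_distinct(self):
        ref = "ACGTACGTACGTACGTACGT"
        aln = make_alignment(
            {"r": ref, "c1": "ACGT--------ACGTACGT", "c2": "ACGTAC--------GTACGT"}
        )
        indels, _ = call_variants(aln)
        assert len(indels) == 2
        assert all(v.length == 8 for v in indels)

    def test_terminal_gaps_are_not_deletions(self):
        ref = "ACGTACGTACGTACGTACGT"
        contig = "-----CGTACGTACGTA---"
        aln = make_alignment({"r": ref, "c": contig})
        indels, snps = call_variants(aln)
        assert indels == [] and snps == []
        assert unaligned_ends(aln)["c"] == (5, 3)

    def test_insertion_anchor_and_sequence(self):
        aln = make_alignment({"r": "ACGTA----CGTAC", "c": "ACGTATTTTCGTAC"})
        indels, _ = call_variants(aln)
        (v,) = indels
        assert (v.kind, v.ref_start, v.length, v.inserted_seq) == ("insertion", 5, 4, "TTTT")

    def test_snp_locus_with_carriers_per_alt(self):
        aln = make_alignment({"r": "ACGTACGT", "c1": "ACATACGT", "c2": "ACTTACGT"})
        _, snps = call_variants(aln)
        (s,) = snps
        assert s.ref_pos == 3 and s.ref_base == "G"
        assert s.alts == {"A": frozenset({"c1"}), "T": frozenset({"c2"})}

    def test_tss_annotation_follows_anchor(self, fta1_anchor):
        anchor = ReferenceAnchor(
            "FTa1", "Chr02", fta1_anchor.tss_genomic, "forward",
            region_start_genomic=fta1_anchor.tss_genomic - 99,
        )
        ref = "A" * 200
        contig = "A" * 50 + "-" * 10 + "A" * 140
        aln = make_alignment({"r": ref, "c": contig})
        indels, _ = call_variants(aln, anchor=anchor)
        (v,) = indels
        # ref pos 51..60 -> genomic tss-99+50 .. -> tss_rel -49..-40
        assert (v.tss_rel_start, v.tss_rel_end) == (-49, -40)

    @given(st.integers(0, 2**31))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_scanner(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_gapped_alignment(rng, n_seqs=3, n_cols=int(rng.integers(20, 200)))
        indels, snps = call_variants(aln)
        dels, ins, snp_set = oracles.variants_as_tuples(indels, snps)
        edels, eins, esnps = oracles.brute_force_variants(aln)
        assert dels == edels
        assert ins == eins
        assert snp_set == esnps

    @given(st.integers(0, 2**31))
    @settings(max_examples=30, deadline=None)
    def test_length_bookkeeping_per_contig(self, seed):
        """Within the aligned span, insertions minus deletions equal the
        ungapped contig-minus-reference length difference."""
        rng = np.random.default_rng(seed)
        aln = random_gapped_alignment(rng, n_seqs=3, n_cols=120)
        indels, _ = call_variants(aln)
        ref = aln.ref_seq
        for sid, seq in aln.sequences.items():
            if sid == aln.ref_id:
                continue
            stripped = seq.strip("-")
            if not stripped:
                continue
            lo = len(seq) - len(seq.lstrip("-"))
            hi = len(seq.rstrip("-"))
            contig_len = len(stripped.replace("-", ""))
            ref_len = len(ref[lo:hi].replace("-", ""))
            delta = sum(
                v.length if v.kind == "insertion" else -v.length
                for v in indels
                if sid in v.carriers
            )
            assert contig_len - ref_len == delta


class TestPolymorphicRegions:
    def test_empty_set(self):
        regions = polymorphic_region_set([], [])
        assert 17 not in regions and regions.is_empty()

    def test_interval_endpoints_inclusive(self):
        ref = "A" * 120
        contig = "A" * 9 + "-" * 90 + "A" * 21
        aln = make_alignment({"r": ref, "c": contig})
        indels, snps = call_variants(aln)
        regions = polymorphic_region_set(indels, snps)
        assert 10 in regions and 99 in regions
        assert 9 not in regions and 100 not in regions

    @given(st.integers(0, 2**31))
    @settings(max_examples=40, deadline=None)
    def test_overlap_matches_per_bp_scan(self, seed):
        rng = np.random.default_rng(seed)
        aln = random_gapped_alignment(rng, n_cols=100)
        indels, snps = call_variants(aln)
        regions = polymorphic_region_set(indels, snps)
        intervals = [(v.aln_start, v.aln_end) for v in indels]
        points = [s.aln_col for s in snps]
        for _ in range(20):
            lo = int(rng.integers(1, 100))
            hi = lo + int(rng.integers(0, 15))
            expected = oracles.brute_force_region_membership(intervals, points, lo, hi)
            assert regions.overlaps(lo, hi) == expected


class TestCompareHomologPositions:
    def test_cross_species_distance(self):
        # a 90-bp indel 3572 bp upstream in one species vs its counterpart
        # 3848 bp upstream in another: 276 bp apart
        pairs = compare_homolog_positions([-3572], [-3848])
        assert pairs == [(-3572, -3848, 276, 276)]

    def test_identical_lists_zero_delta(self):
        assert all(
            d == 0 for _, _, d, _ in compare_homolog_positions([-5, 0, 7], [-5, 0, 7])
        )

    def test_empty_reference_list(self):
        assert compare_homolog_positions([-3572], []) == []

    @given(
        st.lists(st.integers(-5000, 5000), min_size=1, max_size=20),
        st.lists(st.integers(-5000, 5000), min_size=1, max_size=20),
    )
    def test_matches_exhaustive_search(self, a, b):
        got = compare_homolog_positions(a, b)
        exp = oracles.nearest_neighbour_pairs(a, b)
        assert [(x, abs_d) for x, _, _, abs_d in got] == [
            (x, abs_d) for x, _, _, abs_d in exp
        ]


class TestExport:
    def _simple_aln(self):
        ref = "".join("ACGT"[i % 4] for i in range(300))
        contig = ref[:100] + "-" * 90 + ref[190:]
        return make_alignment({"r": ref, "c": contig})

    def test_bed_half_open_conversion(self, tmp_path):
        aln = self._simple_aln()
        indels, snps = call_variants(aln)
        bed = tmp_path / "v.bed"
        export_variants(indels, snps, aln, bed_path=bed)
        chrom, start, end, *_ = bed.read_text().splitlines()[0].split("\t")
        assert (int(start), int(end)) == (100, 190)  # ref 101..190 inclusive

    def test_vcf_round_trip_with_cyvcf2(self, tmp_path):
        cyvcf2 = pytest.importorskip("cyvcf2")
        ref = "".join("ACGT"[i % 4] for i in range(600))
        ref_row = ref[:500] + "-" * 24 + ref[500:]
        contig = ref[:100] + "-" * 90 + ref[190:500] + "TG" * 12 + ref[500:]
        aln = make_alignment({"r": ref_row, "c": contig})
        indels, snps = call_variants(aln)
        vcf = tmp_path / "v.vcf"
        export_variants(indels, snps, aln, vcf_path=vcf)
        recs = list(cyvcf2.VCF(str(vcf)))
        by_type = {}
        for r in recs:
            delta = len(r.ALT[0]) - len(r.REF)
            by_type[r.INFO.get("SVTYPE")] = (r.POS, delta)
        assert by_type["DEL"] == (100, -90)  # left-anchored at ref 100
        assert by_type["INS"][1] == 24
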