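"""Motif scanning, polymorphic-region classification, exclusivity filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from ftindelscan.alignment import call_variants, polymorphic_region_set
from ftindelscan.tfbs import (
    MotifModel,
    MotifSite,
    TfVerdict,
    classify_sites,
    exclusive_tfs,
    per_indel_report,
    revcomp,
    scan_consensus,
    scan_matrix,
)
from conftest import make_alignment


AGL15 = MotifModel("AT5G13790", "AGL15", "consensus", consensus="CARGNCAT")


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def random_matrix(rng, width=8):
    rows = []
    for _ in range(width):
        w = rng.dirichlet([1.0, 1.0, 1.0, 1.0])
        rows.append(tuple(round(float(x), 6) for x in w / w.sum()))
    # renormalise the rounding residue onto the first base
    rows = [
        (round(1.0 - sum(r[1:]), 6),) + r[1:]
        for r in rows
    ]
    return tuple(rows)


class TestScanConsensus:
    def test_degenerate_positions_match(self):
        sites = scan_consensus("s", "CAAGTCAT", AGL15)
        assert len(sites) == 1 and sites[0].score == 1.0

    def test_all_t_window_no_site(self):
        assert scan_consensus("s", "TTTTTTTT", AGL15) == []

    def test_invalid_pattern_letter_rejected(self):
        with pytest.raises(ValueError):
            MotifModel("x", "x", "consensus", consensus="CARG@CAT")

    def test_gaps_skipped_positions_mapped_to_columns(self):
        gapped = "TT--CAAG--TCATTT"
        (site,) = scan_consensus("s", gapped, AGL15)
        assert site.seq_start == 3
        assert (site.aln_start, site.aln_end) == (5, 14)

    @given(st.integers(0, 2**31))
    @settings(max_examples=60, deadline=None)
    def test_matches_word_expansion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 300)
        got = {(s.seq_start, s.strand) for s in scan_consensus("s", seq, AGL15)}
        assert got == oracles.brute_force_consensus_sites(seq, "CARGNCAT")


class TestScanMatrix:
    def test_argmax_window_scores_one(self):
        matrix = tuple((0.7, 0.1, 0.1, 0.1) for _ in range(5))
        m = MotifModel("t", "t", "matrix", matrix=matrix, threshold=0.99)
        sites = scan_matrix("s", "AAAAA", m, strands="+")
        assert len(sites) == 1 and sites[0].score == pytest.approx(1.0)

    def test_uniform_matrix_hits_everywhere(self):
        matrix = tuple((0.25, 0.25, 0.25, 0.25) for _ in range(4))
        m = MotifModel("t", "t", "matrix", matrix=matrix, threshold=1.0)
        sites = scan_matrix("s", "ACGTACG", m, strands="+")
        # every window scores 1.0 on both strands -> reported once as "both"
        assert len(sites) == 4
        assert all(s.score == pytest.approx(1.0) for s in sites)

    def test_window_with_n_skipped(self):
        matrix = tuple((0.7, 0.1, 0.1, 0.1) for _ in range(4))
        m = MotifModel("t", "t", "matrix", matrix=matrix, threshold=0.5)
        assert scan_matrix("s", "AANAA", m, strands="+") == []

    def test_unnormalised_matrix_rejected(self):
        with pytest.raises(ValueError):
            MotifModel("t", "t", "matrix", matrix=((0.5, 0.2, 0.2, 0.2),))

    @given(st.integers(0, 2**31))
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_window_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 200)
        matrix = random_matrix(rng, 8)
        m = MotifModel("t", "t", "matrix", matrix=matrix, threshold=0.80)
        got = {
            (s.seq_start, s.strand, round(s.score, 9))
            for s in scan_matrix("s", seq, m)
        }
        assert got == oracles.brute_force_matrix_sites(seq, matrix, 0.80)


class TestScanEquivalences:
    @given(st.integers(0, 2**31))
    @settings(max_examples=30, deadline=None)
    def test_consensus_equals_binary_matrix_at_threshold_one(self, seed):
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 150)
        mm = AGL15.as_matrix()
        a = {(s.seq_start, s.strand) for s in scan_consensus("s", seq, AGL15)}
        b = {(s.seq_start, s.strand) for s in scan_matrix("s", seq, mm)}
        assert a == b

    @given(st.integers(0, 2**31))
    @settings(max_examples=30, deadline=None)
    def test_strand_symmetry_under_reverse_complement(self, seed):
        """Scanning the reverse complement flips strands and mirrors starts."""
        rng = np.random.default_rng(seed)
        seq = random_seq(rng, 120)
        w = AGL15.width
        fwd = {(s.seq_start, s.strand) for s in scan_consensus("s", seq, AGL15)}
        rc = {
            (len(seq) - (s.seq_start + w - 1) + 1,
             {"+": "-", "-": "+", "both": "both"}[s.strand])
            for s in scan_consensus("s", revcomp(seq), AGL15)
        }
        assert fwd == rc


def _region_fixture():
    ref = "A" * 300
    contig = "A" * 99 + "-" * 50 + "A" * 151
    aln = make_alignment({"r": ref, "c": contig})
    indels, snps = call_variants(aln)
    return indels, snps, polymorphic_region_set(indels, snps)


class TestClassifySites:
    def _site(self, a, b, tf="t1"):
        return MotifSite(tf, "r", a, b, a, "+", 0.9)

    def test_empty_region_set_all_outside(self):
        regions = polymorphic_region_set([], [])
        out = classify_sites([self._site(5, 12)], regions)
        assert not out[0].in_polymorphic_region

    def test_partial_overlap_attaches_label(self):
        indels, snps, regions = _region_fixture()
        (site,) = classify_sites([self._site(95, 102)], regions)
        assert site.in_polymorphic_region
        assert site.indel_labels == {indels[0].label}

    def test_all_or_nothing_mode(self):
        _, _, regions = _region_fixture()
        partly, inside = classify_sites(
            [self._site(95, 102), self._site(110, 117)], regions, all_or_nothing=True
        )
        assert not partly.in_polymorphic_region and inside.in_polymorphic_region

    @given(st.integers(0, 2**31))
    @settings(max_examples=40, deadline=None)
    def test_membership_matches_per_bp_scan(self, seed):
        rng = np.random.default_rng(seed)
        intervals = [
            (a, a + int(rng.integers(0, 20)))
            for a in rng.integers(1, 200, size=4)
        ]
        points = [int(x) for x in rng.integers(1, 200, size=5)]
        sites = [
            self._site(int(a), int(a) + int(rng.integers(0, 10)))
            for a in rng.integers(1, 200, size=15)
        ]
        regions = polymorphic_region_set(
            [
                # fabricate indel-like records purely for their intervals
                type("V", (), {"aln_start": a, "aln_end": b, "label": f"iv{i}"})()
                for i, (a, b) in enumerate(intervals)
            ],
            [type("S", (), {"aln_col": p})() for p in points],
        )
        for s in classify_sites(sites, regions):
            expected = oracles.brute_force_region_membership(
                intervals, points, s.aln_start, s.aln_end
            )
            assert s.in_polymorphic_region == expected


class TestExclusiveTfs:
    def _sites(self, spec):
        # spec: list of (tf, start, inside)
        return [
            MotifSite(tf, "r", a, a + 7, a, "+", 0.9, in_polymorphic_region=inside)
            for tf, a, inside in spec
        ]

    def test_one_outside_site_breaks_exclusivity(self):
        sites = self._sites([("t1", 10, True), ("t1", 40, True), ("t1", 80, False)])
        (v,) = exclusive_tfs(sites, (1, 200))
        assert not v.exclusive and v.n_sites == 3 and v.n_in_polymorphic == 2

    def test_all_sites_inside_is_exclusive(self):
        sites = self._sites([("t1", 10, True), ("t1", 40, True)])
        (v,) = exclusive_tfs(sites, (1, 200))
        assert v.exclusive

    def test_out_of_scope_sites_ignored(self):
        # the downstream (out-of-scope) non-polymorphic site must not count
        sites = self._sites([("t1", 10, True), ("t1", 500, False)])
        (v,) = exclusive_tfs(sites, (1, 200))
        assert v.exclusive and v.n_sites == 1

    def test_monotone_in_region_set(self):
        """Enlarging the polymorphic set can only create exclusivity."""
        rng = np.random.default_rng(42)
        spec = [
            (f"t{rng.integers(1, 6)}", int(a), bool(rng.random() < 0.5))
            for a in rng.integers(1, 190, size=30)
        ]
        small = {v.tf_id: v.exclusive for v in exclusive_tfs(self._sites(spec), (1, 200))}
        grown = {
            v.tf_id: v.exclusive
            for v in exclusive_tfs(
                self._sites([(tf, a, True) for tf, a, _ in spec]), (1, 200)
            )
        }
        for tf, was_exclusive in small.items():
            assert grown[tf] or not was_exclusive

    @given(st.integers(0, 2**31))
    @settings(max_examples=40, deadline=None)
    def test_matches_per_tf_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        spec = [
            (f"t{rng.integers(1, 21)}", int(a), bool(rng.random() < 0.6))
            for a in rng.integers(1, 400, size=60)
        ]
        sites = self._sites(spec)
        got = {
            v.tf_id: (v.n_sites, v.n_in_polymorphic, v.exclusive)
            for v in exclusive_tfs(sites, (1, 300))
        }
        exp = oracles.brute_force_exclusive(
            [(s.tf_id, s.aln_start, s.aln_end, s.in_polymorphic_region) for s in sites],
            1, 300,
        )
        assert got == exp

    def test_inconsistent_verdict_rejected(self):
        with pytest.raises(ValueError):
            TfVerdict("t", 3, 2, exclusive=True)


class TestPerIndelReport:
    def _classified(self):
        return [
            MotifSite("AT5G13790", "r", 161, 168, 161, "both", 1.0,
                      in_polymorphic_region=True,
                      indel_labels=frozenset({"del_2126bp@100", "del_2388bp@120"})),
            MotifSite("AT5G13790", "r", 30, 37, 30, "+", 0.96,
                      in_polymorphic_region=True, indel_labels=frozenset({"SNP"})),
            MotifSite("OTHER", "r", 50, 57, 50, "+", 0.9,
                      in_polymorphic_region=False),
        ]

    def test_empty_flowering_list_empty_table(self):
        sites = self._classified()
        verdicts = exclusive_tfs(sites, (1, 500))
        assert per_indel_report(sites, verdicts, {}).empty

    def test_planted_exclusive_tf_reported(self):
        sites = self._classified()
        verdicts = exclusive_tfs(sites, (1, 500))
        df = per_indel_report(sites, verdicts, {"AT5G13790": "AGL15"})
        assert set(df.tf_name) == {"AGL15"} and len(df) == 2
        assert df.iloc[1].strand == "+/-"  # palindromic hit, sorted by position

    def test_deterministic_serialisation(self, tmp_path):
        sites = self._classified()
        verdicts = exclusive_tfs(sites, (1, 500))
        a = per_indel_report(sites, verdicts, {"AT5G13790": "AGL15"}).to_csv(sep="\t")
        b = per_indel_report(sites, verdicts, {"AT5G13790": "AGL15"}).to_csv(sep="\t")
        assert a == b
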