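import numpy as np
import pytest

from ploidyscope import alnio
from ploidyscope.alnio import (AlignmentRecord, DepthTrack, SamRecord,
                               assembly_stats, depth_from_alignments)


def _random_records(rng, n, n_queries=5, n_refs=5):
    out = []
    for i in range(n):
        qlen = int(rng.integers(200, 2000))
        qs = int(rng.integers(0, qlen - 1))
        qe = int(rng.integers(qs + 1, qlen + 1))
        rlen = int(rng.integers(200, 2000))
        rs = int(rng.integers(0, rlen - 1))
        re_ = int(rng.integers(rs + 1, rlen + 1))
        alnlen = max(qe - qs, re_ - rs)
        matches = int(rng.integers(alnlen // 2, alnlen + 1))
        out.append(AlignmentRecord(
            qname=f"q{int(rng.integers(n_queries))}", qlen=qlen, qstart=qs, qend=qe,
            strand="+" if rng.random() < 0.5 else "-",
            rname=f"r{int(rng.integers(n_refs))}", rlen=rlen, rstart=rs, rend=re_,
            matches=matches, alnlen=alnlen,
            mapq=int(rng.integers(0, 61)), is_secondary=bool(rng.random() < 0.2),
            nm=int(rng.integers(0, 10))))
    return out


class TestAlignmentRecord:
    def test_identity_from_matches(self):
        r = AlignmentRecord("q", 100, 0, 100, "+", "r", 200, 0, 100, 96, 100)
        assert r.identity == pytest.approx(0.96)

    @pytest.mark.parametrize("kw", [
        {"qstart": 50, "qend": 40}, {"qend": 150}, {"rstart": -1},
        {"matches": 200}, {"strand": "x"},
    ])
    def test_invariants_rejected(self, kw):
        base = dict(qname="q", qlen=100, qstart=0, qend=100, strand="+",
                    rname="r", rlen=100, rstart=0, rend=100, matches=90, alnlen=100)
        base.update(kw)
        with pytest.raises(ValueError):
            AlignmentRecord(**base)


class TestPafRoundTrip:
    def test_random_records_identical(self, tmp_path):
        rng = np.random.default_rng(0)
        recs = _random_records(rng, 1000)
        p = tmp_path / "x.paf"
        alnio.write_paf(recs, p)
        back = alnio.read_paf(p)
        assert back == recs

    def test_malformed_line_names_lineno(self, tmp_path):
        p = tmp_path / "bad.paf"
        p.write_text("q\t100\t0\t50\t+\tr\t100\n")
        with pytest.raises(alnio.MalformedLineError, match="1"):
            alnio.read_paf(p)


class TestCoords:
    def test_one_based_inclusive_converted(self, tmp_path):
        p = tmp_path / "c.coords"
        p.write_text("[S1]\t[E1]\t[S2]\t[E2]\t...\n"
                     "1\t100\t1\t100\t100\t100\t96.00\t500\t400\tref1\tqry1\n")
        (r,) = alnio.read_coords(p)
        assert (r.rstart, r.rend, r.qstart, r.qend) == (0, 100, 0, 100)
        assert r.strand == "+"
        assert r.identity == pytest.approx(0.96)

    def test_reverse_strand_normalised(self, tmp_path):
        p = tmp_path / "c.coords"
        p.write_text("10\t100\t200\t101\t91\t100\t95.00\t500\t400\tref1\tqry1\n")
        (r,) = alnio.read_coords(p)
        assert r.strand == "-"
        assert r.qstart < r.qend
        assert (r.qstart, r.qend) == (100, 200)

    def test_round_trip_preserves_geometry(self, tmp_path):
        rng = np.random.default_rng(1)
        recs = [r for r in _random_records(rng, 300)]
        p = tmp_path / "x.coords"
        alnio.write_coords(recs, p)
        back = alnio.read_coords(p)
        assert len(back) == len(recs)
        for a, b in zip(recs, back):
            assert (a.qname, a.qstart, a.qend,
                    a.rname, a.rstart, a.rend, a.qlen, a.rlen) == \
                   (b.qname, b.qstart, b.qend,
                    b.rname, b.rstart, b.rend, b.qlen, b.rlen)
            if a.query_span > 1:  # 1 bp intervals cannot encode strand
                assert a.strand == b.strand
            assert a.identity == pytest.approx(b.identity, abs=1e-3)

    def test_missing_lengths_require_dicts(self, tmp_path):
        p = tmp_path / "c.coords"
        p.write_text("1\t100\t1\t100\t100\t100\t96.00\tref1\tqry1\n")
        with pytest.raises(alnio.MalformedLineError):
            alnio.read_coords(p)
        (r,) = alnio.read_coords(p, ref_lengths={"ref1": 500},
                                 query_lengths={"qry1": 400})
        assert r.rlen == 500 and r.qlen == 400


class TestSam:
    def test_write_read_round_trip(self, tmp_path, sim400):
        aln = sim400["aln"]
        p = tmp_path / "x.sam"
        aln.write_sam(p)
        back = alnio.read_sam(p)
        assert len(back) == len(aln.records)
        for a, b in zip(aln.records[:500], back[:500]):
            assert (a.qname, a.flag, a.rname, a.pos, a.cigar, a.nm) == \
                   (b.qname, b.flag, b.rname, b.pos, b.cigar, b.nm)

    def test_reference_span_from_cigar(self):
        r = SamRecord("q", 0, "r", 10, 60, "5S20M2D3I10M4S", nm=5)
        assert r.reference_span == 20 + 2 + 10
        assert r.aligned_read_bases == 20 + 3 + 10
        assert r.rend == 10 + 32


class TestDepthFromAlignments:
    def _rec(self, rname, rlen, rs, re_, secondary=False):
        return AlignmentRecord("q", re_ - rs, 0, re_ - rs, "+", rname, rlen,
                               rs, re_, re_ - rs, re_ - rs,
                               is_secondary=secondary)

    def test_single_interval(self):
        t = depth_from_alignments([self._rec("c", 20, 0, 10)], {"c": 20})
        assert t["c"][:10].tolist() == [1] * 10
        assert t["c"][10:].tolist() == [0] * 10

    def test_overlap_adds(self):
        t = depth_from_alignments(
            [self._rec("c", 20, 0, 10), self._rec("c", 20, 5, 15)], {"c": 20})
        assert t["c"][5:10].tolist() == [2] * 5

    def test_secondary_excluded_by_default(self):
        t = depth_from_alignments(
            [self._rec("c", 20, 0, 10, secondary=True)], {"c": 20})
        assert int(t["c"].sum()) == 0

    def test_matches_per_base_counting_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            L = int(rng.integers(50, 400))
            recs = []
            for _ in range(int(rng.integers(1, 40))):
                s = int(rng.integers(0, L - 1))
                e = int(rng.integers(s + 1, L + 1))
                recs.append(self._rec("c", L, s, e))
            t = depth_from_alignments(recs, {"c": L})
            oracle = np.array([sum(r.rstart <= b < r.rend for r in recs)
                               for b in range(L)])
            assert np.array_equal(t["c"], oracle)

    def test_beyond_contig_rejected(self):
        with pytest.raises(ValueError):
            depth_from_alignments([self._rec("c", 5, 0, 10)], {"c": 5})


class TestDepthIO:
    def test_bedgraph_runs_maximal(self, tmp_path):
        t = DepthTrack({"c": np.array([1, 1, 1, 2])})
        p = tmp_path / "x.bg"
        alnio.write_bedgraph(t, p)
        rows = [l.split("\t") for l in p.read_text().splitlines()]
        assert rows == [["c", "0", "3", "1"], ["c", "3", "4", "2"]]

    def test_round_trips(self, tmp_path):
        rng = np.random.default_rng(4)
        t = DepthTrack({f"c{i}": rng.integers(0, 8, int(rng.integers(5, 60)))
                        for i in range(4)})
        p1, p2 = tmp_path / "d.tsv", tmp_path / "d.bg"
        alnio.write_depth_tsv(t, p1)
        alnio.write_bedgraph(t, p2)
        assert alnio.read_depth_tsv(p1, t.contig_lengths) == t
        assert alnio.read_bedgraph(p2, t.contig_lengths) == t

    def test_adjacent_equal_rows_merge(self, tmp_path):
        p = tmp_path / "m.bg"
        p.write_text("c\t0\t2\t5\nc\t2\t4\t5\n")
        t = alnio.read_bedgraph(p)
        assert t["c"].tolist() == [5, 5, 5, 5]

    def test_overlapping_bedgraph_rejected(self, tmp_path):
        p = tmp_path / "o.bg"
        p.write_text("c\t0\t3\t5\nc\t2\t4\t6\n")
        with pytest.raises(ValueError, match="overlap"):
            alnio.read_bedgraph(p)


class TestAssemblyStats:
    def test_singleton(self):
        assert assembly_stats([8]).n50 == 8

    def test_tie_case(self):
        s = assembly_stats([5, 5])
        assert s.n50 == 5 and s.span == 10 and s.max_contig == 5

    def test_against_sorted_prefix_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            lengths = rng.integers(1, 500, int(rng.integers(1, 40))).tolist()
            s = assembly_stats(lengths)
            span = sum(lengths)
            candidates = [L for L in sorted(set(lengths), reverse=True)
                          if sum(x for x in lengths if x >= L) >= span / 2]
            assert s.n50 == max(candidates)
            assert s.n50 <= s.max_contig <= s.span

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assembly_stats([])


from hypothesis import given, settings, strategies as st


class TestHypothesisProperties:

    @given(st.lists(st.integers(min_value=1, max_value=10_000), min_size=1,
                    max_size=60))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_n50_definition_holds(self, lengths):
        s = assembly_stats(lengths)
        span = sum(lengths)
        # contigs >= n50 cover at least half the span...
        assert sum(x for x in lengths if x >= s.n50) >= span / 2
        # ...and no larger contig length qualifies
        bigger = [x for x in set(lengths) if x > s.n50]
        for L in bigger:
            assert sum(x for x in lengths if x >= L) < span / 2
        assert s.n50 <= s.max_contig <= s.span

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=1,
                    max_size=300))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_bedgraph_round_trip_lossless(self, values):
        import tempfile
        from pathlib import Path

        track = DepthTrack({"c": np.asarray(values)})
        with tempfile.TemporaryDirectory() as d:
            p = Path(d) / "x.bg"
            alnio.write_bedgraph(track, p)
            assert alnio.read_bedgraph(p, track.contig_lengths) == track
            # runs written are maximal: no two adjacent rows share a value
            rows = [l.split("\t") for l in p.read_text().splitlines()]
        for r1, r2 in zip(rows, rows[1:]):
            assert r1[3] != r2[3]
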