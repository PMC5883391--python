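import edlib
import numpy as np
import pytest

from ploidyscope import alnio, synthio
from ploidyscope.synthio import (ReadSimConfig, SyntheticGenomeConfig, decode,
                                 generate_assembly, generate_diploid_genome,
                                 simulate_reads, truth_align)


def _plain_cfg(**kw):
    base = dict(haploid_size=200_000, het_rate=0.0, repeat_fraction=0.0, seed=5)
    base.update(kw)
    return SyntheticGenomeConfig(**base)


class TestGenome:
    def test_zero_het_haplotypes_identical(self):
        a, b, truth = generate_diploid_genome(_plain_cfg())
        assert np.array_equal(a["chr1"], b["chr1"])
        assert truth.snv_pos.size == 0 and truth.indel_pos.size == 0

    def test_het_event_count_binomial(self):
        cfg = SyntheticGenomeConfig(haploid_size=1_000_000, het_rate=0.005,
                                    repeat_fraction=0.0, seed=7)
        a, b, truth = generate_diploid_genome(cfg)
        n_events = truth.snv_pos.size + truth.indel_pos.size
        expect = 0.005 * 1_000_000
        sd = np.sqrt(1_000_000 * 0.005 * 0.995)
        assert abs(n_events - expect) <= 4 * sd

    def test_divergence_matches_edit_distance_oracle(self):
        # independent check of the het bookkeeping: edlib edit distance
        # between the haplotypes ~ SNV count + indel bases
        cfg = SyntheticGenomeConfig(haploid_size=100_000, het_rate=0.004,
                                    repeat_fraction=0.0, seed=11)
        a, b, truth = generate_diploid_genome(cfg)
        dist = edlib.align(decode(a["chr1"]), decode(b["chr1"]))["editDistance"]
        booked = truth.snv_pos.size + int(truth.indel_len.sum())
        assert dist <= booked  # minimum edit distance cannot exceed it
        assert dist >= 0.97 * booked  # and coincidental savings are rare

    def test_seed_determinism_fasta_bytes(self, tmp_path):
        cfg = SyntheticGenomeConfig(haploid_size=100_000, seed=9)
        p1, p2 = tmp_path / "a1.fa", tmp_path / "a2.fa"
        for p in (p1, p2):
            a, b, _ = generate_diploid_genome(cfg)
            synthio.write_genome_fasta(a, p)
        assert p1.read_bytes() == p2.read_bytes()

    def test_repeat_copies_identical_within_family(self):
        cfg = SyntheticGenomeConfig(haploid_size=200_000, het_rate=0.0,
                                    repeat_fraction=0.2,
                                    repeat_family_count=2,
                                    repeat_unit_len=5_000, seed=3)
        a, _, truth = generate_diploid_genome(cfg)
        rep = np.flatnonzero(truth.loci_kind == 1)
        fam0 = rep[truth.loci_family[rep] == 0]
        assert fam0.size >= 2
        s0 = a["chr1"][truth.loci_start[fam0[0]]:truth.loci_end[fam0[0]]]
        s1 = a["chr1"][truth.loci_start[fam0[1]]:truth.loci_end[fam0[1]]]
        assert np.array_equal(s0, s1)

    def test_infeasible_sizing_rejected(self):
        with pytest.raises(ValueError):
            SyntheticGenomeConfig(haploid_size=10_000, repeat_fraction=0.5,
                                  repeat_unit_len=8000,
                                  repeat_family_count=4).validate()

    @pytest.mark.parametrize("kw", [{"het_rate": 0.2}, {"haploid_size": 0},
                                    {"repeat_fraction": 1.0}])
    def test_config_invariants(self, kw):
        with pytest.raises(ValueError):
            generate_diploid_genome(_plain_cfg(**kw))


class TestAssembly:
    def test_all_collapsed_span_equals_haploid(self):
        a, b, truth = generate_diploid_genome(_plain_cfg())
        contigs, _ = generate_assembly(a, b, truth, state_plan={"COLLAPSED": 1.0})
        assert sum(len(s) for s in contigs.values()) == truth.true_haploid_size

    def test_full_separation_doubles_span(self):
        cfg = _plain_cfg(het_rate=0.005, haploid_size=300_000)
        a, b, truth = generate_diploid_genome(cfg)
        contigs, _ = generate_assembly(a, b, truth, state_plan={"HAP_SEP": 1.0})
        span = sum(len(s) for s in contigs.values())
        assert abs(span - 2 * truth.true_haploid_size) <= 0.01 * truth.true_haploid_size

    def test_mixed_plan_span_ratio(self):
        cfg = _plain_cfg(haploid_size=1_000_000, het_rate=0.0)
        a, b, truth = generate_diploid_genome(cfg)
        contigs, _ = generate_assembly(
            a, b, truth, state_plan={"HAP_SEP": 0.6, "COLLAPSED": 0.4})
        ratio = sum(len(s) for s in contigs.values()) / truth.true_haploid_size
        assert 1.55 <= ratio <= 1.65

    def test_state_bed_conserves_assembly_span(self, sim400):
        bed_total = sum(e - s for _, s, e, _ in sim400["state_bed"])
        assert bed_total == sim400["truth"].assembly.span

    def test_state_bed_intervals_disjoint_sorted(self, sim400):
        by_contig = {}
        for c, s, e, _ in sim400["state_bed"]:
            by_contig.setdefault(c, []).append((s, e))
        for name, ivals in by_contig.items():
            for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
                assert e1 == s2  # contiguous, non-overlapping, sorted

    def test_bad_plan_rejected(self):
        a, b, truth = generate_diploid_genome(_plain_cfg())
        with pytest.raises(ValueError):
            generate_assembly(a, b, truth, state_plan={"HAP_SEP": 0.6})
        with pytest.raises(ValueError):
            generate_assembly(a, b, truth, state_plan={"HAP_SEP": 1.4,
                                                       "COLLAPSED": -0.4})


class TestReads:
    def test_total_bases_tracks_depth(self):
        cfg = _plain_cfg(haploid_size=1_000_000)
        a, b, truth = generate_diploid_genome(cfg)
        reads = simulate_reads((a, b), ReadSimConfig(platform="long", depth=10,
                                                     seed=2),
                               with_sequences=False)
        assert 1.9e7 <= reads.total_bases <= 2.1e7

    def test_error_free_reads_are_exact_substrings(self):
        cfg = _plain_cfg(haploid_size=60_000, het_rate=0.004)
        a, b, truth = generate_diploid_genome(cfg)
        reads = simulate_reads((a, b), ReadSimConfig(platform="long", depth=2,
                                                     long_len_mean=800, seed=4))
        src = (a["chr1"], b["chr1"])
        for i in range(len(reads)):
            origin = src[reads.hap[i]][reads.start[i]:reads.end[i]]
            if reads.rev[i]:
                origin = synthio.revcomp(origin)
            assert reads.seqs[i] == decode(origin)

    def test_paired_mates_equal_counts(self, tmp_path):
        cfg = _plain_cfg(haploid_size=50_000)
        a, b, _ = generate_diploid_genome(cfg)
        reads = simulate_reads((a, b), ReadSimConfig(platform="short_paired",
                                                     depth=3, seed=6))
        p1, p2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        synthio.write_fastq(reads, p1, mate=1)
        synthio.write_fastq(reads, p2, mate=2)
        n1 = p1.read_text().count("\n") // 4
        n2 = p2.read_text().count("\n") // 4
        assert n1 == n2 == len(reads) // 2

    def test_fastq_bytes_deterministic(self, tmp_path):
        cfg = _plain_cfg(haploid_size=50_000)
        a, b, _ = generate_diploid_genome(cfg)
        paths = []
        for tag in ("x", "y"):
            reads = simulate_reads((a, b), ReadSimConfig(platform="long", depth=2,
                                                         long_len_mean=500,
                                                         error_rate=0.01, seed=8))
            p = tmp_path / f"{tag}.fq"
            synthio.write_fastq(reads, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_degenerate_long_reads_rejected(self):
        cfg = _plain_cfg(haploid_size=1_000)
        a, b, _ = generate_diploid_genome(cfg)
        with pytest.raises(ValueError, match="long_len_mean"):
            simulate_reads((a, b), ReadSimConfig(platform="long", depth=2,
                                                 long_len_mean=5_000, seed=1))


class TestTruthAlign:
    def test_collapsed_locus_pair_is_proper_single_site(self):
        cfg = _plain_cfg(haploid_size=100_000)
        a, b, truth = generate_diploid_genome(cfg)
        generate_assembly(a, b, truth, state_plan={"COLLAPSED": 1.0})
        reads = simulate_reads((a, b), ReadSimConfig(platform="short_paired",
                                                     depth=2, seed=3),
                               with_sequences=False)
        aln = truth_align(reads, truth)
        primaries = [r for r in aln.records if not r.is_secondary]
        interior = [r for r in primaries
                    if 2000 < r.pos < 97_000 and not r.is_unmapped]
        assert interior and all(r.is_proper_pair for r in interior)
        assert not any(r.is_secondary for r in aln.records)

    def test_repeat_read_gets_one_placement_per_surviving_copy(self, sim_paired):
        truth = sim_paired["truth"]
        aln = sim_paired["aln"]
        reads = sim_paired["reads"]
        # find a read wholly inside a repeat copy of a 3-survivor family
        by_name = {}
        for r in aln.records:
            by_name.setdefault((r.qname, r.is_read1), []).append(r)
        mids = (reads.start + reads.end) // 2
        a_lo = np.where(reads.hap == 1, truth.b2a(reads.start), reads.start)
        a_hi = np.where(reads.hap == 1, truth.b2a(reads.end), reads.end)
        loc = np.searchsorted(truth.loci_start, (a_lo + a_hi) // 2, side="right") - 1
        found = 0
        for i in range(len(reads)):
            k = loc[i]
            if truth.loci_kind[k] == 1 and a_lo[i] >= truth.loci_start[k] \
                    and a_hi[i] <= truth.loci_end[k]:
                recs = by_name[(reads.name(i), reads.mate[i] == 1)]
                n_surv = len(truth.assembly.survivors[int(truth.loci_family[k])])
                assert len(recs) == n_surv == 3
                assert sum(not r.is_secondary for r in recs) == 1
                found += 1
                if found > 20:
                    break
        assert found > 0

    def test_read_from_deleted_locus_unmapped(self):
        cfg = SyntheticGenomeConfig(haploid_size=100_000, het_rate=0.0,
                                    repeat_fraction=0.1, repeat_family_count=1,
                                    repeat_unit_len=5_000, seed=21)
        a, b, truth = generate_diploid_genome(cfg)
        generate_assembly(a, b, truth, survivors_per_family=0)
        reads = simulate_reads((a, b), ReadSimConfig(platform="long", depth=3,
                                                     long_len_mean=400, seed=2),
                               with_sequences=False)
        aln = truth_align(reads, truth)
        # reads wholly inside any repeat copy have nowhere to go
        mids = (reads.start + reads.end) // 2
        rep = np.flatnonzero(truth.loci_kind == 1)
        n_checked = 0
        for i in range(len(reads)):
            if reads.hap[i] != 0:
                continue
            k = int(np.searchsorted(truth.loci_start, mids[i], side="right")) - 1
            if truth.loci_kind[k] == 1 and reads.start[i] >= truth.loci_start[k] \
                    and reads.end[i] <= truth.loci_end[k]:
                assert aln.prim_ctg[i] == -1
                n_checked += 1
        assert n_checked > 0
        assert aln.n_unmapped >= n_checked

    def test_depth_consistent_between_sam_and_placements(self, sim_paired):
        aln = sim_paired["aln"]
        d_records = alnio.depth_from_alignments(aln.records, aln.contig_lengths)
        assert d_records == aln.depth()

    def test_sam_bytes_deterministic(self, tmp_path, sim400):
        truth = sim400["truth"]
        p1, p2 = tmp_path / "a.sam", tmp_path / "b.sam"
        for p in (p1, p2):
            reads = simulate_reads((sim400["hap_a"], sim400["hap_b"]),
                                   ReadSimConfig(platform="long", depth=2,
                                                 seed=99),
                                   with_sequences=False)
            truth_align(reads, truth).write_sam(p)
        assert p1.read_bytes() == p2.read_bytes()

    def test_nm_matches_true_hamming_distance(self):
        # NM bookkeeping vs actual sequence comparison on collapsed contigs
        cfg = _plain_cfg(haploid_size=80_000, het_rate=0.003)
        a, b, truth = generate_diploid_genome(cfg)
        contigs, _ = generate_assembly(a, b, truth, state_plan={"COLLAPSED": 1.0})
        reads = simulate_reads((a, b), ReadSimConfig(platform="short_paired",
                                                     depth=2, error_rate=0.01,
                                                     seed=5))
        aln = truth_align(reads, truth)
        ref = contigs["ctgA_0000"]
        checked = total_nm = total_ham = 0
        for i, r in enumerate([r for r in aln.records if not r.is_secondary]):
            if r.is_unmapped or "S" in r.cigar or any(
                    op in r.cigar for op in "ID"):
                continue
            seq = reads.seqs[i]
            if reads.rev[i]:
                seq = synthio._revcomp_str(seq)
            target = decode(ref[r.pos:r.pos + len(seq)])
            ham = sum(x != y for x, y in zip(seq, target))
            # NM is the generative count; an error landing on a het site is
            # booked twice but observed at most once, so NM >= hamming with
            # a small aggregate excess
            assert r.nm >= ham
            total_nm += r.nm
            total_ham += ham
            checked += 1
            if checked > 300:
                break
        assert checked > 100
        assert total_nm - total_ham <= 0.02 * total_nm
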