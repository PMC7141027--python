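"""Generator correctness: libraries, genotypes, reads, truth SAM/VCF."""

import numpy as np
import pysam
import pytest

from tecensus import (
    emit_truth_alignments,
    emit_truth_variants,
    load_alignments,
    make_genotype,
    make_te_library,
    sequence_reads,
)
from tecensus.simulate import ReadSet, codes_to_str, _revcomp

from _oracles import majority_recount


class TestLibrary:
    def test_single_family(self):
        lib = make_te_library(1, (500, 500), seed=1)
        assert lib.names == ["TE001"]
        assert len(lib.sequence("TE001")) == 500

    def test_seed_determinism(self):
        a = make_te_library(10, (500, 5000), seed=7)
        b = make_te_library(10, (500, 5000), seed=7)
        assert a.entries == b.entries

    def test_no_shared_read_length_kmer(self):
        lib = make_te_library(2, (1000, 1000), seed=3, unique_kmer=100)
        s1, s2 = lib.sequence("TE001"), lib.sequence("TE002")
        k1 = {s1[i:i + 100] for i in range(len(s1) - 99)}
        k2 = {s2[i:i + 100] for i in range(len(s2) - 99)}
        assert not (k1 & k2)

    def test_invalid_constraints(self):
        with pytest.raises(ValueError):
            make_te_library(0, (500, 500), seed=1)
        with pytest.raises(ValueError):
            make_te_library(1, (50, 80), seed=1)


class TestGenotype:
    def test_zero_copies_leave_no_trace(self, library3):
        genome, truth = make_genotype(
            library3, {"TE001": 0}, genome_length=20_000, seed=5)
        assert truth.true_copy_count("TE001") == 0
        assert library3.sequence("TE001") not in codes_to_str(genome)

    def test_exact_copies_findable(self, library3):
        genome, truth = make_genotype(
            library3, {"TE002": 5}, genome_length=50_000, seed=6)
        text = codes_to_str(genome)
        consensus = library3.sequence("TE002")
        count = 0
        start = 0
        while (hit := text.find(consensus, start)) != -1:
            count += 1
            start = hit + 1
        assert count == 5
        assert truth.true_copy_count("TE002") == 5

    def test_forced_degradation_marks_not_full_length(self, library3):
        L = len(library3.sequence("TE001"))
        keep = int(0.4 * L)
        genome, truth = make_genotype(
            library3, {"TE001": 1}, genome_length=20_000, seed=5,
            deletion_sampler=lambda rng, n: (keep, n))
        (copy,) = truth.copies
        assert copy.full_length is False
        assert copy.deleted_interval == (keep, L)
        assert copy.length == keep
        # the copy's sequence is exactly the kept consensus prefix
        s, e = copy.genome_span
        assert codes_to_str(genome[s:e]) == library3.sequence("TE001")[:keep]

    def test_unknown_family_rejected(self, library3):
        with pytest.raises(KeyError):
            make_genotype(library3, {"nope": 1}, genome_length=20_000, seed=1)

    def test_overfull_genome_rejected(self, library3):
        with pytest.raises(ValueError):
            make_genotype(library3, {"TE001": 50}, genome_length=10_000, seed=1)

    def test_divergence_snps_recorded_as_exact_diffs(self, library3):
        genome, truth = make_genotype(
            library3, {"TE003": 2}, divergence=0.01, genome_length=30_000,
            seed=9)
        consensus = library3.codes("TE003")
        for copy in truth.copies:
            s, e = copy.genome_span
            seq = genome[s:e]
            diffs = np.flatnonzero(seq != consensus)
            assert [p for p, _ in copy.divergence_snps] == list(diffs)
            for p, b in copy.divergence_snps:
                assert codes_to_str(seq[p:p + 1]) == b

    def test_seed_determinism(self, library3):
        a = make_genotype(library3, {"TE001": 3}, divergence=0.01,
                          genome_length=30_000, seed=4)
        b = make_genotype(library3, {"TE001": 3}, divergence=0.01,
                          genome_length=30_000, seed=4)
        assert np.array_equal(a[0], b[0])
        assert a[1].copies == b[1].copies


class TestReads:
    def test_expected_count(self, library3):
        genome, truth = make_genotype(
            library3, {"TE001": 2}, genome_length=100_000, seed=1)
        reads = sequence_reads(genome, truth, depth=20, read_length=100,
                               seed=2)
        expected = 20 * len(genome) / 100
        assert abs(len(reads) - expected) < 5 * np.sqrt(expected)
        fixed = sequence_reads(genome, truth, depth=20, read_length=100,
                               seed=2, count_model="fixed")
        assert len(fixed) == round(expected)

    def test_error_free_reads_match_genome(self, library3):
        genome, truth = make_genotype(
            library3, {"TE001": 1}, genome_length=20_000, seed=1)
        reads = sequence_reads(genome, truth, depth=5, seed=3, error_rate=0.0)
        for i in range(0, len(reads), 37):
            src = genome[reads.starts[i]:reads.starts[i] + reads.read_length]
            got = reads.sequences[i]
            if reads.strands[i] == 1:
                got = _revcomp(got)
            assert np.array_equal(got, src)

    def test_error_rate_mean_mismatches(self, library3):
        genome, truth = make_genotype(
            library3, {"TE001": 1}, genome_length=200_000, seed=1)
        reads = sequence_reads(genome, truth, depth=5, seed=4,
                               error_rate=0.01, count_model="fixed")
        src = genome[reads.starts[:, None] + np.arange(reads.read_length)]
        got = reads.sequences.copy()
        rev = reads.strands == 1
        got[rev] = _revcomp(got[rev])
        mean_mm = (got != src).sum(axis=1).mean()
        assert abs(mean_mm - 1.0) < 0.1

    def test_preconditions(self, library3):
        genome, truth = make_genotype(
            library3, {"TE001": 1}, genome_length=20_000, seed=1)
        with pytest.raises(ValueError):
            sequence_reads(genome, truth, depth=0, seed=1)
        with pytest.raises(ValueError):
            sequence_reads(genome, truth, depth=1,
                           read_length=len(genome) + 1, seed=1)


class TestTruthAlignments:
    def test_conservation_one_record_per_read(self, small_mapped_genotype):
        _, _, reads, aln = small_mapped_genotype
        assert len(aln) == len(reads)

    def test_interior_read_coordinates(self, library3):
        genome, truth = make_genotype(
            library3, {"TE001": 1}, genome_length=20_000, seed=2)
        (copy,) = truth.copies
        s, _ = copy.genome_span
        # one read fully inside the copy at consensus offset 250
        start = np.array([s + 250])
        reads = ReadSet(
            genotype_id="gX", read_length=100, error_rate=0.0,
            starts=start, strands=np.array([0], dtype=np.uint8),
            sequences=genome[start[0]:start[0] + 100][None, :],
            is_duplicate=np.array([False]))
        aln = emit_truth_alignments(reads, truth, library3)
        assert aln.ref_names[int(aln.ref_index[0])] == "TE001"
        assert int(aln.pos0[0]) == 250
        assert int(aln.mapq[0]) == 60

    def test_junction_read_gets_mapq0(self, library3):
        genome, truth = make_genotype(
            library3, {"TE001": 1}, genome_length=20_000, seed=2)
        (copy,) = truth.copies
        s, _ = copy.genome_span
        start = np.array([s - 50])  # straddles the insertion junction
        reads = ReadSet(
            genotype_id="gX", read_length=100, error_rate=0.0,
            starts=start, strands=np.array([0], dtype=np.uint8),
            sequences=genome[start[0]:start[0] + 100][None, :],
            is_duplicate=np.array([False]))
        aln = emit_truth_alignments(reads, truth, library3)
        assert int(aln.mapq[0]) == 0
        assert int(aln.aligned_len[0]) == 50  # clipped at the junction

    def test_sam_round_trip(self, small_mapped_genotype, library3, tmp_path):
        from tecensus import depth_profile, filter_truth_alignments
        _, _, reads, aln = small_mapped_genotype
        path = tmp_path / "gS.sam"
        aln.to_sam(path)
        # parses under pysam and reproduces the in-memory filter result
        loaded = load_alignments(path)
        fast = filter_truth_alignments(aln)
        assert loaded.references == fast.references
        for ref in loaded.references:
            assert loaded.n_on(ref) == fast.n_on(ref)
            assert np.array_equal(depth_profile(loaded, ref).depth,
                                  depth_profile(fast, ref).depth)
        # every record is parseable with valid coordinates
        with pysam.AlignmentFile(str(path)) as af:
            n = 0
            for rec in af:
                n += 1
                assert 0 <= rec.reference_start
                assert rec.reference_end <= af.get_reference_length(
                    rec.reference_name)
            assert n == len(reads)

    def test_sam_bytes_deterministic(self, small_mapped_genotype, tmp_path):
        _, _, _, aln = small_mapped_genotype
        aln.to_sam(tmp_path / "a.sam")
        aln.to_sam(tmp_path / "b.sam")
        assert (tmp_path / "a.sam").read_bytes() == (tmp_path / "b.sam").read_bytes()


class TestTruthVariants:
    def test_zero_divergence_empty(self, library3):
        truths = [make_genotype(library3, {"TE001": 2}, genome_length=20_000,
                                seed=s)[1] for s in (1, 2)]
        tv = emit_truth_variants(truths, library3)
        assert tv.records == []

    def test_fixed_site_frequency_one(self, library3):
        # the same shared SNPs in all copies of all genotypes: seed the
        # haplotype identically by reusing one genotype's copies
        genome, truth = make_genotype(
            library3, {"TE001": 3}, shared_divergence=0.005,
            genome_length=20_000, seed=13, genotype_id="gA")
        import dataclasses
        truth_b = dataclasses.replace(truth, genotype_id="gB")
        tv = emit_truth_variants([truth, truth_b], library3)
        assert tv.records
        for _, _, _, _, gt, _ in tv.records:
            assert (gt == 1).all()  # every genotype alt: fixed difference

    def test_frequencies_match_bruteforce_recount(self, diverged_panel,
                                                  library3):
        tv = emit_truth_variants(diverged_panel, library3)
        oracle = majority_recount(diverged_panel, library3)
        seen = set()
        for fam, pos0, _, alts, gt, _ in tv.records:
            entry = oracle[fam][pos0]
            seen.add((fam, pos0))
            assert set(alts) == entry["_alts"]
            for gi, truth in enumerate(diverged_panel):
                expect = entry[truth.genotype_id]
                if expect == "missing":
                    assert gt[gi] == -1
                elif expect == "ref":
                    assert gt[gi] == 0
                else:
                    assert gt[gi] >= 1
        # no variant position missed
        for fam, table in oracle.items():
            assert {(fam, p) for p in table} <= seen
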