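"""SNP loading, site frequencies, SFS summaries, and Tajima's D."""

import numpy as np
import pytest

from tecensus import (
    average_sfs,
    call_snps_pileup,
    classify_fixed,
    load_vcf,
    sfs_histogram,
    sfs_summary,
    site_frequency,
    tajimas_d,
    tajimas_d_windows,
)
from tecensus.sfs import SnpTable, SiteBlock

from _oracles import tajima_oracle


def write_vcf(path, body_lines, samples=("s1", "s2", "s3", "s4")):
    header = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=TEa,length=2000>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    path.write_text("\n".join(header + body_lines) + "\n")
    return path


class TestLoadVcf:
    def test_depth_filter_boundary(self, tmp_path):
        path = write_vcf(tmp_path / "a.vcf", [
            "TEa\t10\t.\tA\tG\t.\tPASS\t.\tGT:DP\t1/1:3\t1/1:4\t0/0:10\t./.:.",
        ])
        snp = load_vcf(path, min_depth=4)
        block = snp.blocks["TEa"]
        assert np.isnan(block.calls[0, 0])       # depth 3 -> missing
        assert block.calls[0, 1] == 1.0          # depth 4 -> retained
        assert block.calls[0, 2] == 0.0
        assert np.isnan(block.calls[0, 3])

    def test_triallelic_and_indels_dropped(self, tmp_path):
        path = write_vcf(tmp_path / "b.vcf", [
            "TEa\t10\t.\tA\tG,T\t.\tPASS\t.\tGT:DP\t1/1:9\t2/2:9\t0/0:9\t0/0:9",
            "TEa\t20\t.\tAT\tA\t.\tPASS\t.\tGT:DP\t1/1:9\t0/0:9\t0/0:9\t0/0:9",
            "TEa\t30\t.\tA\tC\t.\tPASS\t.\tGT:DP\t1/1:9\t0/0:9\t0/0:9\t0/0:9",
        ])
        snp = load_vcf(path)
        assert snp.blocks["TEa"].positions.tolist() == [30]

    def test_all_missing_site_dropped(self, tmp_path):
        path = write_vcf(tmp_path / "c.vcf", [
            "TEa\t10\t.\tA\tG\t.\tPASS\t.\tGT:DP\t./.:.\t./.:.\t./.:.\t./.:.",
        ])
        snp = load_vcf(path)
        assert "TEa" not in snp.blocks

    def test_het_counts_half(self, tmp_path):
        path = write_vcf(tmp_path / "d.vcf", [
            "TEa\t10\t.\tA\tG\t.\tPASS\t.\tGT:DP\t0/1:9\t1/1:9\t0/0:9\t0/0:9",
        ])
        snp = load_vcf(path)
        assert snp.frequencies("TEa")[0] == pytest.approx(1.5 / 4)

    def test_truth_vcf_round_trip(self, truth_vcf, diverged_panel, library3):
        """Truth-VCF frequencies equal the brute-force truth recount."""
        from _oracles import majority_recount
        snp = load_vcf(truth_vcf)
        oracle = majority_recount(diverged_panel, library3)
        gids = [t.genotype_id for t in diverged_panel]
        assert snp.genotypes == gids
        for fam, block in snp.blocks.items():
            freqs = snp.frequencies(fam)
            for pos1, f in zip(block.positions, freqs):
                entry = oracle[fam][pos1 - 1]
                if len(entry["_alts"]) > 1:
                    continue  # multi-allelic records are dropped on load
                n_alt = sum(entry[g] == "alt" for g in gids)
                n_called = sum(entry[g] != "missing" for g in gids)
                assert f == pytest.approx(n_alt / n_called)


class TestPileupCaller:
    def _aligned(self, library3, spec, seed, **kwargs):
        from tecensus import (
            emit_truth_alignments, make_genotype, sequence_reads,
        )
        out = {}
        for gid, (s, sd) in spec.items():
            genome, truth = make_genotype(
                library3, s, genome_length=40_000, seed=sd,
                genotype_id=gid, **kwargs)
            reads = sequence_reads(genome, truth, depth=25, seed=sd + 1,
                                   error_rate=0.0)
            out[gid] = emit_truth_alignments(reads, truth, library3)
        return out

    def test_zero_divergence_calls_nothing(self, library3):
        aligned = self._aligned(library3, {"gA": ({"TE001": 2}, 3)}, 3)
        snp = call_snps_pileup(aligned, library3)
        assert snp.blocks == {}

    def test_homozygous_snp_called(self, library3):
        aligned = self._aligned(
            library3, {"gA": ({"TE001": 2}, 3), "gB": ({"TE001": 2}, 5)},
            3, shared_divergence=0.005)
        snp = call_snps_pileup(aligned, library3)
        assert "TE001" in snp.blocks
        # called sites match the planted shared SNPs of either genotype
        freqs = snp.frequencies("TE001")
        assert ((freqs > 0) & (freqs <= 1)).all()

    def test_min_depth_masks_low_coverage(self, library3):
        aligned = self._aligned(
            library3, {"gA": ({"TE001": 1}, 7), "gB": ({"TE002": 1}, 9)},
            7, shared_divergence=0.005)
        snp = call_snps_pileup(aligned, library3, min_depth=10_000)
        assert snp.blocks == {}  # nothing reaches the depth floor


class TestFrequenciesAndSpectrum:
    def test_site_frequency_basic(self):
        assert site_frequency(np.array([1, 1, 0, 0.0])) == 0.5
        assert site_frequency(np.array([1, 1, np.nan])) == 1.0
        with pytest.raises(ValueError):
            site_frequency(np.array([np.nan, np.nan]))

    def test_classify_partition(self):
        fixed, poly = classify_fixed(np.array([1.0, 0.3]))
        assert fixed.tolist() == [True, False]
        assert poly.tolist() == [False, True]
        fixed, poly = classify_fixed(np.array([]))
        assert fixed.sum() == 0 and poly.sum() == 0

    def test_average_sfs(self):
        assert average_sfs(np.array([0.5])) == 0.5
        assert np.isnan(average_sfs(np.array([1.0, 1.0])))  # no polymorphism
        assert np.isnan(average_sfs(np.array([])))

    def test_average_sfs_matches_distribution_mean(self):
        rng = np.random.default_rng(12)
        freqs = rng.uniform(0.01, 0.99, size=4000)
        # sample mean within CLT error of the Uniform(0.01, 0.99) mean
        assert average_sfs(freqs) == pytest.approx(
            0.5, abs=4 * 0.283 / np.sqrt(4000))

    def test_histogram_edges(self):
        counts = sfs_histogram(np.array([0.05, 0.95]), 10)
        assert counts[0] == 1 and counts[-1] == 1 and counts.sum() == 2
        assert sfs_histogram(np.array([]), 10).sum() == 0

    def test_histogram_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        freqs = rng.uniform(0.001, 1.0, size=500)
        counts = sfs_histogram(freqs, 7)
        edges = np.linspace(0, 1, 8)
        manual = np.zeros(7, dtype=int)
        for f in freqs:
            if f >= 1.0:
                continue
            for b in range(7):
                if edges[b] <= f < edges[b + 1] or (b == 6 and f >= edges[6]):
                    manual[b] += 1
                    break
        assert counts.tolist() == manual.tolist()

    def test_histogram_fixed_class_appended(self):
        counts = sfs_histogram(np.array([0.5, 1.0, 1.0]), 10,
                               include_fixed=True)
        assert len(counts) == 11 and counts[-1] == 2

    def test_missing_genotype_does_not_move_frequencies(self):
        calls = np.array([[1, 0, 1, np.nan], [0, 0, 1, 1.0]])
        block = SiteBlock(
            positions=np.array([5, 10]), ref=np.array(["A", "C"]),
            alt=np.array(["G", "T"]), calls=calls,
            depth=np.full((2, 4), 10, dtype=np.int32))
        snp = SnpTable(genotypes=["a", "b", "c", "d"], blocks={"TEa": block})
        f1 = snp.frequencies("TEa")
        calls2 = np.column_stack([calls, [np.nan, np.nan]])
        block2 = SiteBlock(
            positions=block.positions, ref=block.ref, alt=block.alt,
            calls=calls2, depth=np.full((2, 5), 10, dtype=np.int32))
        snp2 = SnpTable(genotypes=["a", "b", "c", "d", "e"],
                        blocks={"TEa": block2})
        assert np.allclose(f1, snp2.frequencies("TEa"))

    def test_summary_reports_undefined_as_nan(self):
        calls = np.array([[1, 1, 1, 1.0]])  # one fixed site only
        block = SiteBlock(
            positions=np.array([5]), ref=np.array(["A"]),
            alt=np.array(["G"]), calls=calls,
            depth=np.full((1, 4), 10, dtype=np.int32))
        snp = SnpTable(genotypes=list("abcd"), blocks={"TEa": block})
        out = sfs_summary(snp)
        assert out.loc["TEa", "n_fixed"] == 1
        assert out.loc["TEa", "n_polymorphic"] == 0
        assert np.isnan(out.loc["TEa", "average_sfs"])
        assert (out.loc["TEa", "n_fixed"] + out.loc["TEa", "n_polymorphic"]
                == out.loc["TEa", "n_sites"])


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        assert np.isnan(tajimas_d(np.array([0.0, 4.0]), np.array([4, 4]), 4))

    def test_n_below_two_fails(self):
        with pytest.raises(ValueError):
            tajimas_d(np.array([1.0]), np.array([4]), 1)

    def test_zero_numerator_construction(self):
        # n = 4 (a1 = 11/6): 8 singletons + 3 doubletons give
        # pi = 8*(1/2) + 3*(2/3) = 6 = S/a1 exactly, so D = 0
        k = np.array([1.0] * 8 + [2.0] * 3)
        m = np.full(11, 4)
        assert tajimas_d(k, m, 4) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        S = int(rng.integers(1, 31))
        calls = (rng.random((S, n)) < rng.uniform(0.1, 0.9)).astype(float)
        miss = rng.random((S, n)) < 0.1
        calls[miss] = np.nan
        k = np.nansum(calls, axis=1)
        m = (~np.isnan(calls)).sum(axis=1)
        expected = tajima_oracle(calls, n)
        got = tajimas_d(k, m, n)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-9)

    def test_directional_sign(self):
        # excess of rare variants -> negative D; intermediate -> positive
        n = 12
        singletons = tajimas_d(np.ones(20), np.full(20, n), n)
        balanced = tajimas_d(np.full(20, n // 2), np.full(20, n), n)
        assert singletons < 0 < balanced

    def test_windows(self, truth_vcf):
        snp = load_vcf(truth_vcf)
        fam = snp.references[0]
        length = 1200
        df = tajimas_d_windows(snp, fam, length, window=1000)
        assert len(df) == 2
        assert set(df.columns) >= {"start", "end", "n", "S", "tajimas_d"}
        empty = tajimas_d_windows(snp, "absent", 2500, window=1000)
        assert empty["tajimas_d"].isna().all()
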