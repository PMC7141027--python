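"""Shared fixtures: small simulated panels and crafted SAM files."""

from __future__ import annotations

import numpy as np
import pytest

from tecensus import (
    TELibrary,
    emit_truth_alignments,
    emit_truth_variants,
    make_genotype,
    make_te_library,
    sequence_reads,
)


@pytest.fixture(scope="session")
def library3() -> TELibrary:
    return make_te_library(3, (600, 1200), seed=11)


@pytest.fixture(scope="session")
def diverged_panel(library3):
    """Eight genotypes with shared + private divergence SNPs, plus truth VCF.

    Copy counts are small (0-3) so that per-genotype majority calls are
    well defined and the brute-force recount oracle stays fast.
    """
    rng = np.random.default_rng(42)
    truths = []
    for i in range(8):
        spec = {fam: int(rng.integers(0, 4)) for fam in library3.names}
        _, truth = make_genotype(
            library3, spec, divergence=0.001, shared_divergence=0.01,
            genome_length=40_000, seed=int(rng.integers(2 ** 31)),
            genotype_id=f"g{i}")
        truths.append(truth)
    return truths


@pytest.fixture(scope="session")
def truth_vcf(diverged_panel, library3, tmp_path_factory):
    path = tmp_path_factory.mktemp("vcf") / "truth.vcf"
    emit_truth_variants(diverged_panel, library3).to_vcf(path)
    return path


def write_crafted_sam(path, records, references=(("chrA", 5000), ("TEx", 1000))):
    """Write a SAM file from (flag, ref, pos1, mapq, length) tuples."""
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    lines += [f"@SQ\tSN:{n}\tLN:{L}" for n, L in references]
    for i, (flag, ref, pos1, mapq, length) in enumerate(records):
        seq = "A" * length
        lines.append("\t".join((
            f"r{i}", str(flag), ref, str(pos1), str(mapq),
            f"{length}M", "*", "0", "0", seq, "*")))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def crafted_sam(tmp_path):
    """A 1,000-record SAM with a known filter outcome.

    100 records at MAPQ 0, 50 at MAPQ 14, 50 at MAPQ 15, 700 at MAPQ 60,
    60 duplicate-flagged at MAPQ 60, 20 unmapped, 10 secondary,
    10 supplementary. Hand count retained at mapq_min=15 with duplicate
    removal: 50 + 700 = 750.
    """
    records = []
    records += [(0, "chrA", 1 + i, 0, 50) for i in range(100)]
    records += [(0, "chrA", 200 + i, 14, 50) for i in range(50)]
    records += [(0, "chrA", 400 + i, 15, 50) for i in range(50)]
    records += [(0, "TEx", 1 + (i % 900), 60, 50) for i in range(700)]
    records += [(1024, "TEx", 10 + i, 60, 50) for i in range(60)]
    records += [(4, "chrA", 1, 60, 50) for _ in range(20)]
    records += [(256, "chrA", 50, 60, 50) for _ in range(10)]
    records += [(2048, "chrA", 60, 60, 50) for _ in range(10)]
    path = write_crafted_sam(tmp_path / "crafted.sam", records)
    return path


@pytest.fixture(scope="session")
def small_mapped_genotype(library3):
    """One genotype with reads, truth alignments, and a SAM on disk."""
    _SPEC = {"TE001": 4, "TE002": 2, "TE003": 0}
    genome, truth = make_genotype(
        library3, _SPEC, genome_length=60_000, seed=7, genotype_id="gS")
    reads = sequence_reads(genome, truth, depth=18, seed=8,
                           error_rate=0.0, duplicate_fraction=0.02)
    aln = emit_truth_alignments(reads, truth, library3)
    return genome, truth, reads, aln
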