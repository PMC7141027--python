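"""Synthetic TE-resequencing panels with complete ground truth.

This module generates everything the downstream analysis consumes —
a TE consensus library, inbred genotype genomes carrying 0–200 copies
per family (with per-copy divergence SNPs and internal deletions),
short single-end reads, provenance-derived "truth" alignments in SAM,
and "truth" variant calls in VCF — so the whole pipeline is testable
without an external aligner, variant caller, or any downloaded data.

The simulated regime mirrors resequencing of mostly-homozygous inbred
fly lines: single-end 100-bp reads (the 90-bp paired-end datasets are
emulated read-1-only, i.e. also as single-end), uniform start positions,
substitution-only sequencing errors, and one haploid genome per genotype.

Truth alignments replace a real aligner: a read lying wholly inside one
contiguous reference segment (a backbone stretch, or one consensus
segment of a TE copy) is reported against that reference at the
corresponding coordinate with a high mapping quality; a read straddling
an insertion junction or an internal-deletion breakpoint gets MAPQ 0,
reproducing the *effect* of the downstream MAPQ filter on ambiguous
reads without modelling aligner internals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "TELibrary",
    "CopyRecord",
    "SimTruth",
    "ReadSet",
    "TruthAlignments",
    "TruthVariants",
    "make_te_library",
    "make_genotype",
    "sequence_reads",
    "emit_truth_alignments",
    "emit_truth_variants",
]

# base encoding: A,C,G,T -> 0..3
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G

DEFAULT_BACKBONE = "backbone"


def codes_to_str(codes: np.ndarray) -> str:
    """Decode a uint8 0..3 array to an ACGT string."""
    return _BASES[codes].tobytes().decode("ascii")


def str_to_codes(seq: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("sequence contains characters outside {A,C,G,T}")
    return codes


def _revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes][..., ::-1]


# ---------------------------------------------------------------------------
# TE library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TELibrary:
    """A named set of TE family consensus sequences.

    Plays the role of the consensus reference set against which reads
    from every genotype are quantified. Family names are unique, all
    sequences are plain ACGT and at least 100 bp.
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("TE family names must be unique")
        for name, seq in self.entries:
            if len(seq) < 100:
                raise ValueError(f"consensus {name!r} shorter than 100 bp")
            str_to_codes(seq)  # validates alphabet

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.entries}

    def sequence(self, family: str) -> str:
        for n, s in self.entries:
            if n == family:
                return s
        raise KeyError(family)

    def codes(self, family: str) -> np.ndarray:
        return str_to_codes(self.sequence(family))

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.entries
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path) -> "TELibrary":
        entries = tuple(
            (rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")
        )
        return cls(entries)


def make_te_library(
    n_families: int,
    length_range: tuple[int, int] = (500, 5000),
    seed: int = 0,
    *,
    unique_kmer: int = 100,
    max_attempts: int = 200,
) -> TELibrary:
    """Generate ``n_families`` random consensus sequences.

    Families are rejected and regenerated until no two share any exact
    k-mer of length ``unique_kmer`` (the read length), which guarantees
    that error-free reads of that length map uniquely in simulation.
    Deterministic for a fixed seed.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    lo, hi = length_range
    if lo < 100 or hi < lo:
        raise ValueError("length_range must satisfy 100 <= lo <= hi")
    rng = np.random.default_rng(seed)
    entries: list[tuple[str, str]] = []
    seen_kmers: set[str] = set()
    for i in range(n_families):
        length = int(rng.integers(lo, hi + 1))
        for attempt in range(max_attempts):
            seq = codes_to_str(rng.integers(0, 4, size=length, dtype=np.uint8))
            kmers = {seq[j:j + unique_kmer] for j in range(max(0, length - unique_kmer + 1))}
            if not (kmers & seen_kmers):
                seen_kmers |= kmers
                entries.append((f"TE{i + 1:03d}", seq))
                break
        else:
            raise ValueError(
                f"could not generate family {i + 1} without a shared "
                f"{unique_kmer}-mer after {max_attempts} attempts"
            )
    return TELibrary(tuple(entries))


# ---------------------------------------------------------------------------
# Genotype genomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CopyRecord:
    """One inserted TE copy in one genotype."""

    family: str
    insertion_site: int                 # backbone coordinate (0-based)
    full_length: bool
    deleted_interval: tuple[int, int] | None   # consensus [start, end), or None
    divergence_snps: tuple[tuple[int, str], ...]  # (consensus pos 0-based, alt base)
    length: int                         # copy length after any deletion
    genome_span: tuple[int, int] = (0, 0)  # assembled-genome [start, end)


@dataclass(frozen=True)
class _Piece:
    """One contiguous mapping segment of an assembled genome.

    Assembled positions [asm_start, asm_end) map 1:1 onto reference
    ``ref_name`` starting at ``ref_offset``.
    """

    asm_start: int
    asm_end: int
    ref_name: str
    ref_offset: int


@dataclass(frozen=True)
class SimTruth:
    """Complete ground truth for one simulated genotype."""

    genotype_id: str
    seed: int
    backbone_name: str
    backbone_length: int
    copies: tuple[CopyRecord, ...]
    pieces: tuple[_Piece, ...]
    copy_counts: dict[str, int]

    def __post_init__(self) -> None:
        counted: dict[str, int] = {}
        for c in self.copies:
            counted[c.family] = counted.get(c.family, 0) + 1
        for fam, n in self.copy_counts.items():
            if counted.get(fam, 0) != n:
                raise ValueError(f"copy_counts inconsistent for {fam!r}")

    @property
    def genome_length(self) -> int:
        return self.pieces[-1].asm_end if self.pieces else 0

    def true_copy_count(self, family: str) -> int:
        return self.copy_counts.get(family, 0)


def _default_deletion(rng: np.random.Generator, length: int,
                      frac_range: tuple[float, float]) -> tuple[int, int]:
    frac = rng.uniform(*frac_range)
    del_len = min(max(int(round(frac * length)), 1), length - 1)
    start = int(rng.integers(0, length - del_len + 1))
    return start, start + del_len


def make_genotype(
    library: TELibrary,
    copy_spec: Mapping[str, int | Callable[[np.random.Generator], int]],
    *,
    divergence: float = 0.0,
    shared_divergence: float = 0.0,
    deletion_prob: float = 0.0,
    deletion_length: tuple[float, float] = (0.3, 0.7),
    deletion_sampler: Callable[[np.random.Generator, int], tuple[int, int]] | None = None,
    genome_length: int = 100_000,
    seed: int = 0,
    genotype_id: str = "g0",
    backbone_name: str = DEFAULT_BACKBONE,
) -> tuple[np.ndarray, SimTruth]:
    """Build one haploid genotype genome with inserted TE copies.

    ``copy_spec`` maps family name to a copy count (or a callable drawing
    a count from a per-genotype distribution). Two divergence layers
    mirror how TE copies actually vary: ``shared_divergence`` plants
    family-level SNPs carried by *every* copy of the family in this
    genotype (inherited from the genotype's source copy — these become
    confident per-genotype variant calls), while ``divergence`` adds
    independent per-copy SNPs (private mutations of individual old
    copies). With probability ``deletion_prob`` a copy gains one internal
    deletion whose span is drawn by ``deletion_sampler`` (default: a
    contiguous interval covering a uniform fraction in
    ``deletion_length`` of the consensus). A copy is ``full_length`` iff
    it carries no deletion; each copy's recorded SNPs are its exact
    differences from the consensus.

    Returns the assembled genome (uint8 base codes) and the ground truth,
    including the piece table used to derive truth alignments.
    """
    rng = np.random.default_rng(seed)
    for fam in copy_spec:
        if fam not in library.lengths:
            raise KeyError(f"copy_spec names unknown family {fam!r}")

    counts: dict[str, int] = {}
    for fam, spec in copy_spec.items():
        n = spec(rng) if callable(spec) else int(spec)
        if n < 0:
            raise ValueError("copy counts must be >= 0")
        counts[fam] = n

    copies: list[CopyRecord] = []
    copy_seqs: list[np.ndarray] = []
    for fam in library.names:
        if fam not in counts:
            continue
        consensus = library.codes(fam)
        clen = len(consensus)
        haplotype = consensus.copy()
        if shared_divergence > 0 and counts[fam] > 0:
            pos = np.flatnonzero(rng.random(clen) < shared_divergence)
            if pos.size:
                shift = rng.integers(1, 4, size=pos.size).astype(np.uint8)
                haplotype[pos] = (haplotype[pos] + shift) % 4
        for _ in range(counts[fam]):
            seq = haplotype.copy()
            if divergence > 0:
                pos = np.flatnonzero(rng.random(clen) < divergence)
                if pos.size:
                    shift = rng.integers(1, 4, size=pos.size).astype(np.uint8)
                    seq[pos] = (seq[pos] + shift) % 4
            diff = np.flatnonzero(seq != consensus)
            snps = [(int(p), codes_to_str(seq[p:p + 1])) for p in diff]
            deleted = None
            if deletion_sampler is not None:
                deleted = deletion_sampler(rng, clen)
            elif deletion_prob > 0 and rng.random() < deletion_prob:
                deleted = _default_deletion(rng, clen, deletion_length)
            if deleted is not None:
                ds, de = deleted
                if not (0 <= ds < de <= clen):
                    raise ValueError("deleted_interval outside consensus bounds")
                keep = np.ones(clen, dtype=bool)
                keep[ds:de] = False
                seq = seq[keep]
                snps = [(p, b) for p, b in snps if not (ds <= p < de)]
            copies.append(CopyRecord(
                family=fam,
                insertion_site=0,  # assigned below
                full_length=deleted is None,
                deleted_interval=deleted,
                divergence_snps=tuple(snps),
                length=len(seq),
            ))
            copy_seqs.append(seq)

    total_inserted = sum(c.length for c in copies)
    if total_inserted >= genome_length / 2:
        raise ValueError(
            f"total inserted TE length ({total_inserted}) must be < half "
            f"the backbone length ({genome_length})"
        )

    backbone = rng.integers(0, 4, size=genome_length, dtype=np.uint8)
    n_copies = len(copies)
    if n_copies:
        sites = np.sort(rng.choice(genome_length, size=n_copies, replace=False))
        order = rng.permutation(n_copies)
    else:
        sites = np.empty(0, dtype=int)
        order = np.empty(0, dtype=int)

    pieces: list[_Piece] = []
    parts: list[np.ndarray] = []
    placed: list[CopyRecord] = []
    cursor = 0
    asm = 0
    for site, idx in zip(sites, order):
        site = int(site)
        if site > cursor:
            parts.append(backbone[cursor:site])
            pieces.append(_Piece(asm, asm + site - cursor, backbone_name, cursor))
            asm += site - cursor
        copy = copies[idx]
        seq = copy_seqs[idx]
        span_start = asm
        if copy.deleted_interval is None:
            pieces.append(_Piece(asm, asm + copy.length, copy.family, 0))
        else:
            ds, de = copy.deleted_interval
            clen = library.lengths[copy.family]
            if ds > 0:
                pieces.append(_Piece(asm, asm + ds, copy.family, 0))
            if de < clen:
                pieces.append(_Piece(asm + ds, asm + ds + (clen - de), copy.family, de))
        parts.append(seq)
        asm += copy.length
        placed.append(replace(copy, insertion_site=site,
                              genome_span=(span_start, asm)))
        cursor = site
    if cursor < genome_length:
        parts.append(backbone[cursor:])
        pieces.append(_Piece(asm, asm + genome_length - cursor, backbone_name, cursor))
        asm += genome_length - cursor

    genome = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
    truth = SimTruth(
        genotype_id=genotype_id,
        seed=seed,
        backbone_name=backbone_name,
        backbone_length=genome_length,
        copies=tuple(placed),
        pieces=tuple(pieces),
        copy_counts=counts,
    )
    return genome, truth


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """Simulated single-end reads from one genotype genome.

    ``sequences`` holds as-sequenced base codes (minus-strand reads are
    reverse-complemented relative to the genome); ``starts`` are 0-based
    assembled-genome coordinates of the leftmost aligned base.
    """

    genotype_id: str
    read_length: int
    error_rate: float
    starts: np.ndarray            # int64 (n,)
    strands: np.ndarray           # uint8 (n,), 0 = forward, 1 = reverse
    sequences: np.ndarray         # uint8 (n, read_length)
    is_duplicate: np.ndarray      # bool (n,)

    def __len__(self) -> int:
        return len(self.starts)

    def read_id(self, i: int) -> str:
        return f"{self.genotype_id}.r{i}"

    def to_fastq(self, path) -> None:
        qual = "I" * self.read_length
        with open(path, "w") as fh:
            for i in range(len(self)):
                fh.write(f"@{self.read_id(i)}\n"
                         f"{codes_to_str(self.sequences[i])}\n+\n{qual}\n")


def sequence_reads(
    genome: np.ndarray,
    truth: SimTruth,
    depth: float,
    read_length: int = 100,
    error_rate: float = 0.0,
    seed: int = 0,
    *,
    count_model: str = "poisson",
    duplicate_fraction: float = 0.0,
) -> ReadSet:
    """Draw uniform-start single-end reads at the given fold-coverage.

    The expected read count is ``depth * len(genome) / read_length``
    (Poisson-distributed, or exact with ``count_model="fixed"``).
    Substitution errors are planted at ``error_rate`` per base; indel
    errors and quality modelling are out of scope. With
    ``duplicate_fraction`` > 0 a corresponding number of extra reads are
    exact restarts of existing ones, flagged as duplicates (emulating
    library-prep duplicates that downstream filtering discards).
    """
    glen = len(genome)
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if read_length > glen:
        raise ValueError("read_length exceeds genome length")
    rng = np.random.default_rng(seed)
    expected = depth * glen / read_length
    if count_model == "poisson":
        n = int(rng.poisson(expected))
    elif count_model == "fixed":
        n = int(round(expected))
    else:
        raise ValueError(f"unknown count_model {count_model!r}")

    starts = rng.integers(0, glen - read_length + 1, size=n)
    strands = rng.integers(0, 2, size=n, dtype=np.uint8)
    seqs = genome[starts[:, None] + np.arange(read_length)]
    rev = strands == 1
    if rev.any():
        seqs[rev] = _revcomp(seqs[rev])
    if error_rate > 0 and n > 0:
        n_err = rng.binomial(n * read_length, error_rate)
        if n_err:
            flat = rng.integers(0, n * read_length, size=n_err)
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            flat_seqs = seqs.reshape(-1)
            flat_seqs[flat] = (flat_seqs[flat] + shift) % 4

    is_dup = np.zeros(n, dtype=bool)
    if duplicate_fraction > 0 and n > 0:
        n_dup = int(round(duplicate_fraction * n))
        if n_dup:
            src = rng.integers(0, n, size=n_dup)
            starts = np.concatenate([starts, starts[src]])
            strands = np.concatenate([strands, strands[src]])
            seqs = np.concatenate([seqs, seqs[src]])
            is_dup = np.concatenate([is_dup, np.ones(n_dup, dtype=bool)])

    return ReadSet(
        genotype_id=truth.genotype_id,
        read_length=read_length,
        error_rate=error_rate,
        starts=starts.astype(np.int64),
        strands=strands,
        sequences=seqs,
        is_duplicate=is_dup,
    )


# ---------------------------------------------------------------------------
# Truth alignments
# ---------------------------------------------------------------------------

@dataclass
class TruthAlignments:
    """Provenance-derived alignments of a ReadSet against backbone + consensi.

    One record per read (conservation). ``aligned_len`` < read length
    marks a junction/breakpoint read whose overhang is soft-clipped; such
    reads carry ``mapq_low`` and are removed by the standard MAPQ filter.
    """

    sample_id: str
    references: dict[str, int]          # name -> length, header order
    ref_index: np.ndarray               # int32 (n,), into list(references)
    pos0: np.ndarray                    # int64 (n,), 0-based leftmost
    mapq: np.ndarray                    # uint8 (n,)
    flags: np.ndarray                   # uint16 (n,)
    aligned_len: np.ndarray             # int32 (n,)
    reads: ReadSet

    def __len__(self) -> int:
        return len(self.pos0)

    @property
    def ref_names(self) -> list[str]:
        return list(self.references)

    def to_sam(self, path) -> None:
        """Write valid SAM (1-based POS, soft-clip CIGARs, @SQ header)."""
        names = self.ref_names
        L = self.reads.read_length
        lines = ["@HD\tVN:1.6\tSO:unsorted"]
        lines += [f"@SQ\tSN:{n}\tLN:{self.references[n]}" for n in names]
        lines.append(f"@RG\tID:{self.sample_id}\tSM:{self.sample_id}")
        lines.append("@PG\tID:tecensus\tPN:tecensus")
        seqs = self.reads.sequences
        strands = self.reads.strands
        for i in range(len(self)):
            a = int(self.aligned_len[i])
            cigar = f"{a}M" if a == L else f"{a}M{L - a}S"
            # SEQ is stored in reference-forward orientation
            s = seqs[i] if strands[i] == 0 else _revcomp(seqs[i])
            lines.append("\t".join((
                self.reads.read_id(i),
                str(int(self.flags[i])),
                names[int(self.ref_index[i])],
                str(int(self.pos0[i]) + 1),
                str(int(self.mapq[i])),
                cigar,
                "*", "0", "0",
                codes_to_str(s),
                "*",
                f"RG:Z:{self.sample_id}",
            )))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def emit_truth_alignments(
    reads: ReadSet,
    truth: SimTruth,
    library: TELibrary,
    *,
    mapq_high: int = 60,
    mapq_low: int = 0,
) -> TruthAlignments:
    """Derive the alignment each read *should* have from its provenance.

    Reads wholly inside one mapping piece of the assembled genome are
    reported against that piece's reference (TE consensus at consensus
    coordinates, or the backbone chromosome); reads straddling an
    insertion junction or a deletion breakpoint get ``mapq_low`` with the
    overhang soft-clipped. Output is one record per read.
    """
    if reads.starts is None or len(reads.starts) != len(reads.sequences):
        raise ValueError("read provenance missing or inconsistent")
    references = {truth.backbone_name: truth.backbone_length}
    references.update(library.lengths)
    name_to_idx = {n: i for i, n in enumerate(references)}

    piece_starts = np.array([p.asm_start for p in truth.pieces], dtype=np.int64)
    piece_ends = np.array([p.asm_end for p in truth.pieces], dtype=np.int64)
    piece_ref = np.array([name_to_idx[p.ref_name] for p in truth.pieces], dtype=np.int32)
    piece_off = np.array([p.ref_offset for p in truth.pieces], dtype=np.int64)

    starts = reads.starts
    ends = starts + reads.read_length
    idx = np.searchsorted(piece_starts, starts, side="right") - 1
    within = ends <= piece_ends[idx]
    mapq = np.where(within, mapq_high, mapq_low).astype(np.uint8)
    pos0 = starts - piece_starts[idx] + piece_off[idx]
    aligned = np.minimum(reads.read_length, piece_ends[idx] - starts).astype(np.int32)
    flags = (reads.strands.astype(np.uint16) * 16) | \
        (reads.is_duplicate.astype(np.uint16) * 1024)
    return TruthAlignments(
        sample_id=reads.genotype_id,
        references=references,
        ref_index=piece_ref[idx],
        pos0=pos0,
        mapq=mapq,
        flags=flags,
        aligned_len=aligned,
        reads=reads,
    )


# ---------------------------------------------------------------------------
# Truth variants
# ---------------------------------------------------------------------------

@dataclass
class TruthVariants:
    """Per-family consensus-coordinate variant calls derived from truth.

    One record per (family, position) where any genotype's within-genotype
    majority base differs from the consensus. Genotypes whose copies all
    delete (or lack) the position are missing.
    """

    genotypes: list[str]
    # records: (family, pos0, ref_base, alt_bases, gt_index (n_geno,), dp (n_geno,))
    records: list[tuple[str, int, str, tuple[str, ...], np.ndarray, np.ndarray]]
    reference_lengths: dict[str, int]

    def to_vcf(self, path) -> None:
        lines = [
            "##fileformat=VCFv4.2",
            "##source=tecensus-simulate",
        ]
        lines += [
            f"##contig=<ID={name},length={length}>"
            for name, length in self.reference_lengths.items()
        ]
        lines += [
            '##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of called genotypes">',
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        ]
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.genotypes))
        for fam, pos0, ref, alts, gt, dp in self.records:
            ns = int((gt >= 0).sum())
            fields = [fam, str(pos0 + 1), ".", ref, ",".join(alts), ".",
                      "PASS", f"NS={ns}", "GT:DP"]
            for g, d in zip(gt, dp):
                if g < 0:
                    fields.append("./.:.")
                else:
                    fields.append(f"{g}/{g}:{int(d)}")
            lines.append("\t".join(fields))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def emit_truth_variants(
    truths: Sequence[SimTruth],
    library: TELibrary,
    *,
    depth_per_copy: int = 20,
) -> TruthVariants:
    """Summarize each genotype's divergence SNPs into population variant calls.

    For each consensus position, a genotype's call is the majority base
    across its copies overlapping the position (ties resolved toward the
    consensus base); copies delete coverage inside their
    ``deleted_interval``. ``DP`` is the number of overlapping copies times
    ``depth_per_copy``, the depth a uniform sequencing run would supply.
    """
    if not truths:
        raise ValueError("need at least one genotype")
    genotypes = [t.genotype_id for t in truths]
    records = []
    for fam, consensus in library.entries:
        clen = len(consensus)
        # per genotype: coverage and alt-base counts per position
        cov = np.zeros((len(truths), clen), dtype=np.int32)
        alt_counts: list[dict[int, dict[str, int]]] = [dict() for _ in truths]
        for gi, truth in enumerate(truths):
            for copy in truth.copies:
                if copy.family != fam:
                    continue
                present = np.ones(clen, dtype=bool)
                if copy.deleted_interval is not None:
                    ds, de = copy.deleted_interval
                    present[ds:de] = False
                cov[gi] += present
                for pos, alt in copy.divergence_snps:
                    alt_counts[gi].setdefault(pos, {}).setdefault(alt, 0)
                    alt_counts[gi][pos][alt] += 1
        # candidate positions: any genotype has a majority alt there
        candidates: set[int] = set()
        majority: list[dict[int, str]] = [dict() for _ in truths]
        for gi in range(len(truths)):
            for pos, counts in alt_counts[gi].items():
                total_alt = sum(counts.values())
                ref_n = int(cov[gi, pos]) - total_alt
                best_alt = max(sorted(counts), key=lambda b: counts[b])
                if counts[best_alt] > ref_n:  # strict majority over consensus
                    majority[gi][pos] = best_alt
                    candidates.add(pos)
        for pos in sorted(candidates):
            ref = consensus[pos]
            alts = sorted({majority[gi][pos] for gi in range(len(truths))
                           if pos in majority[gi]})
            allele_idx = {b: i + 1 for i, b in enumerate(alts)}
            gt = np.full(len(truths), -1, dtype=np.int32)
            dp = np.zeros(len(truths), dtype=np.int32)
            for gi in range(len(truths)):
                c = int(cov[gi, pos])
                dp[gi] = c * depth_per_copy
                if c == 0:
                    continue
                gt[gi] = allele_idx.get(majority[gi].get(pos, ""), 0)
            records.append((fam, pos, ref, tuple(alts), gt, dp))
    return TruthVariants(
        genotypes=genotypes,
        records=records,
        reference_lengths=dict(library.lengths),
    )


def write_genome_fasta(genome: np.ndarray, truth: SimTruth, path) -> None:
    """Write one assembled genotype genome as FASTA."""
    rec = SeqRecord(Seq(codes_to_str(genome)), id=truth.genotype_id, description="")
    SeqIO.write([rec], str(path), "fasta")
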