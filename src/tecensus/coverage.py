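"""SAM/BAM ingestion, read filtering, and per-position depth profiles.

Filtering follows the copy-number protocol for resequenced panels:
unmapped, secondary and supplementary records are excluded, records with
mapping quality below 15 are removed (discarding reads that map equally
well to more than one location), and duplicate-flagged records are
dropped. Internally all coordinates are 0-based half-open; SAM's 1-based
positions are converted on read by pysam. Only reference-consuming
aligned bases contribute depth (soft clips do not).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pysam

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import TruthAlignments

__all__ = [
    "FilteredAlignmentSet",
    "DepthProfile",
    "load_alignments",
    "filter_truth_alignments",
    "depth_profile",
    "mean_depth",
]

DEFAULT_MAPQ_MIN = 15


@dataclass
class FilteredAlignmentSet:
    """Retained alignment intervals per reference, after filtering.

    ``intervals[ref]`` is an (n, 2) int64 array of 0-based half-open
    [start, end) aligned spans; ``mapqs[ref]`` the matching qualities.
    Every retained record satisfies mapq >= ``mapq_min`` and, when
    duplicates were dropped, is not duplicate-flagged.
    """

    references: dict[str, int]
    intervals: dict[str, np.ndarray]
    mapqs: dict[str, np.ndarray]
    sample_id: str | None = None
    mapq_min: int = DEFAULT_MAPQ_MIN
    duplicates_dropped: bool = True

    @property
    def n_records(self) -> int:
        return sum(len(v) for v in self.intervals.values())

    def n_on(self, reference: str) -> int:
        return len(self.intervals.get(reference, ()))

    def refilter(self, mapq_min: int) -> "FilteredAlignmentSet":
        """Apply a (possibly stricter) MAPQ threshold to this set."""
        intervals, mapqs = {}, {}
        for ref, iv in self.intervals.items():
            keep = self.mapqs[ref] >= mapq_min
            intervals[ref] = iv[keep]
            mapqs[ref] = self.mapqs[ref][keep]
        return FilteredAlignmentSet(
            references=dict(self.references),
            intervals=intervals,
            mapqs=mapqs,
            sample_id=self.sample_id,
            mapq_min=max(mapq_min, self.mapq_min),
            duplicates_dropped=self.duplicates_dropped,
        )


def load_alignments(
    path,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    drop_duplicates: bool = True,
    sample_id: str | None = None,
) -> FilteredAlignmentSet:
    """Read a SAM/BAM file and apply the standard read filters.

    Excludes unmapped, secondary and supplementary records; removes
    records with mapq < ``mapq_min`` (mapq == ``mapq_min`` is retained);
    removes duplicate-flagged records when ``drop_duplicates``. The file
    header must declare all reference lengths.
    """
    path = Path(path)
    mode = "rb" if path.suffix == ".bam" else "r"
    try:
        af = pysam.AlignmentFile(str(path), mode, check_sq=True)
    except ValueError as exc:
        raise ValueError(f"{path}: missing or invalid header ({exc})") from exc
    with af:
        references = {name: length
                      for name, length in zip(af.references, af.lengths)}
        if not references:
            raise ValueError(f"{path}: header declares no reference sequences")
        per_ref: dict[str, tuple[list, list, list]] = {
            name: ([], [], []) for name in references
        }
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < mapq_min:
                continue
            if drop_duplicates and rec.is_duplicate:
                continue
            ref = rec.reference_name
            if ref not in references:
                raise ValueError(f"{path}: record references unknown sequence {ref!r}")
            starts, ends, quals = per_ref[ref]
            starts.append(rec.reference_start)
            ends.append(rec.reference_end)  # reference-consuming span only
            quals.append(rec.mapping_quality)
    intervals = {
        ref: np.column_stack([
            np.asarray(starts, dtype=np.int64),
            np.asarray(ends, dtype=np.int64),
        ]) if starts else np.empty((0, 2), dtype=np.int64)
        for ref, (starts, ends, _) in per_ref.items()
    }
    mapqs = {
        ref: np.asarray(quals, dtype=np.int32)
        for ref, (_, _, quals) in per_ref.items()
    }
    if sample_id is None:
        sample_id = path.stem
    return FilteredAlignmentSet(
        references=references,
        intervals=intervals,
        mapqs=mapqs,
        sample_id=sample_id,
        mapq_min=mapq_min,
        duplicates_dropped=drop_duplicates,
    )


def filter_truth_alignments(
    aln: "TruthAlignments",
    mapq_min: int = DEFAULT_MAPQ_MIN,
    drop_duplicates: bool = True,
) -> FilteredAlignmentSet:
    """Filter in-memory truth alignments without a SAM round trip.

    Applies exactly the filters of :func:`load_alignments`; used for
    large simulations where serializing millions of records adds nothing.
    The SAM text path is exercised on smaller inputs.
    """
    keep = aln.mapq >= mapq_min
    if drop_duplicates:
        keep &= (aln.flags & 1024) == 0
    ref_idx = aln.ref_index[keep]
    starts = aln.pos0[keep]
    ends = starts + aln.aligned_len[keep]
    quals = aln.mapq[keep].astype(np.int32)
    intervals, mapqs = {}, {}
    for i, name in enumerate(aln.ref_names):
        sel = ref_idx == i
        intervals[name] = np.column_stack([starts[sel], ends[sel]]).astype(np.int64)
        mapqs[name] = quals[sel]
    return FilteredAlignmentSet(
        references=dict(aln.references),
        intervals=intervals,
        mapqs=mapqs,
        sample_id=aln.sample_id,
        mapq_min=mapq_min,
        duplicates_dropped=drop_duplicates,
    )


@dataclass
class DepthProfile:
    """Per-position filtered read depth over one reference sequence."""

    reference_name: str
    depth: np.ndarray      # int64, one entry per reference position
    n_reads: int

    @property
    def total_bases(self) -> int:
        return int(self.depth.sum())

    def __len__(self) -> int:
        return len(self.depth)


def depth_profile(
    alignments: FilteredAlignmentSet,
    reference_name: str,
    reference_length: int | None = None,
) -> DepthProfile:
    """Accumulate per-position depth for one reference.

    ``depth[i]`` counts retained records whose aligned interval covers
    position ``i``; intervals are truncated at the reference bounds.
    """
    if reference_length is None:
        if reference_name not in alignments.references:
            raise KeyError(f"reference {reference_name!r} not in alignment header")
        reference_length = alignments.references[reference_name]
    iv = alignments.intervals.get(
        reference_name, np.empty((0, 2), dtype=np.int64))
    diff = np.zeros(reference_length + 1, dtype=np.int64)
    if len(iv):
        starts = np.clip(iv[:, 0], 0, reference_length)
        ends = np.clip(iv[:, 1], 0, reference_length)
        np.add.at(diff, starts, 1)
        np.add.at(diff, ends, -1)
    depth = np.cumsum(diff[:-1])
    return DepthProfile(
        reference_name=reference_name,
        depth=depth,
        n_reads=len(iv),
    )


def mean_depth(profile: DepthProfile) -> float:
    """Mean per-base depth: total aligned bases / reference length.

    This is the "average counts" statistic used for copy-number
    normalization; unlike a raw read count divided by length it is
    insensitive to read length, so 90-bp and 100-bp datasets normalize
    identically.
    """
    if len(profile.depth) == 0:
        raise ValueError("zero-length reference")
    return float(profile.depth.mean())


def read_rate(profile: DepthProfile) -> float:
    """Alternative normalization statistic: retained reads / reference length."""
    if len(profile.depth) == 0:
        raise ValueError("zero-length reference")
    return profile.n_reads / len(profile.depth)
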