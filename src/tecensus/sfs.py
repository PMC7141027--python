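"""SNP tables, site-frequency spectra, and windowed Tajima's D over TE consensi.

Variant calls over the TE consensus sequences are loaded from VCF
(the production path — the output of a standard haplotype caller) or
produced by a deliberately simple built-in pileup caller used for
simulated data. Filtering follows the panel protocol: indels and sites
with more than two alleles are removed, per-genotype calls with depth
below four are set to missing, and sites are *not* filtered for missing
calls, because genotypes lacking an element cannot carry calls on it.

Inbred lines are treated as haploid units: a homozygous-alt call counts
as one alt observation. Heterozygous calls, should they appear in an
external VCF, contribute 0.5 alt toward the site frequency.

A site's population frequency is (alt calls) / (non-missing calls).
Frequency exactly 1 marks a fixed difference relative to the consensus
(divergence); 0 < f < 1 marks a polymorphism. The average SFS per family
is the mean of polymorphic-site frequencies, undefined (reported "-")
for families without polymorphic sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import TELibrary, TruthAlignments

__all__ = [
    "SnpTable",
    "load_vcf",
    "call_snps_pileup",
    "site_frequency",
    "classify_fixed",
    "average_sfs",
    "sfs_histogram",
    "sfs_summary",
    "tajimas_d",
    "tajimas_d_windows",
]

DEFAULT_MIN_DEPTH = 4
DEFAULT_WINDOW = 1000
_FIXED_TOL = 1e-9


@dataclass
class SiteBlock:
    """All retained biallelic sites of one reference sequence."""

    positions: np.ndarray   # int64, 1-based, strictly increasing
    ref: np.ndarray         # <U1 reference alleles
    alt: np.ndarray         # <U1 alternate alleles
    calls: np.ndarray       # float (n_sites, n_genotypes): 0 ref, 1 alt,
                            # 0.5 het, nan missing
    depth: np.ndarray       # int32 (n_sites, n_genotypes)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class SnpTable:
    """Per-reference biallelic SNP calls across a panel of genotypes."""

    genotypes: list[str]
    blocks: dict[str, SiteBlock] = field(default_factory=dict)

    @property
    def references(self) -> list[str]:
        return list(self.blocks)

    def frequencies(self, reference: str) -> np.ndarray:
        """Per-site alt frequency among non-missing calls."""
        block = self.blocks[reference]
        called = ~np.isnan(block.calls)
        n_called = called.sum(axis=1)
        if (n_called == 0).any():
            raise ValueError(
                f"{reference}: site with all calls missing (should have "
                "been dropped on load)")
        k = np.nansum(block.calls, axis=1)
        return k / n_called

    def n_called(self, reference: str) -> np.ndarray:
        block = self.blocks[reference]
        return (~np.isnan(block.calls)).sum(axis=1)

    def restrict(self, genotypes: Sequence[str]) -> "SnpTable":
        """Subset to the given genotypes, dropping sites left all-missing."""
        idx = [self.genotypes.index(g) for g in genotypes]
        blocks = {}
        for ref, block in self.blocks.items():
            calls = block.calls[:, idx]
            keep = (~np.isnan(calls)).any(axis=1)
            blocks[ref] = SiteBlock(
                positions=block.positions[keep],
                ref=block.ref[keep],
                alt=block.alt[keep],
                calls=calls[keep],
                depth=block.depth[keep][:, idx],
            )
        return SnpTable(genotypes=list(genotypes), blocks=blocks)


def load_vcf(path, min_depth: int = DEFAULT_MIN_DEPTH) -> SnpTable:
    """Load a VCF into a :class:`SnpTable` with the standard filters.

    Indel records and records with more than two alleles are dropped;
    per-genotype calls with depth below ``min_depth`` become missing;
    sites where every call is missing are dropped. Heterozygous calls map
    to 0.5. Raises ``ValueError`` with positional context on malformed
    records.
    """
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:
        raise ValueError(f"{path}: cannot open VCF ({exc})") from exc
    genotypes = list(vcf.samples)
    per_ref: dict[str, list] = {}
    last_pos: dict[str, int] = {}
    # gts012: 0 HOM_REF, 1 HET, 2 HOM_ALT, 3 UNKNOWN
    call_map = np.array([0.0, 0.5, 1.0, np.nan])
    for var in vcf:
        try:
            if var.is_indel or len(var.ALT) != 1:
                continue
            if len(var.REF) != 1 or len(var.ALT[0]) != 1:
                continue
            chrom, pos = var.CHROM, var.POS
            if chrom in last_pos and pos <= last_pos[chrom]:
                raise ValueError("positions not strictly increasing")
            dp = var.format("DP")
            if dp is not None:
                depths = dp.reshape(len(genotypes)).astype(np.int32)
                depths[depths < 0] = 0  # missing DP sentinel
            else:
                depths = var.gt_depths.astype(np.int32)
            calls = call_map[var.gt_types]
            calls = np.where(depths < min_depth, np.nan, calls)
            if np.isnan(calls).all():
                continue
            last_pos[chrom] = pos
            per_ref.setdefault(chrom, []).append(
                (pos, var.REF, var.ALT[0], calls, np.maximum(depths, 0)))
        except ValueError as exc:
            raise ValueError(
                f"{path}: malformed record at {var.CHROM}:{var.POS} ({exc})"
            ) from exc
    blocks = {}
    for ref, rows in per_ref.items():
        blocks[ref] = SiteBlock(
            positions=np.array([r[0] for r in rows], dtype=np.int64),
            ref=np.array([r[1] for r in rows]),
            alt=np.array([r[2] for r in rows]),
            calls=np.vstack([r[3] for r in rows]),
            depth=np.vstack([r[4] for r in rows]).astype(np.int32),
        )
    return SnpTable(genotypes=genotypes, blocks=blocks)


def call_snps_pileup(
    aligned: Mapping[str, "TruthAlignments"],
    library: "TELibrary",
    *,
    mapq_min: int = 15,
    min_depth: int = DEFAULT_MIN_DEPTH,
    min_alt_fraction: float = 0.8,
) -> SnpTable:
    """Simple majority pileup caller over the TE consensi (test substitute).

    This is intentionally naive — per genotype and consensus position it
    calls alt when depth >= ``min_depth`` and the alt-base fraction
    reaches ``min_alt_fraction``, ref symmetrically, missing otherwise —
    and stands in for a real haplotype caller only on simulated reads.
    VCF input is the production path.
    """
    from .simulate import _revcomp  # late import to avoid cycle

    genotypes = list(aligned)
    blocks: dict[str, SiteBlock] = {}
    for fam, consensus in library.entries:
        clen = len(consensus)
        ref_codes = np.frombuffer(consensus.encode(), dtype=np.uint8)
        lut = np.full(256, 255, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            lut[b] = i
        ref_codes = lut[ref_codes]
        depth_g = np.zeros((len(genotypes), clen), dtype=np.int32)
        alt_code = np.full((len(genotypes), clen), -1, dtype=np.int32)
        alt_frac = np.zeros((len(genotypes), clen))
        ref_frac = np.zeros((len(genotypes), clen))
        for gi, gid in enumerate(genotypes):
            aln = aligned[gid]
            try:
                fam_idx = aln.ref_names.index(fam)
            except ValueError:
                continue
            keep = (aln.ref_index == fam_idx) & (aln.mapq >= mapq_min) \
                & ((aln.flags & 1024) == 0)
            if not keep.any():
                continue
            pos0 = aln.pos0[keep]
            alens = aln.aligned_len[keep]
            seqs = aln.reads.sequences[keep]
            strands = aln.reads.strands[keep]
            rev = strands == 1
            if rev.any():
                seqs = seqs.copy()
                seqs[rev] = _revcomp(seqs[rev])  # reference-forward orientation
            L = aln.reads.read_length
            offs = np.arange(L)
            flat_pos = (pos0[:, None] + offs)
            valid = offs[None, :] < alens[:, None]
            counts = np.zeros((clen, 4), dtype=np.int64)
            np.add.at(counts, (flat_pos[valid], seqs[valid]), 1)
            dp = counts.sum(axis=1)
            depth_g[gi] = dp
            with np.errstate(invalid="ignore", divide="ignore"):
                fracs = counts / np.maximum(dp, 1)[:, None]
            rf = fracs[np.arange(clen), ref_codes]
            nonref = fracs.copy()
            nonref[np.arange(clen), ref_codes] = -1
            ac = np.argmax(nonref, axis=1)
            af = nonref[np.arange(clen), ac]
            ref_frac[gi] = rf
            alt_frac[gi] = af
            alt_code[gi] = ac
        callable_ = depth_g >= min_depth
        is_alt = callable_ & (alt_frac >= min_alt_fraction)
        is_ref = callable_ & (ref_frac >= min_alt_fraction)
        site_mask = is_alt.any(axis=0)
        if not site_mask.any():
            continue
        positions = np.flatnonzero(site_mask)
        bases = np.array(list("ACGT"))
        rows_calls, rows_depth, alts = [], [], []
        for p in positions:
            # consensus alt allele: majority alt code among alt-called genotypes
            codes, cnts = np.unique(alt_code[is_alt[:, p], p], return_counts=True)
            chosen = int(codes[np.argmax(cnts)])
            calls = np.full(len(genotypes), np.nan)
            calls[is_ref[:, p]] = 0.0
            calls[is_alt[:, p] & (alt_code[:, p] == chosen)] = 1.0
            # genotype with a *different* alt base stays missing
            rows_calls.append(calls)
            rows_depth.append(depth_g[:, p])
            alts.append(bases[chosen])
        blocks[fam] = SiteBlock(
            positions=(positions + 1).astype(np.int64),
            ref=np.array([consensus[p] for p in positions]),
            alt=np.array(alts),
            calls=np.vstack(rows_calls),
            depth=np.vstack(rows_depth).astype(np.int32),
        )
    return SnpTable(genotypes=genotypes, blocks=blocks)


# ---------------------------------------------------------------------------
# Frequencies and spectra
# ---------------------------------------------------------------------------

def site_frequency(calls: np.ndarray) -> float:
    """Alt frequency of one site: alt calls / non-missing calls."""
    called = ~np.isnan(calls)
    m = int(called.sum())
    if m == 0:
        raise ValueError("site has no non-missing calls")
    return float(np.nansum(calls) / m)


def classify_fixed(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Partition site frequencies into fixed (f = 1) and polymorphic (0 < f < 1).

    Returns boolean masks (fixed, polymorphic). Sites at frequency 0
    (possible in external VCFs listing all-reference sites) fall in
    neither class.
    """
    freqs = np.asarray(freqs, dtype=float)
    fixed = freqs >= 1.0 - _FIXED_TOL
    poly = (freqs > _FIXED_TOL) & ~fixed
    return fixed, poly


def average_sfs(freqs: np.ndarray) -> float:
    """Mean polymorphic-site frequency; NaN (reported "-") when none exist."""
    _, poly = classify_fixed(np.asarray(freqs, dtype=float))
    if not poly.any():
        return float("nan")
    return float(np.mean(np.asarray(freqs, dtype=float)[poly]))


def sfs_histogram(
    freqs: np.ndarray,
    n_bins: int = 10,
    include_fixed: bool = False,
) -> np.ndarray:
    """Bin polymorphic frequencies into ``n_bins`` equal-width bins on (0, 1].

    With ``include_fixed`` the fixed class is appended as one extra final
    count (shown for divergence context, never entering the average SFS).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    freqs = np.asarray(freqs, dtype=float)
    fixed, poly = classify_fixed(freqs)
    counts, _ = np.histogram(freqs[poly], bins=np.linspace(0, 1, n_bins + 1))
    if include_fixed:
        counts = np.append(counts, int(fixed.sum()))
    return counts


def sfs_summary(
    snp: SnpTable,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-family SFS summary: fixed/polymorphic counts and average SFS.

    With ``meta`` (genotype metadata carrying a ``population`` column)
    per-population columns are added alongside the joint estimate —
    frequencies are then recomputed within each population's genotypes.
    """
    rows = []
    for fam in snp.references:
        freqs = snp.frequencies(fam)
        fixed, poly = classify_fixed(freqs)
        row = {
            "family": fam,
            "n_sites": len(freqs),
            "n_fixed": int(fixed.sum()),
            "n_polymorphic": int(poly.sum()),
            "average_sfs": average_sfs(freqs),
        }
        rows.append(row)
    out = pd.DataFrame(rows).set_index("family")
    if meta is not None:
        for pop in sorted(meta["population"].unique()):
            members = [g for g in snp.genotypes
                       if g in meta.index and meta.loc[g, "population"] == pop]
            sub = snp.restrict(members)
            col = {}
            for fam in out.index:
                if fam in sub.blocks and len(sub.blocks[fam]):
                    col[fam] = average_sfs(sub.frequencies(fam))
                else:
                    col[fam] = float("nan")
            out[f"average_sfs_{pop}"] = pd.Series(col)
    return out


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def _tajima_constants(n: int) -> tuple[float, float, float]:
    """(a1, e1, e2) for sample size n, after Tajima (1989)."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return a1, e1, e2


def tajimas_d(
    alt_counts: np.ndarray,
    called_counts: np.ndarray,
    n: int,
) -> float:
    """Tajima's D for one window of sites.

    ``alt_counts`` (possibly fractional, from heterozygous calls) and
    ``called_counts`` are per-site; ``n`` is the number of sequences for
    the Tajima constants — here the count of genotypes with non-missing
    calls in the window, since sites are not filtered for missing calls
    and a fixed panel-wide n would be wrong. Pairwise diversity uses each
    site's own called count: pi = sum over segregating sites of
    2 k (m - k) / (m (m - 1)). Returns NaN when no site segregates.
    """
    if n < 2:
        raise ValueError("Tajima's D requires n >= 2 sequences")
    k = np.asarray(alt_counts, dtype=float)
    m = np.asarray(called_counts, dtype=float)
    seg = (k > _FIXED_TOL) & (k < m - _FIXED_TOL) & (m >= 2)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    ks, ms = k[seg], m[seg]
    pi = float(np.sum(2.0 * ks * (ms - ks) / (ms * (ms - 1.0))))
    a1, e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi - S / a1) / np.sqrt(var))


def tajimas_d_windows(
    snp: SnpTable,
    reference: str,
    reference_length: int,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Tajima's D in non-overlapping windows along one reference.

    Windows with no segregating sites, or fewer than two genotypes
    carrying calls, report D as NaN (missing, never 0). Returns one row
    per window: start (0-based), end, n, S, pi, D.
    """
    block = snp.blocks.get(reference)
    rows = []
    n_windows = max(1, -(-reference_length // window))
    for w in range(n_windows):
        lo, hi = w * window, min((w + 1) * window, reference_length)
        if block is None or len(block) == 0:
            rows.append((lo, hi, 0, 0, 0.0, float("nan")))
            continue
        sel = (block.positions > lo) & (block.positions <= hi)
        calls = block.calls[sel]
        if calls.size == 0:
            rows.append((lo, hi, 0, 0, 0.0, float("nan")))
            continue
        geno_called = (~np.isnan(calls)).any(axis=0)
        n = int(geno_called.sum())
        k = np.nansum(calls, axis=1)
        m = (~np.isnan(calls)).sum(axis=1)
        seg = (k > _FIXED_TOL) & (k < m - _FIXED_TOL) & (m >= 2)
        S = int(seg.sum())
        if n < 2 or S == 0:
            pi = 0.0
            if S and n < 2:
                warnings.warn(
                    f"{reference}:{lo}-{hi}: <2 genotypes called; D undefined")
            rows.append((lo, hi, n, S, pi, float("nan")))
            continue
        d = tajimas_d(k, m, n)
        ks, ms = k[seg], m[seg]
        pi = float(np.sum(2.0 * ks * (ms - ks) / (ms * (ms - 1.0))))
        rows.append((lo, hi, n, S, pi, d))
    return pd.DataFrame(
        rows, columns=["start", "end", "n", "S", "pi", "tajimas_d"])
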