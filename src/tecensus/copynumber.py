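"""Depth-normalized TE copy-number estimation and coverage-profile classes.

Copy number per family is the ratio of mean per-base depth over the
family consensus to mean depth over a single-copy normalization
chromosome (chromosome arm 2L in the fly panels; configurable, since a
synthetic genome names its backbone differently). The ratio is reported
raw — copies per haploid genome equivalent — with no ploidy doubling,
matching how inbred, essentially homozygous lines are summarized.

Coverage profiles over the consensus additionally separate qualitative
classes of families: full-length (most of the consensus covered at
roughly one copy or more), degraded (only a fraction covered, e.g. a
family surviving only as internal fragments), and locally concentrated
(nearly all reads piling into one short window of the consensus).
"""

from __future__ import annotations


from typing import Mapping

import numpy as np
import pandas as pd

from .coverage import DepthProfile, FilteredAlignmentSet, depth_profile, mean_depth

__all__ = [
    "estimate_copy_number",
    "covered_fraction",
    "coverage_concentration",
    "census_below_threshold",
    "genotype_totals",
    "build_copy_number_table",
    "coverage_summary",
]

DEFAULT_COVERAGE_THRESHOLD = 0.25   # copies; per-position presence cutoff
DEFAULT_FULL_LENGTH_FRACTION = 0.8  # covered fraction for "full length"
DEFAULT_CONCENTRATION_WINDOW = 140  # bp


def estimate_copy_number(te_profile: DepthProfile, norm_mean_depth: float) -> float:
    """Copy number = mean depth over the consensus / normalization depth."""
    if norm_mean_depth <= 0:
        raise ValueError(
            "normalization mean depth must be > 0 (sample unusable)")
    if te_profile.n_reads == 0:
        return 0.0
    return mean_depth(te_profile) / norm_mean_depth


def covered_fraction(
    te_profile: DepthProfile,
    norm_mean_depth: float,
    c: float = DEFAULT_COVERAGE_THRESHOLD,
    full_length_fraction: float = DEFAULT_FULL_LENGTH_FRACTION,
) -> tuple[float, bool]:
    """Fraction of consensus positions present at >= ``c`` copies.

    A position counts as covered when its depth, normalized by the
    single-copy depth, reaches ``c`` copies. The family is classed
    full-length when the fraction reaches ``full_length_fraction``.
    Both thresholds are heuristics separating qualitative classes
    (no exact criterion exists) and are configurable.
    """
    if norm_mean_depth <= 0:
        raise ValueError("normalization mean depth must be > 0")
    frac = float(np.mean(te_profile.depth / norm_mean_depth >= c))
    return frac, frac >= full_length_fraction


def coverage_concentration(
    te_profile: DepthProfile,
    window: int = DEFAULT_CONCENTRATION_WINDOW,
) -> tuple[float, tuple[int, int]]:
    """Largest share of aligned bases falling in any ``window``-bp interval.

    Returns (concentration, peak_window); the peak window is the leftmost
    argmax interval. A concentration near 1 with a short window flags a
    family whose reads nearly all map to one short segment of the
    consensus (a locally concentrated remnant rather than full copies).
    With no aligned bases the concentration is defined as 0 over [0, window).
    """
    L = len(te_profile.depth)
    if window > L:
        raise ValueError("window exceeds consensus length")
    total = te_profile.total_bases
    if total == 0:
        return 0.0, (0, window)
    cs = np.concatenate([[0], np.cumsum(te_profile.depth)])
    window_sums = cs[window:] - cs[:-window]
    best = int(np.argmax(window_sums))  # leftmost on ties
    return float(window_sums[best] / total), (best, best + window)


def build_copy_number_table(
    samples: Mapping[str, FilteredAlignmentSet],
    families: list[str],
    norm_reference: str,
) -> pd.DataFrame:
    """Genotype x family matrix of normalized copy numbers.

    ``samples`` maps genotype id to its filtered alignments. Families
    absent from a sample's alignment header get copy number 0 (absent,
    not missing). Raises if the normalization reference has no depth.
    """
    rows = {}
    for genotype, aset in samples.items():
        if norm_reference not in aset.references:
            raise KeyError(
                f"normalization reference {norm_reference!r} absent from "
                f"sample {genotype!r}")
        norm = mean_depth(depth_profile(aset, norm_reference))
        if norm <= 0:
            raise ValueError(
                f"sample {genotype!r}: zero depth on {norm_reference!r}")
        row = {}
        for fam in families:
            if fam in aset.references:
                row[fam] = estimate_copy_number(
                    depth_profile(aset, fam), norm)
            else:
                row[fam] = 0.0
        rows[genotype] = row
    table = pd.DataFrame.from_dict(rows, orient="index", columns=families)
    table.index.name = "genotype_id"
    return table


def census_below_threshold(
    table: pd.DataFrame,
    family: str,
    population: str,
    meta: pd.DataFrame,
    threshold: float = 0.3,
) -> int:
    """Count genotypes in a population with copy number strictly below ``threshold``.

    The census behind statements like "N individuals carry fewer than 0.3
    estimated copies" of an invading element: strict inequality, so a
    genotype at exactly the threshold is *not* counted.
    """
    if family not in table.columns:
        raise KeyError(f"unknown family {family!r}")
    members = meta.index[meta["population"] == population]
    if len(members) == 0:
        raise KeyError(f"unknown or empty population {population!r}")
    values = table.loc[members, family]
    return int((values < threshold).sum())


def genotype_totals(
    table: pd.DataFrame,
    meta: pd.DataFrame | None = None,
) -> tuple[pd.Series, pd.Series | None]:
    """Per-genotype total copy number, and per-population mean of totals."""
    if table.empty:
        raise ValueError("copy-number table is empty")
    totals = table.sum(axis=1)
    totals.name = "total_copies"
    if meta is None:
        return totals, None
    pop_means = totals.groupby(meta.loc[totals.index, "population"]).mean()
    pop_means.name = "mean_total_copies"
    return totals, pop_means


def coverage_summary(
    samples: Mapping[str, FilteredAlignmentSet],
    families: list[str],
    norm_reference: str,
    *,
    c: float = DEFAULT_COVERAGE_THRESHOLD,
    full_length_fraction: float = DEFAULT_FULL_LENGTH_FRACTION,
    window: int = DEFAULT_CONCENTRATION_WINDOW,
) -> pd.DataFrame:
    """Per (genotype, family) coverage-profile classification table.

    Columns: covered_fraction, full_length, concentration, peak_start,
    peak_end. Families shorter than the concentration window use the
    whole consensus as the window.
    """
    records = []
    for genotype, aset in samples.items():
        norm = mean_depth(depth_profile(aset, norm_reference))
        for fam in families:
            if fam not in aset.references:
                records.append((genotype, fam, 0.0, False, 0.0, 0, 0))
                continue
            prof = depth_profile(aset, fam)
            frac, full = covered_fraction(
                prof, norm, c=c, full_length_fraction=full_length_fraction)
            w = min(window, len(prof.depth))
            conc, (ps, pe) = coverage_concentration(prof, window=w)
            records.append((genotype, fam, frac, full, conc, ps, pe))
    return pd.DataFrame(
        records,
        columns=["genotype_id", "family", "covered_fraction", "full_length",
                 "concentration", "peak_start", "peak_end"],
    )
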