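"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written the slow, obvious way (explicit
loops, enumeration, standard formulas transcribed directly) and shares no
code path with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def tajima_oracle(calls: np.ndarray, n: int) -> float:
    """Tajima's D by explicit pairwise enumeration, Tajima (1989) constants.

    ``calls``: (sites, genotypes) array of 0/1/NaN haploid calls.
    """
    pi = 0.0
    S = 0
    for site in calls:
        vals = [v for v in site if not math.isnan(v)]
        m = len(vals)
        if m < 2:
            continue
        k = sum(vals)
        if not (0 < k < m):
            continue
        S += 1
        diffs = sum(1 for a, b in itertools.combinations(vals, 2) if a != b)
        pi += diffs / math.comb(m, 2)
    if S == 0:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def welch_oracle(x, y) -> tuple[float, float]:
    """Welch two-sample t and two-sided p via the textbook formulas.

    p uses the regularized incomplete beta function directly rather than
    any t-test routine.
    """
    from scipy.special import betainc

    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    # two-sided p from the t CDF expressed through I_x(a, b)
    p = betainc(df / 2, 0.5, df / (df + t * t))
    return t, float(p)


def f_test_oracle(x, y) -> tuple[float, float]:
    """Variance-ratio F and two-sided p via the incomplete beta function."""
    from scipy.special import betainc

    x, y = np.asarray(x, float), np.asarray(y, float)
    d1, d2 = len(x) - 1, len(y) - 1
    f = x.var(ddof=1) / y.var(ddof=1)
    # F CDF: P(F <= f) = I_{d1 f/(d1 f + d2)}(d1/2, d2/2)
    cdf = betainc(d1 / 2, d2 / 2, d1 * f / (d1 * f + d2))
    p = 2 * min(cdf, 1 - cdf)
    return f, float(min(p, 1.0))


def majority_recount(truths, library) -> dict:
    """Recount per-(family, position) genotype majority calls from SimTruth.

    Pure-dict reimplementation of the truth-variant rule: per genotype,
    the call is the strict-majority base over copies covering the
    position (ties -> consensus); genotypes with no covering copy are
    missing. Returns {family: {pos0: {genotype: 'ref'|'alt'|'missing',
    '_alts': set}}}.
    """
    out: dict = {}
    for fam, consensus in library.entries:
        clen = len(consensus)
        per_pos: dict = {}
        for truth in truths:
            copies = [c for c in truth.copies if c.family == fam]
            # coverage per position for this genotype
            for pos in range(clen):
                cov = 0
                alt_votes: dict = {}
                for c in copies:
                    if c.deleted_interval is not None:
                        ds, de = c.deleted_interval
                        if ds <= pos < de:
                            continue
                    cov += 1
                    for p, b in c.divergence_snps:
                        if p == pos:
                            alt_votes[b] = alt_votes.get(b, 0) + 1
                if not alt_votes:
                    continue
                best = max(sorted(alt_votes), key=lambda b: alt_votes[b])
                ref_votes = cov - sum(alt_votes.values())
                if alt_votes[best] > ref_votes:
                    per_pos.setdefault(pos, {})[truth.genotype_id] = best
        # fill in ref/missing for the remaining genotypes at variant positions
        table: dict = {}
        for pos, alt_of in per_pos.items():
            entry: dict = {"_alts": set(alt_of.values())}
            for truth in truths:
                gid = truth.genotype_id
                if gid in alt_of:
                    entry[gid] = "alt"
                    continue
                cov = 0
                for c in truth.copies:
                    if c.family != fam:
                        continue
                    if c.deleted_interval is not None:
                        ds, de = c.deleted_interval
                        if ds <= pos < de:
                            continue
                    cov += 1
                entry[gid] = "ref" if cov > 0 else "missing"
            table[pos] = entry
        if table:
            out[fam] = table
    return out
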