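"""Between-population comparison of TE copy numbers, and outlier genotypes.

Per family, the two populations' copy-number distributions are compared
with a two-sample t test for means (Welch by default — many families
show strongly unequal variances between populations, and the sample
sizes are very unbalanced) and an F test for variances, both
Bonferroni-corrected across the families tested (alpha / m, strictly;
m defaults to the number of families, 128 in the fly panels).

The model/results pair :class:`PanelComparison` /
:class:`PanelComparisonResults` wraps these tests statsmodels-style:
build the model from a copy-number DataFrame plus sample metadata,
``fit()`` to obtain per-family statistics, flags and a ``summary()``.

Outlier genotypes — single lines carrying a family at many times the
population mean, the signature of a recently active element in that
genotype — are flagged with a leave-one-out z-score plus an absolute
excess floor, both configurable (the qualitative observation fixes no
numeric rule, so the rule here is the package's own).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass


import numpy as np
import pandas as pd
from scipy import stats

from .sfs import SnpTable, classify_fixed

__all__ = [
    "compare_means",
    "compare_variances",
    "bonferroni_flags",
    "detect_outliers",
    "wild_vs_inbred",
    "population_summary",
    "PanelComparison",
    "PanelComparisonResults",
]

DEFAULT_ALPHA = 0.05
DEFAULT_Z_MIN = 4.0
DEFAULT_ABS_MIN = 5.0


def compare_means(
    values_1: np.ndarray,
    values_2: np.ndarray,
    method: str = "welch",
) -> tuple[float, float]:
    """Two-sample t test for means; (t, two-sided p).

    Welch (unequal variances) by default; ``method="student"`` pools.
    t is positive when group 1's mean is larger.
    """
    x, y = np.asarray(values_1, float), np.asarray(values_2, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 values")
    if method not in ("welch", "student"):
        raise ValueError(f"unknown method {method!r}")
    res = stats.ttest_ind(x, y, equal_var=(method == "student"))
    return float(res.statistic), float(res.pvalue)


def compare_variances(
    values_1: np.ndarray,
    values_2: np.ndarray,
) -> tuple[float, float]:
    """Variance-ratio F test; (F, two-sided p).

    F = s1^2 / s2^2 (n-1 denominators); p = 2 * min(P(F<=f), P(F>=f))
    under F(n1-1, n2-1), capped at 1. A zero sample variance in either
    group makes the test undefined: returns (nan, nan) rather than a
    silent 0.
    """
    x, y = np.asarray(values_1, float), np.asarray(values_2, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 values")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0 or v2 == 0:
        return float("nan"), float("nan")
    f = v1 / v2
    d1, d2 = len(x) - 1, len(y) - 1
    p = 2.0 * min(stats.f.cdf(f, d1, d2), stats.f.sf(f, d1, d2))
    return float(f), float(min(p, 1.0))


def bonferroni_flags(
    p_values: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    m: int | None = None,
) -> np.ndarray:
    """Strict Bonferroni significance flags: p < alpha / m.

    ``m`` defaults to the number of hypotheses supplied (the number of
    families tested; 128 in the full panel configuration, giving the
    threshold 0.05/128 = 0.000390625).
    """
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("m must be >= 1")
    with np.errstate(invalid="ignore"):
        return p < alpha / m


def _genotype_snp_counts(
    snp: SnpTable, family: str, genotype: str,
) -> tuple[int, int]:
    """(fixed differences, polymorphisms) carried by one genotype in one family.

    Fixed differences: alt-called sites in this genotype whose population
    frequency is 1; polymorphisms: alt-called sites segregating in the
    population (0 < f < 1).
    """
    if family not in snp.blocks:
        return 0, 0
    block = snp.blocks[family]
    gi = snp.genotypes.index(genotype)
    freqs = np.nansum(block.calls, axis=1) / (~np.isnan(block.calls)).sum(axis=1)
    fixed, poly = classify_fixed(freqs)
    carries = block.calls[:, gi] >= 0.5
    carries = np.where(np.isnan(block.calls[:, gi]), False, carries)
    return int((carries & fixed).sum()), int((carries & poly).sum())


def detect_outliers(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    z_min: float = DEFAULT_Z_MIN,
    abs_min: float = DEFAULT_ABS_MIN,
    snp: SnpTable | None = None,
) -> pd.DataFrame:
    """Flag genotypes with exceptional per-family copy number.

    Genotype g is flagged for family f when its leave-one-out z-score
    (computed from its population excluding g) reaches ``z_min`` AND its
    absolute excess over the leave-one-out mean reaches ``abs_min``
    copies. A leave-one-out sd of 0 with positive excess reports an
    infinite z. When a SnpTable is supplied each record is enriched with
    the genotype's fixed/polymorphic SNP counts for the family.
    """
    records = []
    for pop in sorted(meta["population"].unique()):
        members = [g for g in table.index if meta.loc[g, "population"] == pop]
        if len(members) < 3:
            raise ValueError(f"population {pop!r} needs >= 3 genotypes")
        sub = table.loc[members]
        vals = sub.to_numpy(dtype=float)
        for j, fam in enumerate(sub.columns):
            col = vals[:, j]
            for i, g in enumerate(members):
                rest = np.delete(col, i)
                loo_mean = rest.mean()
                loo_sd = rest.std(ddof=1)
                excess = col[i] - loo_mean
                if excess < abs_min:
                    continue
                z = np.inf if loo_sd == 0 else excess / loo_sd
                if z >= z_min:
                    rec = {
                        "genotype_id": g, "family": fam, "population": pop,
                        "copy_number": col[i], "population_mean": loo_mean,
                        "population_sd": loo_sd, "loo_z": z,
                    }
                    if snp is not None:
                        fx, pl = _genotype_snp_counts(snp, fam, g)
                        rec["fixed_diffs"], rec["polymorphisms"] = fx, pl
                    records.append(rec)
    cols = ["genotype_id", "family", "population", "copy_number",
            "population_mean", "population_sd", "loo_z"]
    if snp is not None:
        cols += ["fixed_diffs", "polymorphisms"]
    return pd.DataFrame(records, columns=cols)


def wild_vs_inbred(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    population: str | None = None,
) -> pd.DataFrame:
    """Per-family Welch t test of wild vs inbred genotypes within a population.

    Only populations containing both origin classes are compared (for the
    fly panels, the African lines, five of which were sequenced directly
    from the wild sample). Families are Bonferroni-corrected over the
    number of families tested. Families where either class has < 2
    genotypes are skipped with a warning.
    """
    if population is None:
        pops = [p for p in sorted(meta["population"].unique())
                if meta.loc[meta["population"] == p, "origin"].nunique() == 2]
        if not pops:
            raise ValueError("no population contains both wild and inbred lines")
    else:
        pops = [population]
    rows = []
    for pop in pops:
        members = meta.index[meta["population"] == pop]
        wild = [g for g in members if meta.loc[g, "origin"] == "wild"]
        inbred = [g for g in members if meta.loc[g, "origin"] == "inbred"]
        if len(wild) < 2 or len(inbred) < 2:
            warnings.warn(f"population {pop!r}: an origin class has <2 "
                          "genotypes; skipped")
            continue
        for fam in table.columns:
            w = table.loc[wild, fam].to_numpy(dtype=float)
            i = table.loc[inbred, fam].to_numpy(dtype=float)
            if w.std(ddof=1) == 0 and i.std(ddof=1) == 0:
                t, p = (0.0, 1.0) if w.mean() == i.mean() else (np.inf, 0.0)
            else:
                t, p = compare_means(w, i)
            rows.append({"population": pop, "family": fam,
                         "mean_wild": w.mean(), "mean_inbred": i.mean(),
                         "t_stat": t, "t_p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["significant"] = bonferroni_flags(out["t_p"].to_numpy(), alpha=alpha)
    else:
        out["significant"] = pd.Series(dtype=bool)
    return out


def population_summary(
    table: pd.DataFrame,
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-family, per-population copy-number mean and sample variance.

    Sample variance uses the n-1 denominator; single-genotype populations
    report variance as NaN (rendered "-"). The layout mirrors the standard
    per-family summary table: family rows, (population mean, variance)
    column pairs.
    """
    if table.empty:
        raise ValueError("copy-number table is empty")
    out = pd.DataFrame(index=table.columns)
    out.index.name = "family"
    for pop in sorted(meta["population"].unique()):
        members = [g for g in table.index if meta.loc[g, "population"] == pop]
        sub = table.loc[members]
        out[f"{pop}_mean"] = sub.mean(axis=0)
        out[f"{pop}_variance"] = sub.var(axis=0, ddof=1) if len(sub) > 1 \
            else np.nan
    return out


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class PanelComparison:
    """Between-population comparison model over a copy-number panel.

    Parameters
    ----------
    table:
        Genotype x family copy-number DataFrame.
    meta:
        Genotype metadata indexed by genotype id with at least a
        ``population`` column (and ``origin`` for wild/inbred contrasts).
    group_1, group_2:
        The two population labels to compare; default the first two in
        sorted order.
    """

    def __init__(self, table: pd.DataFrame, meta: pd.DataFrame,
                 group_1: str | None = None, group_2: str | None = None):
        missing = [g for g in table.index if g not in meta.index]
        if missing:
            raise ValueError(f"genotypes without metadata: {missing[:5]}")
        self.table = table
        self.meta = meta
        pops = sorted(meta.loc[table.index, "population"].unique())
        if group_1 is None or group_2 is None:
            if len(pops) < 2:
                raise ValueError("need two populations to compare")
            group_1, group_2 = pops[:2]
        self.group_1, self.group_2 = group_1, group_2

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, meta: pd.DataFrame,
                       **kwargs) -> "PanelComparison":
        return cls(table, meta, **kwargs)

    def fit(self, alpha: float = DEFAULT_ALPHA, m: int | None = None,
            test: str = "welch") -> "PanelComparisonResults":
        """Run per-family mean and variance tests with Bonferroni correction.

        Bonferroni is applied separately to the mean-test family and the
        variance-test family of hypotheses, each with the same m
        (defaulting to the number of families tested).
        """
        g1 = [g for g in self.table.index
              if self.meta.loc[g, "population"] == self.group_1]
        g2 = [g for g in self.table.index
              if self.meta.loc[g, "population"] == self.group_2]
        rows = []
        for fam in self.table.columns:
            x = self.table.loc[g1, fam].to_numpy(dtype=float)
            y = self.table.loc[g2, fam].to_numpy(dtype=float)
            if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
                t, tp = (0.0, 1.0) if x.mean() == y.mean() else (np.inf, 0.0)
            else:
                t, tp = compare_means(x, y, method=test)
            f, fp = compare_variances(x, y)
            rows.append({
                "family": fam,
                "mean_1": x.mean(), "mean_2": y.mean(),
                "var_1": x.var(ddof=1), "var_2": y.var(ddof=1),
                "t_stat": t, "t_p": tp, "f_stat": f, "f_p": fp,
                "direction": self.group_1 if x.mean() >= y.mean()
                else self.group_2,
            })
        comp = pd.DataFrame(rows).set_index("family")
        m_eff = m if m is not None else len(comp)
        comp["mean_significant"] = bonferroni_flags(
            comp["t_p"].to_numpy(), alpha=alpha, m=m_eff)
        comp["var_significant"] = bonferroni_flags(
            comp["f_p"].to_numpy(), alpha=alpha, m=m_eff)
        return PanelComparisonResults(self, comp, alpha=alpha, m=m_eff,
                                      test=test)


@dataclass
class PanelComparisonResults:
    """Fitted per-family comparison results with a text summary."""

    model: PanelComparison
    comparisons: pd.DataFrame
    alpha: float
    m: int
    test: str

    @property
    def n_mean_significant(self) -> int:
        return int(self.comparisons["mean_significant"].sum())

    @property
    def n_var_significant(self) -> int:
        return int(self.comparisons["var_significant"].sum())

    def detect_outliers(self, **kwargs) -> pd.DataFrame:
        return detect_outliers(self.model.table, self.model.meta, **kwargs)

    def summary(self, max_rows: int = 20) -> str:
        c = self.comparisons
        g1, g2 = self.model.group_1, self.model.group_2
        lines = [
            "Panel copy-number comparison",
            "=" * 60,
            f"groups: {g1} (n={sum(self.model.meta.loc[self.model.table.index, 'population'] == g1)})"
            f" vs {g2} (n={sum(self.model.meta.loc[self.model.table.index, 'population'] == g2)})",
            f"test: {self.test} t (means), F (variances); "
            f"Bonferroni alpha={self.alpha}, m={self.m} "
            f"(threshold {self.alpha / self.m:.3g})",
            f"families tested: {len(c)}",
            f"significant mean differences: {self.n_mean_significant}",
            f"significant variance differences: {self.n_var_significant}",
            "-" * 60,
            f"{'family':<16}{'mean_' + g1:>10}{'mean_' + g2:>10}"
            f"{'t':>9}{'p_t':>11}{'sig':>5}",
        ]
        shown = c.reindex(c["t_p"].sort_values().index).head(max_rows)
        for fam, row in shown.iterrows():
            lines.append(
                f"{fam:<16}{row['mean_1']:>10.2f}{row['mean_2']:>10.2f}"
                f"{row['t_stat']:>9.2f}{row['t_p']:>11.3g}"
                f"{'*' if row['mean_significant'] else '':>5}")
        return "\n".join(lines)
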