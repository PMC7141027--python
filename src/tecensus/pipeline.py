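"""End-to-end orchestration: simulate -> coverage -> copy number -> SFS -> compare.

A run is described by a :class:`RunConfig` holding either a simulation
block (all synthetic-panel parameters) or input paths (per-sample
SAM/BAM alignments, a VCF over the TE consensi, the consensus FASTA,
and a metadata table), plus the module thresholds, an output directory
and a seed. ``run_pipeline`` produces a fixed bundle of TSV outputs, a
markdown report and a JSON manifest; identical config + seed give
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coverage import load_alignments
from .copynumber import build_copy_number_table, coverage_summary
from .popstats import PanelComparison, detect_outliers, population_summary, wild_vs_inbred
from .sfs import load_vcf, sfs_summary, tajimas_d_windows
from .simulate import (
    TELibrary, emit_truth_alignments, emit_truth_variants, make_genotype,
    make_te_library, sequence_reads,
)

__all__ = ["RunConfig", "run_pipeline", "simulate_panel", "write_report"]

log = logging.getLogger("tecensus")

OUTPUT_FILES = [
    "copy_number_matrix.tsv",
    "copy_number_summary.tsv",
    "sfs_summary.tsv",
    "tajimas_d.tsv",
    "comparisons.tsv",
    "outliers.tsv",
    "coverage_classes.tsv",
]

_DEFAULT_THRESHOLDS: dict[str, Any] = {
    "mapq_min": 15,
    "min_depth": 4,
    "coverage_threshold": 0.25,
    "full_length_fraction": 0.8,
    "concentration_window": 140,
    "tajima_window": 1000,
    "alpha": 0.05,
    "m": None,
    "test": "welch",
    "z_min": 4.0,
    "abs_min": 5.0,
}

_DEFAULT_SIMULATION: dict[str, Any] = {
    "n_families": 6,
    "length_range": [1500, 3000],
    "genome_length": 250_000,
    "populations": {"CA": 6, "AF": 6},
    "n_wild": {"AF": 2},
    "depth": 10.0,
    "read_length": 100,
    "error_rate": 0.005,
    "divergence": 0.002,
    "shared_divergence": 0.01,
    "deletion_prob": 0.0,
    "duplicate_fraction": 0.0,
    "copy_rate_range": [0.5, 6.0],
    "population_multiplier": {"CA": 1.3},
}


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    output_dir: Path
    seed: int = 0
    normalization_reference: str = "backbone"
    thresholds: dict[str, Any] = field(default_factory=dict)
    simulation: dict[str, Any] | None = None
    inputs: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError(
                "exactly one of a simulation block or an inputs block "
                "must be configured")
        self.output_dir = Path(self.output_dir)
        merged = dict(_DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        unknown = set(merged) - set(_DEFAULT_THRESHOLDS)
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        self.thresholds = merged
        if self.simulation is not None:
            sim = dict(_DEFAULT_SIMULATION)
            sim.update(self.simulation)
            unknown = set(sim) - set(_DEFAULT_SIMULATION)
            if unknown:
                raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
            self.simulation = sim

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        return cls(
            output_dir=d["output_dir"],
            seed=int(d.get("seed", 0)),
            normalization_reference=d.get("normalization_reference", "backbone"),
            thresholds=dict(d.get("thresholds", {})),
            simulation=dict(d["simulation"]) if "simulation" in d else None,
            inputs=dict(d["inputs"]) if "inputs" in d else None,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict[str, Any]:
        return {
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "normalization_reference": self.normalization_reference,
            "thresholds": self.thresholds,
            "simulation": self.simulation,
            "inputs": {k: str(v) if not isinstance(v, dict)
                       else {kk: str(vv) for kk, vv in v.items()}
                       for k, v in self.inputs.items()}
            if self.inputs else None,
        }


def simulate_panel(config: RunConfig) -> dict[str, Any]:
    """Simulate a full panel and write FASTA/SAM/VCF/TSV inputs to disk.

    Per family a base copy rate is drawn once (uniform over
    ``copy_rate_range``), scaled per population by
    ``population_multiplier``; each genotype's count is Poisson around
    that rate — panels differ in mean copy number between populations and
    between genotypes, the structure the analysis is built to measure.
    Returns an inputs block pointing at the written files.
    """
    sim = config.simulation
    assert sim is not None
    rng = np.random.default_rng(config.seed)
    outdir = config.output_dir / "sim"
    outdir.mkdir(parents=True, exist_ok=True)

    library = make_te_library(
        sim["n_families"], tuple(sim["length_range"]),
        seed=int(rng.integers(2 ** 31)),
        unique_kmer=sim["read_length"])
    library.to_fasta(outdir / "library.fasta")

    rates = {fam: rng.uniform(*sim["copy_rate_range"]) for fam in library.names}
    multipliers = dict(sim["population_multiplier"])

    alignments: dict[str, Path] = {}
    truths = []
    meta_rows = []
    truth_counts = {}
    gi = 0
    for pop in sorted(sim["populations"]):
        n = sim["populations"][pop]
        mult = multipliers.get(pop, 1.0)
        n_wild = dict(sim.get("n_wild") or {}).get(pop, 0)
        for k in range(n):
            gid = f"{pop}{k + 1:03d}"
            spec = {fam: int(rng.poisson(rates[fam] * mult))
                    for fam in library.names}
            genome, truth = make_genotype(
                library, spec,
                divergence=sim["divergence"],
                shared_divergence=sim["shared_divergence"],
                deletion_prob=sim["deletion_prob"],
                genome_length=sim["genome_length"],
                seed=int(rng.integers(2 ** 31)),
                genotype_id=gid,
                backbone_name=config.normalization_reference,
            )
            reads = sequence_reads(
                genome, truth, depth=sim["depth"],
                read_length=sim["read_length"],
                error_rate=sim["error_rate"],
                seed=int(rng.integers(2 ** 31)),
                duplicate_fraction=sim["duplicate_fraction"],
            )
            aln = emit_truth_alignments(reads, truth, library)
            sam_path = outdir / f"{gid}.sam"
            aln.to_sam(sam_path)
            alignments[gid] = sam_path
            truths.append(truth)
            meta_rows.append({
                "genotype_id": gid, "population": pop,
                "origin": "wild" if k < n_wild else "inbred",
            })
            truth_counts[gid] = truth.copy_counts
            log.info("simulated %s: %d reads, %d TE copies",
                     gid, len(reads), len(truth.copies))
            gi += 1

    variants = emit_truth_variants(truths, library)
    vcf_path = outdir / "truth.vcf"
    variants.to_vcf(vcf_path)

    meta = pd.DataFrame(meta_rows).set_index("genotype_id")
    meta_path = outdir / "metadata.tsv"
    meta.to_csv(meta_path, sep="\t")
    truth_table = pd.DataFrame.from_dict(truth_counts, orient="index")
    truth_table.index.name = "genotype_id"
    truth_table.to_csv(outdir / "truth_copy_numbers.tsv", sep="\t")

    return {
        "alignments": alignments,
        "vcf": vcf_path,
        "library_fasta": outdir / "library.fasta",
        "metadata": meta_path,
    }


def write_report(tables: Mapping[str, pd.DataFrame],
                 group_labels: tuple[str, str] | None = None) -> str:
    """Render a human-readable markdown summary of a run's tables."""
    summary = tables["copy_number_summary"]
    comparisons = tables["comparisons"]
    outliers = tables["outliers"]
    sfs = tables["sfs_summary"]
    lines = ["# TE census report", ""]

    lines.append("## Top families by copy number")
    for col in [c for c in summary.columns if c.endswith("_mean")]:
        pop = col[:-5]
        top = summary[col].sort_values(ascending=False).head(5)
        lines.append(f"- {pop}: " + ", ".join(
            f"{fam} ({v:.1f})" for fam, v in top.items()))
    lines.append("")

    lines.append("## Significant between-population differences")
    sig_mean = comparisons.index[comparisons["mean_significant"]].tolist()
    sig_var = comparisons.index[comparisons["var_significant"]].tolist()
    if not sig_mean and not sig_var:
        lines.append("No significant families.")
    else:
        lines.append(f"- mean differences ({len(sig_mean)}): "
                     + (", ".join(sig_mean) or "none"))
        lines.append(f"- variance differences ({len(sig_var)}): "
                     + (", ".join(sig_var) or "none"))
    lines.append("")

    lines.append("## Outlier genotypes")
    if outliers.empty:
        lines.append("No outlier genotypes flagged.")
    else:
        for _, row in outliers.iterrows():
            lines.append(
                f"- {row['genotype_id']}: {row['family']} at "
                f"{row['copy_number']:.1f} copies "
                f"(population mean {row['population_mean']:.1f})")
    lines.append("")

    lines.append("## Families with undefined average SFS")
    undef = sfs.index[sfs["average_sfs"].isna()].tolist()
    lines.append(", ".join(undef) if undef else "none")
    lines.append("")
    return "\n".join(lines)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g", index=index, na_rep="-")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis; returns the paths of the written bundle.

    Stages: (optional) simulation, alignment loading + filtering, copy
    number, coverage classification, SFS + Tajima's D, population
    comparison, outlier detection, report + manifest. Any stage failure
    raises with the stage name attached.
    """
    th = config.thresholds
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "configure"
    try:
        if config.simulation is not None:
            stage = "simulate"
            inputs = simulate_panel(config)
        else:
            inputs = dict(config.inputs)  # type: ignore[arg-type]
            aln = inputs["alignments"]
            if not isinstance(aln, dict):  # TSV listing: sample_id <tab> path
                listing = pd.read_csv(aln, sep="\t", header=None,
                                      names=["sample_id", "path"])
                inputs["alignments"] = dict(
                    zip(listing["sample_id"], listing["path"]))

        stage = "coverage"
        library = TELibrary.from_fasta(inputs["library_fasta"])
        meta = pd.read_csv(inputs["metadata"], sep="\t",
                           index_col="genotype_id")
        samples = {}
        for gid in sorted(inputs["alignments"]):
            aset = load_alignments(
                inputs["alignments"][gid], mapq_min=th["mapq_min"],
                sample_id=gid)
            samples[gid] = aset
            log.info("%s: %d records retained after filters", gid,
                     aset.n_records)

        stage = "copy_number"
        table = build_copy_number_table(
            samples, library.names, config.normalization_reference)
        summary = population_summary(table, meta)
        classes = coverage_summary(
            samples, library.names, config.normalization_reference,
            c=th["coverage_threshold"],
            full_length_fraction=th["full_length_fraction"],
            window=th["concentration_window"])

        stage = "sfs"
        snp = load_vcf(inputs["vcf"], min_depth=th["min_depth"])
        sfs = sfs_summary(snp, meta=meta)
        sfs = sfs.reindex(library.names)  # families absent -> all-NaN rows
        sfs.index.name = "family"
        tajima_frames = []
        for fam in library.names:
            df = tajimas_d_windows(snp, fam, library.lengths[fam],
                                   window=th["tajima_window"])
            df.insert(0, "family", fam)
            tajima_frames.append(df)
        tajima = pd.concat(tajima_frames, ignore_index=True)

        stage = "compare"
        model = PanelComparison(table, meta)
        results = model.fit(alpha=th["alpha"], m=th["m"], test=th["test"])
        outliers = detect_outliers(table, meta, z_min=th["z_min"],
                                   abs_min=th["abs_min"], snp=snp)
        try:
            wild = wild_vs_inbred(table, meta, alpha=th["alpha"])
        except ValueError:
            wild = pd.DataFrame()

        stage = "write"
        tables = {
            "copy_number_matrix": table,
            "copy_number_summary": summary,
            "sfs_summary": sfs,
            "tajimas_d": tajima,
            "comparisons": results.comparisons,
            "outliers": outliers,
            "coverage_classes": classes,
        }
        paths: dict[str, Path] = {}
        for name, df in tables.items():
            path = outdir / f"{name}.tsv"
            _write_tsv(df, path,
                       index=name not in ("tajimas_d", "outliers",
                                          "coverage_classes"))
            paths[name] = path
        if len(wild):
            _write_tsv(wild, outdir / "wild_vs_inbred.tsv", index=False)
            paths["wild_vs_inbred"] = outdir / "wild_vs_inbred.tsv"

        report = write_report(tables)
        (outdir / "report.md").write_text(report)
        paths["report"] = outdir / "report.md"

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "outputs": {
                name: hashlib.sha256(p.read_bytes()).hexdigest()
                for name, p in sorted(paths.items())
            },
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        paths["manifest"] = outdir / "manifest.json"
        return paths
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
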