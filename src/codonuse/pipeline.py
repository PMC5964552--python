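"""End-to-end orchestration: io -> filtering -> metrics -> analyses -> reports.

``run_pipeline`` reads one or more genomes, applies the selection filters,
computes per-gene indices against each genome's own pooled reference,
derives cohort-level statistics and writes all tabular outputs (TSV), the
dendrogram (Newick) and a machine-readable run manifest (JSON).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    ClusterResult,
    CorrelationMatrix,
    GenomeAnalysis,
    LinearFit,
    analyze_genome,
    cbi_enc_relationship,
    cluster_genomes,
    correlation_matrix,
    enc_plot_table,
    equalize_enc,
    length_gc_profile,
    neutrality_stats,
    rscu_long_table,
    summarize_genome,
)
from .genetic_code import START_CODONS_DEFAULT
from .metrics import RSCUTable, compute_rscu, pooled_counts
from .sequences import (
    CodingSequence,
    FilterReport,
    apply_selection_filters,
    read_fasta_cds,
    read_genbank_cds,
    write_fasta,
    write_filter_reports,
)

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.6g"


@dataclass
class GenomeInput:
    path: str
    label: str | None = None
    fmt: str = "fasta"  # fasta | genbank
    country: str | None = None


@dataclass
class RunConfig:
    """Configuration of one pipeline run; defaults follow the method's
    standard thresholds (length > 300 nt, superior RSCU > 1.6, abundant
    RSCU > 1.5, protein-length cap 1500 aa)."""

    inputs: list[GenomeInput] = field(default_factory=list)
    outdir: str = "codonuse_out"
    start_codons: frozenset[str] = START_CODONS_DEFAULT
    min_length: int = 300
    superior_rscu: float = 1.6
    abundant_rscu: float = 1.5
    max_protein_length: int = 1500
    fop_mode: str = "ratio"
    corr_level: str = "gene"     # gene | genome
    linkage: str = "single"
    seed: int = 0
    plots: bool = False
    write_filtered: bool = False

    def to_dict(self) -> dict:
        d = {
            "inputs": [vars(i) for i in self.inputs],
            "outdir": str(self.outdir),
            "start_codons": sorted(self.start_codons),
            "min_length": self.min_length,
            "superior_rscu": self.superior_rscu,
            "abundant_rscu": self.abundant_rscu,
            "max_protein_length": self.max_protein_length,
            "fop_mode": self.fop_mode,
            "corr_level": self.corr_level,
            "linkage": self.linkage,
            "seed": self.seed,
            "plots": self.plots,
            "write_filtered": self.write_filtered,
        }
        return d


@dataclass
class CohortAnalysis:
    """All cohort-level results for a set of genomes."""

    genomes: dict[str, GenomeAnalysis]
    selected: dict[str, list[CodingSequence]]
    filter_reports: dict[str, FilterReport]
    all_metrics: pd.DataFrame
    pooled_rscu: RSCUTable
    correlation: CorrelationMatrix | None
    neutrality: LinearFit | None
    cbi_eenc: LinearFit | None
    cluster: ClusterResult | None


def read_genome(inp: GenomeInput) -> list[CodingSequence]:
    label = inp.label or Path(inp.path).stem
    if inp.fmt == "fasta":
        return read_fasta_cds(inp.path, genome_label=label, country=inp.country)
    if inp.fmt == "genbank":
        genes = read_genbank_cds(inp.path, country=inp.country)
        if inp.label:
            for g in genes:
                g.genome = inp.label
        return genes
    raise ValueError(f"unknown input format {inp.fmt!r}")


def analyze_cohort(
    genes_by_genome: Mapping[str, Sequence[CodingSequence]],
    config: RunConfig | None = None,
    prefiltered: bool = False,
) -> CohortAnalysis:
    """Filter and analyze a multi-genome cohort.

    Each genome gets its own pooled reference for CAI/CBI/FOP; correlation,
    neutrality and the CBI~E.ENC fit are computed over genes pooled across
    genomes (``corr_level='gene'``) or over genome means
    (``corr_level='genome'``).  Clustering needs at least two genomes.
    """
    config = config or RunConfig()
    analyses: dict[str, GenomeAnalysis] = {}
    selected: dict[str, list[CodingSequence]] = {}
    reports: dict[str, FilterReport] = {}
    for label, genes in genes_by_genome.items():
        if prefiltered:
            kept, report = list(genes), FilterReport(
                genome=label, n_total=len(genes), n_selected=len(genes)
            )
        else:
            kept, report = apply_selection_filters(
                genes,
                start_codons=config.start_codons,
                min_length=config.min_length,
                genome_label=label,
            )
        reports[label] = report
        selected[label] = kept
        logger.info(
            "%s: %d of %d genes pass filters", label, report.n_selected, report.n_total
        )
        if kept:
            analyses[label] = analyze_genome(
                kept,
                genome=label,
                superior_rscu=config.superior_rscu,
                fop_mode=config.fop_mode,
            )
    if analyses:
        all_metrics = pd.concat(
            [a.metrics for a in analyses.values()], ignore_index=True
        )
    else:
        all_metrics = pd.DataFrame()
    pooled = pooled_counts([a.pooled for a in analyses.values()], source="pooled")
    pooled_rscu = compute_rscu(pooled)

    corr = neut = fit = None
    stats_df = all_metrics
    if config.corr_level == "genome" and analyses:
        rows = []
        for label, a in analyses.items():
            s = summarize_genome(a.metrics, a.rscu, genome=label)
            rows.append({"gene": label, "genome": label, **s.means})
        stats_df = pd.DataFrame(rows)
    if len(stats_df) >= 3:
        try:
            corr = correlation_matrix(stats_df)
            neut = neutrality_stats(stats_df)
            fit = cbi_enc_relationship(stats_df)
        except ValueError as exc:
            logger.warning("cohort statistics unavailable: %s", exc)

    cluster = None
    if len(analyses) >= 2:
        labels = list(analyses)
        try:
            cluster = cluster_genomes(
                [analyses[l].rscu for l in labels], labels, linkage_method=config.linkage
            )
        except ValueError as exc:
            logger.warning("clustering skipped: %s", exc)

    return CohortAnalysis(
        genomes=analyses,
        selected=selected,
        filter_reports=reports,
        all_metrics=all_metrics,
        pooled_rscu=pooled_rscu,
        correlation=corr,
        neutrality=neut,
        cbi_eenc=fit,
        cluster=cluster,
    )


def _fit_row(name: str, fit: LinearFit | None) -> dict:
    if fit is None:
        return {"analysis": name, "r": math.nan, "slope": math.nan,
                "intercept": math.nan, "n": 0}
    return {"analysis": name, "r": fit.r, "slope": fit.slope,
            "intercept": fit.intercept, "n": fit.n}


def write_outputs(result: CohortAnalysis, config: RunConfig) -> dict[str, str]:
    """Write all tabular/tree outputs; returns {output name: path}."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def save_df(df: pd.DataFrame, name: str, **kw) -> None:
        p = outdir / name
        df.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FORMAT, **kw)
        outputs[name] = str(p)

    write_filter_reports(result.filter_reports.values(), outdir / "filter_report.tsv")
    outputs["filter_report.tsv"] = str(outdir / "filter_report.tsv")

    save_df(result.all_metrics, "gene_metrics.tsv")

    rscu_tables = {label: a.rscu for label, a in result.genomes.items()}
    counts = {label: a.pooled for label, a in result.genomes.items()}
    save_df(rscu_long_table(rscu_tables, counts), "rscu_per_genome.tsv")
    save_df(rscu_long_table({"pooled": result.pooled_rscu}), "rscu_pooled.tsv")

    summaries = []
    for label, a in result.genomes.items():
        s = summarize_genome(a.metrics, a.rscu, genome=label)
        summaries.append({"genome": label, "n_genes": s.n_genes, **s.means})
    if result.genomes and len(result.all_metrics):
        s_all = summarize_genome(result.all_metrics, result.pooled_rscu, genome="ALL")
        summaries.append({"genome": "ALL", "n_genes": s_all.n_genes, **s_all.means})
    save_df(pd.DataFrame(summaries), "genome_summary.tsv")

    if result.correlation is not None:
        p = outdir / "correlation_matrix.tsv"
        result.correlation.r.to_csv(p, sep="\t", float_format=_FLOAT_FORMAT)
        outputs["correlation_matrix.tsv"] = str(p)
        p = outdir / "correlation_n.tsv"
        result.correlation.n.to_csv(p, sep="\t")
        outputs["correlation_n.tsv"] = str(p)

    df = result.all_metrics
    if len(df):
        save_df(enc_plot_table(df), "enc_plot.tsv")
        save_df(df[["gene", "genome", "pr2_x", "pr2_y"]], "pr2.tsv")
        save_df(df[["gene", "genome", "gc3", "gc12"]], "neutrality.tsv")
        try:
            eenc = equalize_enc(df["enc"].to_numpy(float), df["cbi"].to_numpy(float))
            save_df(
                df[["gene", "genome", "cbi", "enc"]].assign(eenc=eenc),
                "cbi_eenc.tsv",
            )
        except ValueError:
            pass
        profile = length_gc_profile(df, max_len=config.max_protein_length)
        save_df(profile.rows, "length_gc.tsv")
        save_df(profile.binned, "length_gc_binned.tsv")

    fits = pd.DataFrame(
        [
            _fit_row("cbi_vs_eenc", result.cbi_eenc),
            _fit_row("neutrality_gc12_vs_gc3", result.neutrality),
        ]
    )
    save_df(fits, "fits.tsv")

    if result.cluster is not None:
        p = outdir / "genomes.nwk"
        p.write_text(result.cluster.newick + "\n")
        outputs["genomes.nwk"] = str(p)
        result.cluster.distance_matrix().to_csv(
            outdir / "rscu_distances.tsv", sep="\t", float_format=_FLOAT_FORMAT
        )
        outputs["rscu_distances.tsv"] = str(outdir / "rscu_distances.tsv")

    if config.plots and len(df):
        from . import plots

        outputs.update(plots.standard_plots(result, config, outdir / "plots"))
    return outputs


def write_manifest(config: RunConfig, outputs: Mapping[str, str]) -> str:
    cfg = config.to_dict()
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest = {
        "package": "codonuse",
        "version": __version__,
        "config": cfg,
        "config_hash": digest,
        "seed": config.seed,
        "outputs": dict(outputs),
    }
    path = Path(config.outdir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return str(path)


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Run the full pipeline for the configured inputs; returns output paths."""
    genes_by_genome: dict[str, list[CodingSequence]] = {}
    for inp in config.inputs:
        label = inp.label or Path(inp.path).stem
        genes_by_genome[label] = read_genome(inp)
    result = analyze_cohort(genes_by_genome, config)
    outputs = write_outputs(result, config)
    if config.write_filtered:
        outdir = Path(config.outdir)
        for label, kept in result.selected.items():
            p = outdir / f"{label}.filtered.fasta"
            write_fasta(kept, p)
            outputs[p.name] = str(p)
    outputs["manifest.json"] = write_manifest(config, outputs)
    return outputs
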