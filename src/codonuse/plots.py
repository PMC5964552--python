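"""Standard diagnostic plots (PNG, matplotlib Agg backend).

These mirror the classic codon-usage figures: the ENC plot with the
expected-ENC curve, the PR2 quadrant plot, the neutrality plot, the pooled
RSCU bar chart with abundant codons highlighted, the per-genome RSCU
heatmap, the CBI versus equalized-ENC scatter with its fitted line, the
length-versus-GC scatter and the genome dendrogram.
"""

from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster.hierarchy import dendrogram

from .analysis import equalize_enc
from .genetic_code import CLUSTER_CODONS, CODONS, STOP_SYMBOL, CODON_TO_AA, rna_codon
from .metrics import expected_enc

if TYPE_CHECKING:  # pragma: no cover
    from .pipeline import CohortAnalysis, RunConfig


def _savefig(fig, path: Path) -> str:
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return str(path)


def enc_plot(df, path: Path) -> str:
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(df["gc3"], df["enc"], s=4, alpha=0.3, label="genes")
    s = np.linspace(0.01, 0.99, 200)
    ax.plot(s, [expected_enc(v) for v in s], "r-", label="expected ENC")
    ax.set_xlabel("GC3")
    ax.set_ylabel("ENC")
    ax.legend()
    return _savefig(fig, path)


def pr2_plot(df, path: Path) -> str:
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(df["pr2_x"], df["pr2_y"], s=4, alpha=0.3)
    ax.axhline(0.5, color="grey", lw=0.8)
    ax.axvline(0.5, color="grey", lw=0.8)
    ax.set_xlabel("G3/(G3+C3)")
    ax.set_ylabel("A3/(A3+T3)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    return _savefig(fig, path)


def neutrality_plot(df, path: Path) -> str:
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(df["gc3"], df["gc12"], s=4, alpha=0.3)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("GC3")
    ax.set_ylabel("GC12")
    return _savefig(fig, path)


def rscu_bar_plot(rscu, path: Path, abundant_threshold: float = 1.5) -> str:
    codons = [c for c in CODONS if CODON_TO_AA[c] != STOP_SYMBOL]
    vals = np.array([rscu.rscu[c] for c in codons])
    colors = ["red" if v > abundant_threshold else ("blue" if v < 0.5 else "grey") for v in vals]
    fig, ax = plt.subplots(figsize=(12, 4))
    ax.bar(range(len(codons)), np.nan_to_num(vals), color=colors)
    ax.axhline(1.0, color="k", lw=0.6)
    ax.set_xticks(range(len(codons)))
    ax.set_xticklabels([rna_codon(c) for c in codons], rotation=90, fontsize=6)
    ax.set_ylabel("RSCU")
    return _savefig(fig, path)


def rscu_heatmap(rscu_tables: dict, path: Path) -> str:
    labels = list(rscu_tables)
    M = np.array([[rscu_tables[l].rscu[c] for c in CLUSTER_CODONS] for l in labels])
    fig, ax = plt.subplots(figsize=(12, 0.4 * len(labels) + 2))
    im = ax.imshow(M, aspect="auto", cmap="viridis")
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels, fontsize=7)
    ax.set_xticks(range(len(CLUSTER_CODONS)))
    ax.set_xticklabels([rna_codon(c) for c in CLUSTER_CODONS], rotation=90, fontsize=5)
    fig.colorbar(im, ax=ax, label="RSCU")
    return _savefig(fig, path)


def cbi_eenc_plot(df, fit, path: Path) -> str:
    cbi = df["cbi"].to_numpy(float)
    eenc = equalize_enc(df["enc"].to_numpy(float), cbi)
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(cbi, eenc, s=4, alpha=0.3)
    if fit is not None and np.isfinite(fit.slope):
        x = np.linspace(np.nanmin(cbi), np.nanmax(cbi), 50)
        ax.plot(x, fit.intercept + fit.slope * x, "r-",
                label=f"r = {fit.r:.3f}")
        ax.legend()
    ax.set_xlabel("CBI")
    ax.set_ylabel("equalized ENC")
    return _savefig(fig, path)


def length_gc_plot(df, path: Path, max_len: int = 1500) -> str:
    sub = df[df["protein_length"] < max_len]
    fig, ax = plt.subplots(figsize=(6, 4.5))
    ax.scatter(sub["protein_length"], sub["gc3"], s=4, alpha=0.3, label="GC3")
    ax.scatter(sub["protein_length"], sub["gc12"], s=4, alpha=0.3, label="GC12")
    ax.set_xlabel("protein length (aa)")
    ax.set_ylabel("GC fraction")
    ax.legend()
    return _savefig(fig, path)


def dendrogram_plot(cluster, path: Path) -> str:
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(cluster.labels) + 2))
    dendrogram(cluster.linkage_matrix, labels=list(cluster.labels),
               orientation="right", ax=ax)
    ax.set_xlabel("RSCU Euclidean distance")
    return _savefig(fig, path)


def standard_plots(result: "CohortAnalysis", config: "RunConfig", outdir: Path) -> dict[str, str]:
    """Render the full plot set for a cohort analysis; returns name->path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = result.all_metrics
    out: dict[str, str] = {}
    out["plots/enc_plot.png"] = enc_plot(df, outdir / "enc_plot.png")
    out["plots/pr2.png"] = pr2_plot(df, outdir / "pr2.png")
    out["plots/neutrality.png"] = neutrality_plot(df, outdir / "neutrality.png")
    out["plots/rscu_pooled.png"] = rscu_bar_plot(
        result.pooled_rscu, outdir / "rscu_pooled.png", config.abundant_rscu
    )
    if result.genomes:
        out["plots/rscu_heatmap.png"] = rscu_heatmap(
            {l: a.rscu for l, a in result.genomes.items()}, outdir / "rscu_heatmap.png"
        )
    try:
        out["plots/cbi_eenc.png"] = cbi_eenc_plot(df, result.cbi_eenc, outdir / "cbi_eenc.png")
    except ValueError:
        pass
    out["plots/length_gc.png"] = length_gc_plot(df, outdir / "length_gc.png",
                                                config.max_protein_length)
    if result.cluster is not None:
        out["plots/dendrogram.png"] = dendrogram_plot(result.cluster, outdir / "dendrogram.png")
    return out
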