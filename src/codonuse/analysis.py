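"""Genome- and cohort-level analyses.

Builds on the per-gene metrics: pooled genome summaries, the correlation
matrix over the basic indices, the neutrality regression (GC12 on GC3),
ENC equalization onto the CBI range and the CBI~E.ENC fit, the
length-versus-GC profile, and RSCU-based hierarchical clustering of
genomes with Newick output.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage as scipy_linkage
from scipy.spatial.distance import pdist, squareform
from skbio.tree import TreeNode

from .genetic_code import CLUSTER_CODONS, CODONS, CODON_TO_AA
from .metrics import (
    GENE_METRIC_FIELDS,
    CodonCountTable,
    GeneMetrics,
    RSCUTable,
    compute_rscu,
    expected_enc,
    gene_metrics,
    optimal_codons,
    pooled_counts,
    relative_adaptiveness,
)
from .sequences import CodingSequence

#: Correlation-matrix variable order (GC, GC3s, CAI, CBI, ENC, FoP, GC12).
CORRELATION_VARIABLES = ("gc", "gc3s", "cai", "cbi", "enc", "fop", "gc12")
CORRELATION_LABELS = ("GC", "GC3s", "CAI", "CBI", "ENC", "FoP", "GC12")


@dataclass
class GenomeAnalysis:
    """Per-gene metrics of one genome plus the genome-wide reference tables."""

    genome: str
    metrics: pd.DataFrame
    rscu: RSCUTable                  # plain pooled RSCU (no pseudocount)
    reference_rscu: RSCUTable        # pseudocounted RSCU behind w
    w: dict[str, float]
    optimal: frozenset[str]
    pooled: CodonCountTable


def metrics_dataframe(records: Iterable[GeneMetrics]) -> pd.DataFrame:
    df = pd.DataFrame([vars(m) for m in records])
    if df.empty:
        df = pd.DataFrame(columns=list(GENE_METRIC_FIELDS))
    return df[list(GENE_METRIC_FIELDS)]


def analyze_genome(
    genes: Sequence[CodingSequence],
    genome: str | None = None,
    superior_rscu: float = 1.6,
    fop_mode: str = "ratio",
    pseudocount: float = 0.5,
) -> GenomeAnalysis:
    """Compute all per-gene indices for one genome.

    The CAI reference is self-referential: relative adaptiveness ``w`` is
    derived from the pooled RSCU of the genome's own selected genes, with
    zero-count codons given a pseudo-count of ``pseudocount`` so that no
    observed family produces ``w = 0``.  Optimal codons are those with
    pooled (unpseudocounted) RSCU strictly above ``superior_rscu``.
    """
    if genome is None:
        labels = {g.genome for g in genes}
        genome = labels.pop() if len(labels) == 1 else "combined"
    pooled = pooled_counts(genes, source=genome)
    rscu = compute_rscu(pooled)
    reference = compute_rscu(pooled, pseudocount=pseudocount)
    w = relative_adaptiveness(reference)
    optimal = optimal_codons(rscu, threshold=superior_rscu)
    records = [
        gene_metrics(g, w, optimal, fop_mode=fop_mode, reference_rscu=rscu)
        for g in genes
    ]
    return GenomeAnalysis(
        genome=genome,
        metrics=metrics_dataframe(records),
        rscu=rscu,
        reference_rscu=reference,
        w=w,
        optimal=optimal,
        pooled=pooled,
    )


@dataclass
class GenomeSummary:
    """Per-genome means of every metric plus the pooled RSCU table."""

    genome: str
    n_genes: int
    means: dict[str, float]
    n_defined: dict[str, int]
    rscu: RSCUTable


_SUMMARY_FIELDS = tuple(f for f in GENE_METRIC_FIELDS if f not in ("gene", "genome"))


def summarize_genome(metrics: pd.DataFrame, rscu: RSCUTable, genome: str | None = None) -> GenomeSummary:
    """Arithmetic means of each index over genes with defined values.

    Infinite ENC values (possible for extremely short or uniform genes)
    are excluded from the ENC mean alongside NaN.  The pooled RSCU comes
    from summed counts, not from averaging per-gene RSCU.
    """
    if genome is None:
        labels = set(metrics["genome"]) if len(metrics) else set()
        genome = labels.pop() if len(labels) == 1 else "combined"
    means: dict[str, float] = {}
    n_defined: dict[str, int] = {}
    for f in _SUMMARY_FIELDS:
        col = pd.to_numeric(metrics[f], errors="coerce").replace([np.inf, -np.inf], np.nan)
        n = int(col.notna().sum())
        n_defined[f] = n
        means[f] = float(col.mean()) if n else math.nan
    return GenomeSummary(
        genome=genome, n_genes=len(metrics), means=means, n_defined=n_defined, rscu=rscu
    )


def equalize_enc(
    enc_values: Sequence[float], cbi_values: Sequence[float]
) -> np.ndarray:
    """Rescale ENC affinely onto the CBI range of the same gene set.

    ``E.ENC = (ENC - ENCmin)/(ENCmax - ENCmin) * (CBImax - CBImin) + CBImin``
    with the extrema taken over defined (finite) values of the supplied
    lists.  Raises when either range is degenerate.
    """
    enc = np.asarray(enc_values, dtype=float)
    cbi = np.asarray(cbi_values, dtype=float)
    enc_f = enc[np.isfinite(enc)]
    cbi_f = cbi[np.isfinite(cbi)]
    if enc_f.size < 2 or cbi_f.size < 2:
        raise ValueError("need at least 2 defined ENC and CBI values")
    enc_min, enc_max = enc_f.min(), enc_f.max()
    cbi_min, cbi_max = cbi_f.min(), cbi_f.max()
    if enc_max == enc_min:
        raise ValueError("degenerate ENC range: max(ENC) == min(ENC)")
    return (enc - enc_min) / (enc_max - enc_min) * (cbi_max - cbi_min) + cbi_min


@dataclass
class LinearFit:
    r: float
    slope: float
    intercept: float
    n: int


def _paired_fit(x: np.ndarray, y: np.ndarray) -> LinearFit:
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need at least 3 paired defined values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return LinearFit(math.nan, math.nan, math.nan, int(x.size))
    res = stats.linregress(x, y)
    return LinearFit(float(res.rvalue), float(res.slope), float(res.intercept), int(x.size))


def cbi_enc_relationship(metrics: pd.DataFrame) -> LinearFit:
    """Pearson r and OLS line for CBI (x) versus equalized ENC (y).

    Because the equalization is affine, r equals the plain correlation of
    CBI with raw ENC; the rescaling only places both variables on a common
    axis range for plotting.
    """
    cbi = metrics["cbi"].to_numpy(dtype=float)
    enc = metrics["enc"].to_numpy(dtype=float)
    eenc = equalize_enc(enc, cbi)
    return _paired_fit(cbi, eenc)


def neutrality_stats(metrics: pd.DataFrame) -> LinearFit:
    """Neutrality plot statistics: OLS regression of GC12 (y) on GC3 (x).

    A slope near 1 indicates mutation pressure acting equally on all codon
    positions; a slope near 0 indicates selection constraining positions 1
    and 2 independently of third-position composition.
    """
    return _paired_fit(
        metrics["gc3"].to_numpy(dtype=float), metrics["gc12"].to_numpy(dtype=float)
    )


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations over the basic codon-usage indices."""

    variables: tuple[str, ...]
    r: pd.DataFrame
    n: pd.DataFrame


def correlation_matrix(
    metrics: pd.DataFrame,
    variables: Sequence[str] = CORRELATION_VARIABLES,
    labels: Sequence[str] = CORRELATION_LABELS,
    gc3s_column: str = "gc3",
    min_periods: int = 3,
) -> CorrelationMatrix:
    """Pearson correlation matrix across pooled genes, pairwise-complete.

    ``gc3s_column`` selects which per-gene column stands behind the GC3s
    variable: the default uses all-codon third-position GC (``gc3``);
    pass ``"gc3s"`` for the synonymous-only variant.
    """
    cols = {}
    for var, lab in zip(variables, labels):
        src = gc3s_column if var == "gc3s" else var
        cols[lab] = pd.to_numeric(metrics[src], errors="coerce").replace(
            [np.inf, -np.inf], np.nan
        )
    sub = pd.DataFrame(cols)
    r = sub.corr(method="pearson", min_periods=min_periods)
    notna = sub.notna().astype(int)
    n = pd.DataFrame(notna.T.values @ notna.values, index=r.index, columns=r.columns)
    return CorrelationMatrix(variables=tuple(labels), r=r, n=n)


@dataclass
class LengthGCProfile:
    """Per-gene length/GC rows plus binned means for trend inspection."""

    rows: pd.DataFrame
    binned: pd.DataFrame
    max_len: int
    bin_width: int


def length_gc_profile(
    metrics: pd.DataFrame, max_len: int = 1500, bin_width: int = 50
) -> LengthGCProfile:
    """Protein length versus GC12/GC3 for proteins shorter than ``max_len`` aa.

    The cap is strict (a 1500-aa protein is excluded).  Binned means use
    half-open length bins ``[i*bin_width, (i+1)*bin_width)``.
    """
    rows = metrics.loc[
        metrics["protein_length"] < max_len, ["protein_length", "gc12", "gc3"]
    ].reset_index(drop=True)
    if len(rows):
        bins = (rows["protein_length"] // bin_width).astype(int)
        binned = (
            rows.assign(bin_start=bins * bin_width)
            .groupby("bin_start")
            .agg(
                n=("protein_length", "size"),
                mean_length=("protein_length", "mean"),
                mean_gc12=("gc12", "mean"),
                mean_gc3=("gc3", "mean"),
            )
            .reset_index()
        )
    else:
        binned = pd.DataFrame(columns=["bin_start", "n", "mean_length", "mean_gc12", "mean_gc3"])
    return LengthGCProfile(rows=rows, binned=binned, max_len=max_len, bin_width=bin_width)


def enc_plot_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-gene (GC3, ENC, expected ENC) rows for the ENC plot."""
    out = metrics[["gene", "genome", "gc3", "enc"]].copy()
    out["expected_enc"] = [
        expected_enc(s) if np.isfinite(s) else math.nan for s in out["gc3"]
    ]
    return out


@dataclass
class ClusterResult:
    """Hierarchical clustering of genomes by their pooled RSCU profiles."""

    labels: tuple[str, ...]
    condensed_distances: np.ndarray
    linkage_matrix: np.ndarray
    newick: str

    def distance_matrix(self) -> pd.DataFrame:
        sq = squareform(self.condensed_distances)
        return pd.DataFrame(sq, index=list(self.labels), columns=list(self.labels))


def rscu_matrix(per_genome_rscu: Sequence[RSCUTable], labels: Sequence[str]) -> np.ndarray:
    """Stack per-genome RSCU tables into a (genomes x 59) matrix.

    The 59 dimensions are the sense codons minus ATG and TGG (single-codon
    amino acids) — the stop codons and the two no-choice codons would only
    encode amino-acid composition, not synonymous preference.  An
    undefined RSCU entry is an error naming the genome and codon.
    """
    X = np.empty((len(labels), len(CLUSTER_CODONS)), dtype=float)
    for i, (table, label) in enumerate(zip(per_genome_rscu, labels)):
        for j, codon in enumerate(CLUSTER_CODONS):
            v = table.rscu[codon]
            if math.isnan(v):
                raise ValueError(f"genome {label}: RSCU undefined for codon {codon}")
            X[i, j] = v
    return X


def cluster_genomes(
    per_genome_rscu: Sequence[RSCUTable],
    labels: Sequence[str],
    linkage_method: str = "single",
) -> ClusterResult:
    """Agglomerative clustering of genomes on Euclidean RSCU distance.

    Pairwise Euclidean distances between 59-dimensional RSCU vectors are
    joined by the requested linkage (default single, mirroring the
    classic pdist/dendrogram defaults); the dendrogram is serialized to
    Newick with branch lengths derived from merge heights.
    """
    if len(per_genome_rscu) != len(labels):
        raise ValueError("one RSCU table per label required")
    if len(labels) < 2:
        raise ValueError("need at least 2 genomes to cluster")
    X = rscu_matrix(per_genome_rscu, labels)
    d = pdist(X, metric="euclidean")
    Z = scipy_linkage(d, method=linkage_method)
    tree = TreeNode.from_linkage_matrix(Z, list(labels))
    buf = io.StringIO()
    tree.write(buf)
    return ClusterResult(
        labels=tuple(labels),
        condensed_distances=d,
        linkage_matrix=Z,
        newick=buf.getvalue().strip(),
    )


def rscu_long_table(rscu_tables: Mapping[str, RSCUTable], counts: Mapping[str, CodonCountTable] | None = None) -> pd.DataFrame:
    """Long-format RSCU table: one row per (genome, codon)."""
    rows = []
    for label, table in rscu_tables.items():
        for codon in CODONS:
            row = {
                "genome": label,
                "codon": codon,
                "amino_acid": CODON_TO_AA[codon],
                "rscu": table.rscu[codon],
            }
            if counts is not None and label in counts:
                row["count"] = counts[label].counts[codon]
            rows.append(row)
    return pd.DataFrame(rows)
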