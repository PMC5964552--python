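"""Per-gene codon-usage indices.

This module implements the metric suite for a single gene (or a pooled
genome treated as one long gene):

* codon counting into a 64-entry table;
* RSCU, the relative synonymous codon usage
  ``RSCU_ij = g_ij / ((1/n_i) * sum_j g_ij)``, computed per synonymous
  family, with the three stop codons treated as one family of size 3;
* the effective number of codons
  ``ENC = 2 + 9/f2 + 1/f3 + 5/f4 + 3/f6``, where ``fk`` is the mean
  per-amino-acid homozygosity ``f = (nS - 1)/(n - 1)``,
  ``S = sum_i (n_i/n)^2``, over the k-fold degenerate amino acids
  (9 two-fold, Ile as the single three-fold, 5 four-fold, 3 six-fold);
  values above 61 are reported as computed, never clipped;
* the expected ENC under mutation bias alone,
  ``ENC(s) = 2 + s + 29 / (s^2 + (1-s)^2)`` with ``s`` = GC3;
* CAI, the geometric mean of relative adaptiveness
  ``w_ij = RSCU_ij / RSCU_imax`` over the codons of the gene (stop codons,
  ATG and TGG excluded), evaluated in log space;
* CBI ``= (N_opt - N_ran)/(N_tot - N_ran)`` and FOP over a set of optimal
  ("superior") codons, by default those with genome-wide RSCU > 1.6;
* positional GC composition (GC, GC12, GC3, GC3s and the four
  third-position base fractions) and the PR2 coordinates
  ``x = G3/(G3+C3)``, ``y = A3/(A3+T3)``.

Undefined quantities (e.g. RSCU of an absent family, ENC of a gene missing
a whole degeneracy class) are reported as NaN, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genetic_code import (
    BASES,
    CODONS,
    CODON_TO_AA,
    ENC_CLASSES,
    FAMILIES,
    NONDEGENERATE_CODONS,
    SENSE_CODONS,
    SINGLE_CODON_AAS,
    STOP_CODONS,
    STOP_SYMBOL,
    dna_codon,
)
from .sequences import CodingSequence

_BASE_CODE = np.full(256, -1, dtype=np.int16)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i

_STOP_SET = frozenset(STOP_CODONS)


def codon_count_vector(seq: str) -> np.ndarray:
    """Count non-overlapping codons of ``seq`` into a length-64 int vector.

    The vector is indexed in lexicographic ACGT codon order (see
    :data:`codonuse.genetic_code.CODONS`).
    """
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    arr = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.size and arr.min() < 0:
        raise ValueError("sequence contains non-ACGT characters")
    idx = arr[0::3] * 16 + arr[1::3] * 4 + arr[2::3]
    return np.bincount(idx, minlength=64)


@dataclass
class CodonCountTable:
    """Counts of the 64 codons for one gene or one pooled genome."""

    counts: dict[str, int]
    source: str = ""

    @classmethod
    def from_sequence(cls, gene: CodingSequence) -> "CodonCountTable":
        return cls.from_string(gene.seq, source=gene.id)

    @classmethod
    def from_string(cls, seq: str, source: str = "") -> "CodonCountTable":
        vec = codon_count_vector(seq)
        return cls(counts={c: int(vec[i]) for i, c in enumerate(CODONS)}, source=source)

    @classmethod
    def from_vector(cls, vec: np.ndarray, source: str = "") -> "CodonCountTable":
        return cls(counts={c: int(vec[i]) for i, c in enumerate(CODONS)}, source=source)

    def vector(self) -> np.ndarray:
        return np.array([self.counts[c] for c in CODONS], dtype=np.int64)

    def total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def nt_total(self) -> int:
        return 3 * self.total()


def count_codons(gene: CodingSequence) -> CodonCountTable:
    """Codon counts for one gene; the terminal stop codon is included."""
    return CodonCountTable.from_sequence(gene)


def pooled_counts(
    tables: Iterable[CodonCountTable | CodingSequence], source: str = "pooled"
) -> CodonCountTable:
    """Sum codon counts over genes (equivalent to counting the concatenation)."""
    vec = np.zeros(64, dtype=np.int64)
    for t in tables:
        if isinstance(t, CodingSequence):
            vec += codon_count_vector(t.seq)
        else:
            vec += t.vector()
    return CodonCountTable.from_vector(vec, source=source)


@dataclass
class RSCUTable:
    """RSCU values for the 64 codons; NaN marks codons of absent families."""

    rscu: dict[str, float]
    source: str = ""

    def __getitem__(self, codon: str) -> float:
        return self.rscu[dna_codon(codon)]

    def defined(self) -> dict[str, float]:
        return {c: v for c, v in self.rscu.items() if not math.isnan(v)}

    def vector(self, codons: Sequence[str]) -> np.ndarray:
        return np.array([self.rscu[c] for c in codons], dtype=float)


def compute_rscu(counts: CodonCountTable, pseudocount: float = 0.0) -> RSCUTable:
    """RSCU per synonymous family, including the 3-codon stop family.

    ``pseudocount`` (used when building a CAI reference) replaces zero
    counts *within families that are observed at least once*, so that no
    observed family yields a zero relative adaptiveness.  Families with no
    occurrences at all are NaN.
    """
    rscu: dict[str, float] = {}
    for fam in FAMILIES.values():
        g = np.array([counts.counts[c] for c in fam], dtype=float)
        total = g.sum()
        if total == 0:
            for c in fam:
                rscu[c] = math.nan
            continue
        if pseudocount > 0:
            g[g == 0] = pseudocount
            total = g.sum()
        expected = total / len(fam)
        for c, v in zip(fam, g):
            rscu[c] = float(v / expected)
    return RSCUTable(rscu=rscu, source=counts.source)


def fk_homozygosity(family_counts: Sequence[int]) -> float:
    """Codon homozygosity ``f = (nS - 1)/(n - 1)`` for one amino acid.

    ``n`` is the number of occurrences of the amino acid and
    ``S = sum_i (n_i/n)^2`` over its synonymous codons.  Undefined (NaN)
    when ``n < 2``; note that ``f`` may fall below ``1/k`` for small
    ``n`` (e.g. counts (2, 2) give 1/3), which is why per-gene ENC can
    exceed 61.
    """
    n = int(sum(family_counts))
    if n < 2:
        return math.nan
    s = sum((ni / n) ** 2 for ni in family_counts)
    return (n * s - 1.0) / (n - 1.0)


def enc_from_class_means(f2: float, f3: float, f4: float, f6: float) -> float:
    """``ENC = 2 + 9/f2 + 1/f3 + 5/f4 + 3/f6``; infinite if a mean is 0."""
    means = (f2, f3, f4, f6)
    if any(math.isnan(f) for f in means):
        return math.nan
    if any(f == 0 for f in means):
        return math.inf
    return 2.0 + 9.0 / f2 + 1.0 / f3 + 5.0 / f4 + 3.0 / f6


def compute_enc(counts: CodonCountTable) -> float:
    """Effective number of codons of a gene from its codon counts.

    Per degeneracy class the homozygosities of the member amino acids are
    averaged over amino acids with ``n >= 2``.  A missing three-fold class
    mean (Ile absent or seen once) falls back to the average of the
    two-fold and four-fold class means; if any other class is entirely
    missing the ENC of the gene is undefined (NaN).  Values range from 20
    (one codon per amino acid) upward without any cap at 61.
    """
    class_means: dict[int, float] = {}
    for k, aas in ENC_CLASSES.items():
        fks = []
        for aa in aas:
            f = fk_homozygosity([counts.counts[c] for c in FAMILIES[aa]])
            if not math.isnan(f):
                fks.append(f)
        class_means[k] = float(np.mean(fks)) if fks else math.nan
    if math.isnan(class_means[3]) and not math.isnan(class_means[2]) and not math.isnan(class_means[4]):
        class_means[3] = (class_means[2] + class_means[4]) / 2.0
    return enc_from_class_means(class_means[2], class_means[3], class_means[4], class_means[6])


def expected_enc(gc3: float) -> float:
    """Expected ENC under mutation bias alone: ``2 + s + 29/(s^2 + (1-s)^2)``."""
    s = float(gc3)
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3 must lie in [0, 1], got {s}")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def relative_adaptiveness(reference_rscu: RSCUTable) -> dict[str, float]:
    """Relative adaptiveness ``w = RSCU / RSCU_max`` within each family.

    Stop codons and the single-codon amino acids Met (ATG) and Trp (TGG)
    are excluded; families absent from the reference yield no entries.
    """
    w: dict[str, float] = {}
    for aa, fam in FAMILIES.items():
        if aa == STOP_SYMBOL or aa in SINGLE_CODON_AAS:
            continue
        vals = [reference_rscu.rscu[c] for c in fam]
        if any(math.isnan(v) for v in vals):
            continue
        m = max(vals)
        if m == 0:
            continue
        for c, v in zip(fam, vals):
            w[c] = v / m
    return w


def compute_cai(counts: CodonCountTable, w: Mapping[str, float]) -> float:
    """Codon adaptation index: geometric mean of ``w`` over counted codons.

    ``L`` is the number of counted codons that carry a defined ``w``
    (stop codons, ATG and TGG never do).  Computed in log space; NaN when
    no counted codon has a defined ``w``.
    """
    log_sum = 0.0
    L = 0
    for codon, n in counts.counts.items():
        if n == 0 or codon not in w:
            continue
        wv = w[codon]
        if wv <= 0:
            raise ValueError(f"codon {codon} has non-positive w={wv}; "
                             "use a pseudocounted reference")
        L += n
        log_sum += n * math.log(wv)
    if L == 0:
        return math.nan
    return math.exp(log_sum / L)


def optimal_codons(reference_rscu: RSCUTable, threshold: float = 1.6) -> frozenset[str]:
    """Superior codons: non-stop codons with reference RSCU strictly > threshold."""
    return frozenset(
        c for c in SENSE_CODONS
        if not math.isnan(reference_rscu.rscu[c]) and reference_rscu.rscu[c] > threshold
    )


def _optimal_by_aa(optimal: Iterable[str]) -> dict[str, list[str]]:
    # sorted iteration keeps float summation order independent of set
    # iteration order (which varies with per-process hash randomization)
    by_aa: dict[str, list[str]] = {}
    for c in sorted(optimal):
        aa = CODON_TO_AA[c]
        if aa == STOP_SYMBOL:
            continue
        by_aa.setdefault(aa, []).append(c)
    return dict(sorted(by_aa.items()))


def compute_cbi(counts: CodonCountTable, optimal: Iterable[str]) -> float:
    """Codon bias index ``(N_opt - N_ran)/(N_tot - N_ran)``.

    ``N_opt`` counts optimal-codon occurrences; ``N_tot`` counts
    occurrences of the amino acids owning at least one optimal codon;
    ``N_ran`` is the expected optimal count under random synonymous
    choice, ``sum_aa n_aa * (#optimal codons of aa / family size)``.
    NaN when the optimal set is empty or ``N_tot == N_ran``.
    """
    by_aa = _optimal_by_aa(optimal)
    if not by_aa:
        return math.nan
    n_opt = n_tot = 0
    n_ran = 0.0
    for aa, opts in by_aa.items():
        fam = FAMILIES[aa]
        n_aa = sum(counts.counts[c] for c in fam)
        n_tot += n_aa
        n_ran += n_aa * len(opts) / len(fam)
        n_opt += sum(counts.counts[c] for c in opts)
    denom = n_tot - n_ran
    if denom == 0:
        return math.nan
    return (n_opt - n_ran) / denom


def compute_fop(
    counts: CodonCountTable,
    optimal: Iterable[str],
    mode: str = "ratio",
    rscu: RSCUTable | None = None,
) -> float:
    """Frequency of optimal codons.

    ``ratio`` (default): the fraction ``N_opt / N_tot`` of optimal-codon
    usage among amino acids possessing at least one optimal codon — the
    standard FOP.  ``rscu_weighted``: the count-weighted mean reference
    RSCU of the optimal codons used by the gene (an alternative reading of
    "weighted average of the RSCU of superior codons"); requires ``rscu``.
    """
    by_aa = _optimal_by_aa(optimal)
    if not by_aa:
        return math.nan
    if mode == "ratio":
        n_opt = n_tot = 0
        for aa, opts in by_aa.items():
            n_tot += sum(counts.counts[c] for c in FAMILIES[aa])
            n_opt += sum(counts.counts[c] for c in opts)
        return math.nan if n_tot == 0 else n_opt / n_tot
    if mode == "rscu_weighted":
        if rscu is None:
            raise ValueError("rscu_weighted mode requires a reference RSCU table")
        num = den = 0.0
        for opts in by_aa.values():
            for c in opts:
                n = counts.counts[c]
                num += n * rscu.rscu[c]
                den += n
        return math.nan if den == 0 else num / den
    raise ValueError(f"unknown FOP mode {mode!r}")


@dataclass
class Composition:
    """Positional base composition of a gene (over sense codons by default)."""

    n_codons: int
    gc: float
    gc1: float
    gc2: float
    gc12: float
    gc3: float
    gc3s: float
    a3: float
    t3: float
    g3: float
    c3: float


def positional_composition(
    counts: CodonCountTable, include_stops: bool = False
) -> Composition:
    """Per-position base fractions from codon counts.

    GC12 is the mean of the position-1 and position-2 GC fractions and the
    overall GC is ``(GC1 + GC2 + GC3)/3``.  Stop codons are excluded by
    default so the composition describes the translated frame.  ``gc3s``
    is the third-position GC restricted to synonymously variable codons
    (also excluding ATG and TGG, whose third base carries no choice).
    """
    pos = np.zeros((3, 4), dtype=float)   # all counted codons
    pos_s = np.zeros(4, dtype=float)      # third position, synonymous codons only
    n_codons = 0
    for codon, n in counts.counts.items():
        if n == 0:
            continue
        if codon in _STOP_SET and not include_stops:
            continue
        n_codons += n
        for p in range(3):
            pos[p, "ACGT".index(codon[p])] += n
        if codon not in NONDEGENERATE_CODONS:
            pos_s["ACGT".index(codon[2])] += n
    if n_codons == 0:
        nan = math.nan
        return Composition(0, nan, nan, nan, nan, nan, nan, nan, nan, nan, nan)
    # base order ACGT -> indices: A=0, C=1, G=2, T=3
    gc_by_pos = (pos[:, 1] + pos[:, 2]) / n_codons
    third = pos[2] / n_codons
    n_syn = pos_s.sum()
    gc3s = float((pos_s[1] + pos_s[2]) / n_syn) if n_syn else math.nan
    gc1, gc2, gc3 = (float(x) for x in gc_by_pos)
    return Composition(
        n_codons=n_codons,
        gc=(gc1 + gc2 + gc3) / 3.0,
        gc1=gc1,
        gc2=gc2,
        gc12=(gc1 + gc2) / 2.0,
        gc3=gc3,
        gc3s=gc3s,
        a3=float(third[0]),
        t3=float(third[3]),
        g3=float(third[2]),
        c3=float(third[1]),
    )


def pr2_coordinates(
    counts: CodonCountTable, include_stops: bool = False
) -> tuple[float, float]:
    """PR2 plot coordinates ``(G3/(G3+C3), A3/(A3+T3))`` over third positions.

    At the PR2 center (0.5, 0.5) the third-position bases obey A = T and
    G = C.  Either coordinate is NaN when its denominator is zero.
    """
    third = np.zeros(4, dtype=float)
    for codon, n in counts.counts.items():
        if n == 0 or (codon in _STOP_SET and not include_stops):
            continue
        third["ACGT".index(codon[2])] += n
    a3, c3, g3, t3 = third
    x = g3 / (g3 + c3) if (g3 + c3) > 0 else math.nan
    y = a3 / (a3 + t3) if (a3 + t3) > 0 else math.nan
    return float(x), float(y)


@dataclass
class GeneMetrics:
    """All per-gene codon-usage indices for one coding sequence."""

    gene: str
    genome: str
    protein_length: int
    n_codons: int
    enc: float
    cai: float
    cbi: float
    fop: float
    gc: float
    gc12: float
    gc3: float
    gc3s: float
    a3: float
    t3: float
    g3: float
    c3: float
    pr2_x: float
    pr2_y: float


#: TSV column order for per-gene metric tables.
GENE_METRIC_FIELDS = (
    "gene", "genome", "protein_length", "n_codons", "enc", "cai", "cbi", "fop",
    "gc", "gc12", "gc3", "gc3s", "a3", "t3", "g3", "c3", "pr2_x", "pr2_y",
)


def gene_metrics(
    gene: CodingSequence,
    w: Mapping[str, float],
    optimal: Iterable[str],
    fop_mode: str = "ratio",
    reference_rscu: RSCUTable | None = None,
) -> GeneMetrics:
    """Compute the full metric record for one gene.

    ``w`` and ``optimal`` come from a reference gene set (normally the
    pooled usage of the gene's genome).  ``protein_length`` counts codons
    excluding a terminal stop.
    """
    counts = count_codons(gene)
    n_codons = counts.total()
    has_terminal_stop = len(gene.seq) >= 3 and gene.seq[-3:] in _STOP_SET
    comp = positional_composition(counts)
    x, y = pr2_coordinates(counts)
    return GeneMetrics(
        gene=gene.id,
        genome=gene.genome,
        protein_length=n_codons - (1 if has_terminal_stop else 0),
        n_codons=n_codons,
        enc=compute_enc(counts),
        cai=compute_cai(counts, w),
        cbi=compute_cbi(counts, optimal),
        fop=compute_fop(counts, optimal, mode=fop_mode, rscu=reference_rscu),
        gc=comp.gc,
        gc12=comp.gc12,
        gc3=comp.gc3,
        gc3s=comp.gc3s,
        a3=comp.a3,
        t3=comp.t3,
        g3=comp.g3,
        c3=comp.c3,
        pr2_x=x,
        pr2_y=y,
    )


def stop_codon_partition(stop_rscu: Mapping[str, float]) -> dict[str, float]:
    """Fraction of stop-codon usage per stop codon from stop RSCU values.

    Because the three stop codons form one synonymous family of size 3,
    their RSCU values sum to 3 and ``RSCU/3`` is each codon's share of all
    stop codons (e.g. an RSCU of 1.645 means 54.8% of stops).  Accepts DNA
    or RNA codon spellings.
    """
    vals = {dna_codon(c): float(v) for c, v in stop_rscu.items()}
    if set(vals) != set(STOP_CODONS):
        raise ValueError(f"expected RSCU for exactly {STOP_CODONS}, got {sorted(vals)}")
    return {c: vals[c] / len(STOP_CODONS) for c in STOP_CODONS}
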