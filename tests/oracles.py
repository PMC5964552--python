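"""Independent brute-force reimplementations of every codon-usage index.

These oracles are written against the formulas directly, from the raw
sequence string, with plain dict/loop code and their own hardcoded genetic
code table.  They deliberately share nothing with the package internals so
that agreement between the two routes is evidence, not tautology.
"""

from __future__ import annotations

import math

_BASES = "TCAG"
# NCBI translation table 1 amino-acid string in TCAG codon order.
_AA_STRING = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

CODON_AA = {
    a + b + c: _AA_STRING[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
STOPS = [c for c, aa in CODON_AA.items() if aa == "*"]

AA_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(CODON_AA.items()):
    AA_CODONS.setdefault(aa, []).append(codon)


def codon_list(seq: str) -> list[str]:
    assert len(seq) % 3 == 0
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def oracle_counts(seq: str) -> dict[str, int]:
    counts = {c: 0 for c in CODON_AA}
    for codon in codon_list(seq):
        counts[codon] += 1
    return counts


def oracle_rscu(seq: str) -> dict[str, float]:
    """RSCU per synonymous family (stops form a family of 3); NaN if absent."""
    counts = oracle_counts(seq)
    rscu: dict[str, float] = {}
    for aa, codons in AA_CODONS.items():
        total = sum(counts[c] for c in codons)
        for c in codons:
            rscu[c] = math.nan if total == 0 else counts[c] * len(codons) / total
    return rscu


def oracle_fk(counts_for_aa: list[int]) -> float:
    n = sum(counts_for_aa)
    if n < 2:
        return math.nan
    s = sum((ni / n) ** 2 for ni in counts_for_aa)
    return (n * s - 1) / (n - 1)


def oracle_enc(seq: str) -> float:
    """ENC = 2 + 9/f2 + 1/f3 + 5/f4 + 3/f6 computed per amino acid."""
    counts = oracle_counts(seq)
    by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in AA_CODONS.items():
        k = len(codons)
        if aa == "*" or k == 1:
            continue
        f = oracle_fk([counts[c] for c in codons])
        if not math.isnan(f):
            by_class[k].append(f)
    means = {k: (sum(v) / len(v) if v else math.nan) for k, v in by_class.items()}
    if math.isnan(means[3]) and not math.isnan(means[2]) and not math.isnan(means[4]):
        means[3] = (means[2] + means[4]) / 2
    if any(math.isnan(means[k]) for k in (2, 3, 4, 6)):
        return math.nan
    if any(means[k] == 0 for k in (2, 3, 4, 6)):
        return math.inf
    return 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]


def oracle_w(reference_seq: str, pseudocount: float = 0.5) -> dict[str, float]:
    """Relative adaptiveness from a reference sequence's own codon usage."""
    counts = oracle_counts(reference_seq)
    w: dict[str, float] = {}
    for aa, codons in AA_CODONS.items():
        if aa in ("*", "M", "W"):
            continue
        g = [counts[c] for c in codons]
        if sum(g) == 0:
            continue
        g = [x if x > 0 else pseudocount for x in g]
        m = max(g)
        for c, x in zip(codons, g):
            w[c] = x / m
    return w


def oracle_cai(seq: str, w: dict[str, float]) -> float:
    """Direct product form of CAI (no log space)."""
    used = [c for c in codon_list(seq) if c in w]
    if not used:
        return math.nan
    prod = 1.0
    for c in used:
        prod *= w[c]
    return prod ** (1.0 / len(used))


def oracle_cbi(seq: str, optimal: set[str]) -> float:
    counts = oracle_counts(seq)
    aas = {CODON_AA[c] for c in optimal if CODON_AA[c] != "*"}
    if not aas:
        return math.nan
    n_opt = n_tot = 0
    n_ran = 0.0
    for aa in aas:
        codons = AA_CODONS[aa]
        n_aa = sum(counts[c] for c in codons)
        n_tot += n_aa
        n_opt += sum(counts[c] for c in codons if c in optimal)
        n_ran += n_aa * sum(1 for c in codons if c in optimal) / len(codons)
    if n_tot - n_ran == 0:
        return math.nan
    return (n_opt - n_ran) / (n_tot - n_ran)


def oracle_fop(seq: str, optimal: set[str]) -> float:
    counts = oracle_counts(seq)
    aas = {CODON_AA[c] for c in optimal if CODON_AA[c] != "*"}
    if not aas:
        return math.nan
    n_opt = sum(counts[c] for c in optimal if CODON_AA[c] in aas)
    n_tot = sum(counts[c] for aa in aas for c in AA_CODONS[aa])
    return math.nan if n_tot == 0 else n_opt / n_tot


def oracle_pr2(seq: str) -> tuple[float, float]:
    third = {b: 0 for b in "ACGT"}
    for codon in codon_list(seq):
        if codon in STOPS:
            continue
        third[codon[2]] += 1
    gc = third["G"] + third["C"]
    at = third["A"] + third["T"]
    x = third["G"] / gc if gc else math.nan
    y = third["A"] / at if at else math.nan
    return x, y


def oracle_composition(seq: str) -> tuple[float, float, float]:
    """(gc, gc12, gc3) over sense codons."""
    sense = [c for c in codon_list(seq) if c not in STOPS]
    n = len(sense)
    gcp = [sum(1 for c in sense if c[p] in "GC") / n for p in range(3)]
    return (sum(gcp) / 3, (gcp[0] + gcp[1]) / 2, gcp[2])
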