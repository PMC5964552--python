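"""Synthetic coding-sequence generation.

The generator emulates the shape of a bacterial CDS cohort — per-genome
sets of ~1000–2000 genes, lengths mostly 300–4500 nt — with two
independently controllable forces acting on synonymous codon choice:

* a *mutational tilt* ``t`` that multiplies the weight of every codon
  ending in G or C by ``exp(t)``; ``t`` is solved by bisection so the
  cohort hits a requested expected GC3 (``target_gc3``), emulating
  directional mutation pressure;
* a *selection-like bias* ``b`` (``bias_strength``) that multiplies the
  weight of one preferred codon per synonymous family by ``exp(b)``;
  ``b = 0`` gives uniform synonymous usage, large ``b`` collapses each
  family onto a single codon (driving per-gene ENC toward 20).

Within a family the codon probabilities are the softmax of these two
log-weights.  Each gene is framed as start codon + body + stop codon, and
cohorts can plant violations of the four selection filters at requested
rates with ground-truth labels, so filtering code can be tested against a
known answer.

Protein lengths are drawn from a lognormal distribution (median ~260 aa,
most genes under 500 aa) clipped to 100–1499 aa, i.e. 306–4503 nt with
framing.  Amino-acid composition defaults to uniform over the 20 amino
acids; a GC-rich proteome profile typical of high-GC bacteria is provided
for study-shaped cohorts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import AMINO_ACIDS, FAMILIES, STOP_CODONS
from .sequences import FILTER_RULES, CodingSequence, write_fasta

logger = logging.getLogger(__name__)

#: amino-acid frequency profile of a GC-rich bacterial proteome
#: (alanine/glycine/proline/arginine-rich), used by study-shaped cohorts.
GC_RICH_AA_FREQS: dict[str, float] = {
    "A": 0.12, "G": 0.09, "P": 0.06, "R": 0.07, "V": 0.09, "L": 0.10,
    "T": 0.07, "S": 0.06, "D": 0.06, "E": 0.06, "I": 0.04, "K": 0.02,
    "N": 0.02, "F": 0.03, "Q": 0.03, "H": 0.02, "Y": 0.02, "C": 0.01,
    "M": 0.015, "W": 0.015,
}


def _preferred_codon(aa: str, optimal_set: frozenset[str] | None) -> str:
    """One preferred codon per family: explicit override, else first C- then
    G-ending codon in table order (GC-enders mimic real optimal codons in
    GC-rich genomes)."""
    fam = FAMILIES[aa]
    if optimal_set:
        for c in fam:
            if c in optimal_set:
                return c
    for base in ("C", "G"):
        for c in fam:
            if c.endswith(base):
                return c
    return fam[0]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic genome (gene set).

    ``target_gc3 = None`` means no mutational tilt (``t = 0``), which with
    ``bias_strength = 0`` gives exactly uniform synonymous usage.
    ``bias_range`` (when set) draws a per-gene bias uniformly from the
    interval, planting gene-to-gene variation in selection intensity.
    ``filter_violation_rates`` maps rule name (length/start/frame/
    internal_stop) to the fraction of genes constructed to violate it.
    """

    n_genes: int = 1000
    median_protein_aa: float = 260.0
    sigma_log_aa: float = 0.45
    min_protein_aa: int = 100
    max_protein_aa: int = 1499
    target_gc3: float | None = None
    bias_strength: float = 0.0
    bias_range: tuple[float, float] | None = None
    optimal_codon_set: frozenset[str] | None = None
    filter_violation_rates: Mapping[str, float] = field(default_factory=dict)
    aa_freqs: Mapping[str, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for rule, rate in self.filter_violation_rates.items():
            if rule not in FILTER_RULES:
                raise ValueError(f"unknown filter rule {rule!r}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"violation rate for {rule!r} outside [0, 1]")
        if sum(self.filter_violation_rates.values()) > 1.0:
            raise ValueError("violation rates sum to more than 1")
        if self.target_gc3 is not None and not 0.0 <= self.target_gc3 <= 1.0:
            raise ValueError("target_gc3 must lie in [0, 1]")


def _aa_probs(spec: SyntheticSpec) -> np.ndarray:
    if spec.aa_freqs is None:
        return np.full(len(AMINO_ACIDS), 1.0 / len(AMINO_ACIDS))
    p = np.array([spec.aa_freqs.get(aa, 0.0) for aa in AMINO_ACIDS], dtype=float)
    if p.sum() <= 0:
        raise ValueError("amino-acid frequencies sum to zero")
    return p / p.sum()


def _family_probs(bias: float, tilt: float, optimal_set: frozenset[str] | None) -> dict[str, np.ndarray]:
    """Softmax codon probabilities per amino-acid family (plus stops)."""
    probs: dict[str, np.ndarray] = {}
    for aa, fam in FAMILIES.items():
        pref = _preferred_codon(aa, optimal_set) if aa != "*" else None
        logw = np.array(
            [
                tilt * (c[2] in "GC") + (bias if c == pref else 0.0)
                for c in fam
            ],
            dtype=float,
        )
        logw -= logw.max()
        w = np.exp(logw)
        probs[aa] = w / w.sum()
    return probs


def _expected_gc3(probs: Mapping[str, np.ndarray], aa_p: np.ndarray) -> float:
    e = 0.0
    for aa, p in zip(AMINO_ACIDS, aa_p):
        fam = FAMILIES[aa]
        gc_flags = np.array([c[2] in "GC" for c in fam], dtype=float)
        e += p * float(probs[aa] @ gc_flags)
    return e


def solve_tilt(
    target_gc3: float,
    bias: float,
    aa_p: np.ndarray,
    optimal_set: frozenset[str] | None = None,
    lo: float = -40.0,
    hi: float = 40.0,
    tol: float = 1e-10,
) -> float:
    """Bisection for the GC-ending tilt achieving ``target_gc3`` in expectation.

    Expected GC3 is monotone increasing in the tilt.  Targets outside the
    achievable range (Met/Trp pin some third positions to G) log a warning
    and clamp to the nearest achievable value.
    """
    f = lambda t: _expected_gc3(_family_probs(bias, t, optimal_set), aa_p) - target_gc3
    f_lo, f_hi = f(lo), f(hi)
    if f_lo >= 0:
        if f_lo > tol:
            logger.warning("target GC3 %.3f below achievable range; clamping", target_gc3)
        return lo
    if f_hi <= 0:
        if f_hi < -tol:
            logger.warning("target GC3 %.3f above achievable range; clamping", target_gc3)
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def _tilt_function(spec: SyntheticSpec, aa_p: np.ndarray):
    """Tilt as a function of per-gene bias, precomputed per genome.

    When bias varies per gene the exact bisection is replaced by linear
    interpolation over a 33-point grid across ``bias_range``; the tilt is
    smooth in the bias, so the induced GC3 error is far below sampling
    noise.
    """
    if spec.target_gc3 is None:
        return lambda b: 0.0
    if spec.bias_range is None:
        t0 = solve_tilt(spec.target_gc3, spec.bias_strength, aa_p, spec.optimal_codon_set)
        return lambda b: t0
    grid = np.linspace(spec.bias_range[0], spec.bias_range[1], 33)
    tilts = np.array(
        [solve_tilt(spec.target_gc3, b, aa_p, spec.optimal_codon_set) for b in grid]
    )
    return lambda b: float(np.interp(b, grid, tilts))


def _draw_protein_length(spec: SyntheticSpec, rng: np.random.Generator) -> int:
    la = int(round(rng.lognormal(math.log(spec.median_protein_aa), spec.sigma_log_aa)))
    return int(np.clip(la, spec.min_protein_aa, spec.max_protein_aa))


def _build_gene_seq(
    n_body_aa: int,
    probs: Mapping[str, np.ndarray],
    aa_p: np.ndarray,
    rng: np.random.Generator,
) -> str:
    """ATG + body codons drawn per family + one stop codon."""
    aas = rng.choice(len(AMINO_ACIDS), size=n_body_aa, p=aa_p)
    codons = np.empty(n_body_aa, dtype=object)
    for i, aa in enumerate(AMINO_ACIDS):
        where = np.flatnonzero(aas == i)
        if where.size == 0:
            continue
        fam = FAMILIES[aa]
        picks = rng.choice(len(fam), size=where.size, p=probs[aa])
        for j, k in zip(where, picks):
            codons[j] = fam[k]
    stop = STOP_CODONS[rng.choice(len(STOP_CODONS), p=probs["*"])]
    return "ATG" + "".join(codons) + stop


def generate_gene(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    gene_id: str = "synthetic_gene",
    genome: str = "synthetic",
) -> CodingSequence:
    """Generate one clean coding sequence under ``spec``.

    Deterministic for a fixed RNG state (or ``spec.seed`` when no RNG is
    passed).  The gene is start codon + body + terminal stop, passes all
    four selection filters, and its synonymous usage follows the
    tilt/bias softmax described in the module docstring.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    aa_p = _aa_probs(spec)
    bias = spec.bias_strength
    if spec.bias_range is not None:
        bias = float(rng.uniform(*spec.bias_range))
    tilt = 0.0
    if spec.target_gc3 is not None:
        tilt = solve_tilt(spec.target_gc3, bias, aa_p, spec.optimal_codon_set)
    probs = _family_probs(bias, tilt, spec.optimal_codon_set)
    la = _draw_protein_length(spec, rng)
    seq = _build_gene_seq(la - 1, probs, aa_p, rng)
    return CodingSequence(id=gene_id, genome=genome, seq=seq)


@dataclass
class CohortResult:
    """Synthetic multi-genome cohort plus the ground truth used to build it."""

    genes: dict[str, list[CodingSequence]]
    truth: pd.DataFrame  # gene, genome, rule_violated, target_gc3, bias, seed


def _plant_violation(
    rule: str,
    spec: SyntheticSpec,
    probs: Mapping[str, np.ndarray],
    aa_p: np.ndarray,
    rng: np.random.Generator,
) -> str:
    """Build a sequence violating exactly one selection rule."""
    if rule == "length":
        # total nt = 3 * (body + 2) <= 300  ->  body <= 98
        body = int(rng.integers(20, 99))
        return _build_gene_seq(body, probs, aa_p, rng)
    seq = _build_gene_seq(_draw_protein_length(spec, rng) - 1, probs, aa_p, rng)
    if rule == "start":
        return "CCC" + seq[3:]
    if rule == "frame":
        extra = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 3))))
        return seq + extra
    if rule == "internal_stop":
        n_codons = len(seq) // 3
        pos = int(rng.integers(1, n_codons - 1)) * 3
        stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
        return seq[:pos] + stop + seq[pos + 3 :]
    raise ValueError(f"unknown rule {rule!r}")


def generate_labelled_cohort(
    specs: Sequence[SyntheticSpec],
    labels: Sequence[str],
    seed: int | None = None,
) -> CohortResult:
    """Generate one gene set per label with planted filter violations.

    Each genome runs on its own RNG stream: ``spec.seed`` when set,
    otherwise a child stream spawned from ``seed``.  Violation rules are
    assigned per gene by a single categorical draw over
    ``filter_violation_rates`` (mutually exclusive), and recorded in the
    returned ground-truth table.
    """
    if len(specs) != len(labels):
        raise ValueError("one spec per label required")
    streams = np.random.SeedSequence(seed).spawn(len(specs))
    genes: dict[str, list[CodingSequence]] = {}
    truth_rows = []
    for spec, label, stream in zip(specs, labels, streams):
        rng = np.random.default_rng(spec.seed if spec.seed is not None else stream)
        aa_p = _aa_probs(spec)
        tilt_of = _tilt_function(spec, aa_p)
        rules = list(spec.filter_violation_rates)
        rates = np.array([spec.filter_violation_rates[r] for r in rules], dtype=float)
        genome_genes: list[CodingSequence] = []
        for i in range(spec.n_genes):
            bias = spec.bias_strength
            if spec.bias_range is not None:
                bias = float(rng.uniform(*spec.bias_range))
            probs = _family_probs(bias, tilt_of(bias), spec.optimal_codon_set)
            u = rng.random()
            rule = None
            acc = 0.0
            for r, rate in zip(rules, rates):
                acc += rate
                if u < acc:
                    rule = r
                    break
            gene_id = f"{label}_g{i + 1:05d}"
            if rule is None:
                seq = _build_gene_seq(_draw_protein_length(spec, rng) - 1, probs, aa_p, rng)
            else:
                seq = _plant_violation(rule, spec, probs, aa_p, rng)
            genome_genes.append(CodingSequence(id=gene_id, genome=label, seq=seq))
            truth_rows.append(
                {
                    "gene": gene_id,
                    "genome": label,
                    "rule_violated": rule or "",
                    "target_gc3": spec.target_gc3 if spec.target_gc3 is not None else np.nan,
                    "bias": bias,
                    "seed": spec.seed if spec.seed is not None else seed,
                }
            )
        genes[label] = genome_genes
    return CohortResult(genes=genes, truth=pd.DataFrame(truth_rows))


def generate_cohort(
    specs: Sequence[SyntheticSpec],
    labels: Sequence[str],
    seed: int | None = None,
) -> dict[str, list[CodingSequence]]:
    """Like :func:`generate_labelled_cohort` but returning only the genes."""
    return generate_labelled_cohort(specs, labels, seed=seed).genes


def write_cohort(cohort: CohortResult, outdir: str | Path) -> list[Path]:
    """Write one FASTA per genome plus the ground-truth TSV; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, genes in cohort.genes.items():
        p = outdir / f"{label}.fasta"
        write_fasta(genes, p)
        paths.append(p)
    truth_path = outdir / "ground_truth.tsv"
    cohort.truth.to_csv(truth_path, sep="\t", index=False)
    paths.append(truth_path)
    return paths


def study_like_specs(
    seed: int,
    n_genomes: int = 12,
    n_genes: int = 1200,
) -> tuple[list[SyntheticSpec], list[str]]:
    """Specs for a GC-rich multi-genome cohort shaped like a real study set.

    Twelve genomes of ~1200 genes each; third-position GC targets drawn
    around 0.79 (spread 0.74–0.84 across genomes) on a GC-rich proteome
    profile; per-gene selection bias uniform on [0, 3] so the cohort spans
    weakly to strongly biased genes; and ~12% of genes planted per filter
    rule so roughly half the cohort survives selection, as in real
    annotation sets with permissive gene calling.
    """
    rng = np.random.default_rng(seed)
    gc3_targets = np.clip(rng.normal(0.79, 0.025, size=n_genomes), 0.74, 0.84)
    rates = {r: 0.12 for r in FILTER_RULES}
    specs = [
        SyntheticSpec(
            n_genes=n_genes,
            target_gc3=float(gc3_targets[i]),
            bias_range=(0.0, 3.0),
            filter_violation_rates=rates,
            aa_freqs=GC_RICH_AA_FREQS,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for i in range(n_genomes)
    ]
    labels = [f"SYN{i + 1:02d}" for i in range(n_genomes)]
    return specs, labels


# ---------------------------------------------------------------------------
# hand-constructed genes with analytically known metric values
# ---------------------------------------------------------------------------

#: optimal-codon set paired with the ``cbi_*`` fixtures below.
KNOWN_OPTIMAL_SET = frozenset({"GCC"})


def known_answer_fixtures() -> dict[str, CodingSequence]:
    """Hand-constructed genes whose metric values are known analytically.

    * ``enc20``      — one codon per amino-acid family, each used 6 times:
      every homozygosity is 1, so ENC = 20 exactly; self-referential CAI
      is 1 (only family-maximal codons are used).
    * ``cai_one``    — same single-codon-per-family construction with the
      alternate codon choice; CAI = 1 under its own pooled reference.
    * ``rscu_uniform`` — every sense codon used exactly twice, so every
      sense-family RSCU is exactly 1.
    * ``pr2_center`` — third-position counts balanced (A3=T3=G3=C3
      including the ATG start), so the PR2 coordinates are (0.5, 0.5).
    * ``cbi_all_optimal`` / ``cbi_at_random`` — with the optimal set
      ``{GCC}``: all-GCC alanine usage gives CBI = FOP = 1; equal usage of
      the four alanine codons matches the random expectation, CBI = 0.
    * ``filter_short`` (exactly 300 nt), ``filter_bad_start``,
      ``filter_frame`` (307 nt), ``filter_internal_stop`` — each violates
      exactly one selection rule; ``clean`` passes all four.
    """
    fixtures: dict[str, CodingSequence] = {}

    def mk(name: str, seq: str) -> None:
        fixtures[name] = CodingSequence(id=name, genome="fixture", seq=seq)

    # one codon per family; Met first so the gene starts with ATG
    first_choice = ["ATG"] + [
        FAMILIES[aa][0] for aa in AMINO_ACIDS if aa != "M"
    ]
    mk("enc20", "".join(c * 6 for c in first_choice) + "TAA")
    last_choice = ["ATG"] + [
        FAMILIES[aa][-1] for aa in AMINO_ACIDS if aa != "M"
    ]
    mk("cai_one", "".join(c * 6 for c in last_choice) + "TAA")

    sense_once = ["ATG"] + [c for c in sorted(set().union(*[FAMILIES[aa] for aa in AMINO_ACIDS]))]
    body = "".join(c * 2 for c in sense_once if c != "ATG")
    mk("rscu_uniform", "ATG" + "ATG" + body + "TAA")

    mk("pr2_center", "ATG" + "GCT" * 30 + "GCA" * 30 + "GCC" * 30 + "GCG" * 29 + "TAA")

    mk("cbi_all_optimal", "ATG" + "GCC" * 100 + "TAA")
    mk("cbi_at_random", "ATG" + ("GCT" + "GCA" + "GCC" + "GCG") * 25 + "TAA")

    mk("clean", "ATG" + "GCC" * 100 + "TAA")                       # 306 nt
    mk("filter_short", "ATG" + "GCC" * 98 + "TAA")                 # 300 nt exactly
    mk("filter_bad_start", "CCC" + "GCC" * 100 + "TAA")
    mk("filter_frame", "ATG" + "GCC" * 100 + "TAA" + "A")          # 307 nt
    mk("filter_internal_stop", "ATG" + "GCC" * 50 + "TAA" + "GCC" * 50 + "TAA")
    return fixtures
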