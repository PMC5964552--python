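"""Reading, normalising and filtering coding sequences.

Input CDS sets arrive either as nucleotide multi-FASTA or as GenBank flat
files with annotated CDS features.  Before any codon counting, each gene set
is passed through four selection rules applied in a fixed order:

1. ``length``         — the sequence must contain more than ``min_length``
                        (default 300) bases; the bound is strict.
2. ``start``          — the first codon must belong to the accepted
                        start-codon set (default ``{ATG}``).
3. ``frame``          — the number of bases must be a multiple of 3.
4. ``internal_stop``  — no stop codon (TAA/TAG/TGA) may occur at any codon
                        position except the final one.  A terminal stop is
                        allowed and is kept for codon counting so that
                        stop-codon RSCU remains computable.

A sequence failing several rules is attributed to the first failing rule in
the order above, which makes the failure tallies deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import UndefinedSequenceError
from Bio.SeqFeature import SimpleLocation

from .genetic_code import START_CODONS_DEFAULT, STOP_CODONS

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")

#: filter rules in attribution order.
FILTER_RULES: tuple[str, ...] = ("length", "start", "frame", "internal_stop")


@dataclass
class CodingSequence:
    """One coding sequence: identifier, genome label and normalized bases."""

    id: str
    genome: str
    seq: str
    country: str | None = None

    @property
    def length_nt(self) -> int:
        return len(self.seq)

    def codons(self) -> list[str]:
        """Non-overlapping triplets from position 0; requires frame 0."""
        if len(self.seq) % 3:
            raise ValueError(f"{self.id}: length {len(self.seq)} not divisible by 3")
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]


@dataclass
class FilterReport:
    """Tallies from one pass of the four selection rules over a gene set."""

    genome: str
    n_total: int
    n_selected: int
    per_rule_failures: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in FILTER_RULES}
    )

    @property
    def n_failed(self) -> int:
        return sum(self.per_rule_failures.values())


def normalize_sequence(raw: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return raw.upper().replace("U", "T")


def read_fasta_cds(
    path: str | Path, genome_label: str, country: str | None = None
) -> list[CodingSequence]:
    """Read a nucleotide multi-FASTA into :class:`CodingSequence` records.

    Records containing bases other than A/C/G/T after normalization
    (including N and other IUPAC ambiguity codes) are excluded with a logged
    warning, because codon classification requires unambiguous bases.
    """
    path = Path(path)
    genes: list[CodingSequence] = []
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        seq = normalize_sequence(str(rec.seq))
        bad = set(seq) - _VALID_BASES
        if bad:
            logger.warning(
                "%s: record %s excluded (non-ACGT characters: %s)",
                path.name, rec.id, "".join(sorted(bad)),
            )
            continue
        genes.append(CodingSequence(id=rec.id, genome=genome_label, seq=seq, country=country))
    if n_records == 0 and path.stat().st_size > 0:
        raise ValueError(f"{path}: no FASTA records parsed; is this FASTA nucleotide data?")
    return genes


def _location_is_fuzzy(location) -> bool:
    for part in location.parts:
        if not isinstance(part, SimpleLocation):
            return True
        if type(part.start).__name__ != "ExactPosition" or type(part.end).__name__ != "ExactPosition":
            return True
    return False


def read_genbank_cds(path: str | Path, country: str | None = None) -> list[CodingSequence]:
    """Extract CDS features from a GenBank flat file.

    Minus-strand features are reverse-complemented and ``join(...)``
    locations concatenated in order (both via Biopython's feature
    extraction), so every returned sequence reads 5'->3' in coding sense.
    The genome label is the record accession.  CDS features with fuzzy
    location endpoints are skipped with a warning; a record without sequence
    data (no ORIGIN) is an error.
    """
    path = Path(path)
    genes: list[CodingSequence] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        n_cds = 0
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            n_cds += 1
            if feat.location is None or _location_is_fuzzy(feat.location):
                logger.warning("%s: CDS %d has fuzzy/missing location; skipped", rec.id, n_cds)
                continue
            try:
                raw = str(feat.extract(rec.seq))
            except UndefinedSequenceError as exc:
                raise ValueError(f"{path}: record {rec.id} has no ORIGIN sequence") from exc
            seq = normalize_sequence(raw)
            bad = set(seq) - _VALID_BASES
            if bad:
                logger.warning(
                    "%s: CDS %d excluded (non-ACGT characters: %s)",
                    rec.id, n_cds, "".join(sorted(bad)),
                )
                continue
            quals = feat.qualifiers
            gene_id = (
                quals.get("locus_tag", [None])[0]
                or quals.get("protein_id", [None])[0]
                or quals.get("gene", [None])[0]
                or f"{rec.id}_CDS{n_cds}"
            )
            genes.append(CodingSequence(id=gene_id, genome=rec.id, seq=seq, country=country))
    return genes


def first_violation(
    seq: str,
    start_codons: frozenset[str] | set[str] = START_CODONS_DEFAULT,
    min_length: int = 300,
) -> str | None:
    """Return the first selection rule violated by ``seq``, or None."""
    if len(seq) <= min_length:
        return "length"
    if seq[:3] not in start_codons:
        return "start"
    if len(seq) % 3:
        return "frame"
    for i in range(3, len(seq) - 3, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return "internal_stop"
    return None


def apply_selection_filters(
    genes: Sequence[CodingSequence],
    start_codons: frozenset[str] | set[str] = START_CODONS_DEFAULT,
    min_length: int = 300,
    genome_label: str | None = None,
) -> tuple[list[CodingSequence], FilterReport]:
    """Apply the four CDS selection rules and tally failures per rule.

    Returns the retained sequences (original order preserved) and a
    :class:`FilterReport`.  An empty input yields an empty output and a
    zero report.  Filtering is idempotent.
    """
    start_codons = frozenset(start_codons)
    kept: list[CodingSequence] = []
    failures = {r: 0 for r in FILTER_RULES}
    for gene in genes:
        rule = first_violation(gene.seq, start_codons, min_length)
        if rule is None:
            kept.append(gene)
        else:
            failures[rule] += 1
    if genome_label is None:
        labels = {g.genome for g in genes}
        genome_label = labels.pop() if len(labels) == 1 else "combined"
    report = FilterReport(
        genome=genome_label,
        n_total=len(genes),
        n_selected=len(kept),
        per_rule_failures=failures,
    )
    return kept, report


def write_fasta(genes: Iterable[CodingSequence], path: str | Path, width: int = 70) -> None:
    """Write sequences as multi-FASTA (plain text, fixed line width)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i : i + width] + "\n")


def write_filter_reports(reports: Iterable[FilterReport], path: str | Path) -> None:
    """Write filter reports as a TSV with one row per genome."""
    cols = ["genome", "n_total", "n_selected"] + [f"fail_{r}" for r in FILTER_RULES]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in reports:
            row = [r.genome, str(r.n_total), str(r.n_selected)] + [
                str(r.per_rule_failures[rule]) for rule in FILTER_RULES
            ]
            fh.write("\t".join(row) + "\n")
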