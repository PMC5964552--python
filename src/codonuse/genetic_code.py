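"""Standard genetic code tables and the degeneracy partition used by ENC.

Everything downstream (RSCU families, the ENC amino-acid classes, the
59-codon vector used for clustering) is derived from Biopython's standard
codon table at import time, so the constants here cannot drift out of sync
with the code itself.
"""

from __future__ import annotations

from Bio.Data import CodonTable

BASES = "ACGT"

#: All 64 codons in lexicographic ACGT order; index = 16*b1 + 4*b2 + b3.
CODONS: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

STOP_SYMBOL = "*"
_standard = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS: tuple[str, ...] = tuple(sorted(_standard.stop_codons))  # TAA, TAG, TGA

#: codon -> one-letter amino acid; the three stop codons map to "*" and are
#: treated as a synonymous family of size 3 (their RSCU values sum to 3).
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _c in STOP_CODONS:
    CODON_TO_AA[_c] = STOP_SYMBOL

SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if CODON_TO_AA[c] != STOP_SYMBOL)

_fam: dict[str, list[str]] = {}
for _c in CODONS:
    _fam.setdefault(CODON_TO_AA[_c], []).append(_c)
#: amino acid (or "*") -> synonymous codons, in ACGT order.
FAMILIES: dict[str, tuple[str, ...]] = {aa: tuple(v) for aa, v in _fam.items()}

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(aa for aa in FAMILIES if aa != STOP_SYMBOL))

#: Met and Trp: one codon each, hence no synonymous choice.
SINGLE_CODON_AAS: tuple[str, ...] = tuple(
    sorted(aa for aa, fam in FAMILIES.items() if aa != STOP_SYMBOL and len(fam) == 1)
)

# ENC partitions amino acids by codon degeneracy k; Met/Trp are excluded.
# The class sizes (9 two-fold, 1 three-fold, 5 four-fold, 3 six-fold) are the
# coefficients of the ENC formula.
_classes: dict[int, list[str]] = {}
for _aa, _f in FAMILIES.items():
    if _aa == STOP_SYMBOL or len(_f) == 1:
        continue
    _classes.setdefault(len(_f), []).append(_aa)
ENC_CLASSES: dict[int, tuple[str, ...]] = {k: tuple(sorted(v)) for k, v in sorted(_classes.items())}

assert {k: len(v) for k, v in ENC_CLASSES.items()} == {2: 9, 3: 1, 4: 5, 6: 3}

#: default accepted start codons; many actinobacterial genes start GTG/TTG,
#: so pipelines may widen this to {"ATG", "GTG", "TTG"}.
START_CODONS_DEFAULT = frozenset({"ATG"})
START_CODONS_EXTENDED = frozenset({"ATG", "GTG", "TTG"})

#: codons carrying no synonymous choice: the three stops plus ATG (Met) and
#: TGG (Trp).  Excluded from CAI/CBI/FOP and from clustering vectors.
NONDEGENERATE_CODONS = frozenset(STOP_CODONS) | {"ATG", "TGG"}

#: the 59 codons used for RSCU-based clustering of genomes.
CLUSTER_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in NONDEGENERATE_CODONS)
assert len(CLUSTER_CODONS) == 59


def dna_codon(codon: str) -> str:
    """Normalize a codon written in RNA or lowercase to uppercase DNA."""
    return codon.upper().replace("U", "T")


def rna_codon(codon: str) -> str:
    """Render a DNA codon in RNA form (T -> U), as codon tables are printed."""
    return codon.upper().replace("T", "U")
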