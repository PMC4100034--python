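"""Standard genetic code tables used throughout the package.

Everything here is a fixed constant of the standard (NCBI table 1) genetic
code: codon -> amino-acid mapping, synonymous families, stop codons, and the
set of amino acids whose tRNAs carry the A34 -> inosine ADAT modification.
"""

from __future__ import annotations

from Bio.Data import CodonTable
from Bio.Seq import Seq

NUCLEOTIDES = "ACGT"

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, 61 sense codons
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

ALL_CODONS: tuple[str, ...] = tuple(
    a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES
)

#: one-letter amino acid -> sorted tuple of synonymous codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)

AA_THREE_LETTER: dict[str, str] = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

#: amino acids whose tRNAs are substrates of ADAT (adenosine deaminase acting
#: on tRNA): the wobble A34 is edited to inosine, broadening decoding.
ADAT_AMINO_ACIDS: frozenset[str] = frozenset("ARILPSTV")

#: single-codon amino acids, always excluded from optimal-codon analyses
SINGLE_CODON_AA: frozenset[str] = frozenset(
    aa for aa, codons in AA_TO_CODONS.items() if len(codons) == 1
)


def reverse_complement(codon: str) -> str:
    """Reverse complement of a codon; the anticodon read 5'->3'."""
    return str(Seq(codon).reverse_complement())


def is_gc_ending(codon: str) -> bool:
    return codon[2] in "GC"
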