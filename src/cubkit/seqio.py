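"""Coding-sequence ingestion, codon counting, and positional composition.

A coding sequence (CDS) is accepted when its length is a positive multiple
of three, it contains only unambiguous bases, and it has no internal stop
codon. A terminal stop codon is kept on the record but stop codons are
excluded from every downstream tally (stop codons have no synonymous
competition, so the analysis space is the 61 sense codons).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import ALL_CODONS, STOP_CODONS

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")


class EmptyInputError(ValueError):
    """No record survived validation."""


@dataclass(frozen=True)
class CodingSequence:
    """A validated in-frame CDS."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence
        if not seq or len(seq) % 3 != 0:
            raise ValueError(f"{self.gene_id}: length {len(seq)} not a positive multiple of 3")
        if not VALID_BASES.issuperset(seq):
            raise ValueError(f"{self.gene_id}: ambiguity characters present")
        for i in range(0, len(seq) - 3, 3):
            if seq[i : i + 3] in STOP_CODONS:
                raise ValueError(f"{self.gene_id}: internal stop codon at position {i}")

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3


@dataclass(frozen=True)
class CodonCounts:
    """Per-gene codon tally over all 64 codons."""

    gene_id: str
    counts: Mapping[str, int]
    n_codons: int = field(default=0)

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if self.n_codons == 0:
            object.__setattr__(self, "n_codons", total)
        elif total != self.n_codons:
            raise ValueError(f"{self.gene_id}: counts sum {total} != n_codons {self.n_codons}")

    def sense_counts(self) -> dict[str, int]:
        return {c: n for c, n in self.counts.items() if c not in STOP_CODONS}


@dataclass(frozen=True)
class PositionalComposition:
    """GC and purine (A+G) fractions at the three codon positions."""

    gc: tuple[float, float, float]
    purine: tuple[float, float, float]

    def __post_init__(self) -> None:
        for v in (*self.gc, *self.purine):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"composition fraction {v} outside [0, 1]")


def _validate(gene_id: str, seq: str) -> str | None:
    """Return a rejection reason, or None if the sequence is a valid CDS."""
    if not seq or len(seq) % 3 != 0:
        return "length"
    if not VALID_BASES.issuperset(seq):
        return "ambiguity"
    for i in range(0, len(seq) - 3, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return "internal stop"
    return None


def read_cds_fasta(path: str | Path) -> list[CodingSequence]:
    """Read and validate a CDS FASTA file.

    Rejected records are logged with the reason (length / ambiguity /
    internal stop). When a gene id occurs on several records the longest
    surviving record is kept.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    EmptyInputError
        If no record survives validation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    best: dict[str, CodingSequence] = {}
    n_seen = n_rejected = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_seen += 1
        seq = str(record.seq).upper()
        reason = _validate(record.id, seq)
        if reason is not None:
            n_rejected += 1
            logger.warning("rejected %s: %s", record.id, reason)
            continue
        prev = best.get(record.id)
        if prev is None or len(seq) > len(prev.sequence):
            best[record.id] = CodingSequence(record.id, seq)
    if not best:
        raise EmptyInputError(f"{path}: no valid CDS among {n_seen} records")
    logger.info("read %d records, kept %d genes, rejected %d", n_seen, len(best), n_rejected)
    return list(best.values())


def write_cds_fasta(sequences: Iterable[CodingSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.sequence), id=s.gene_id, description="") for s in sequences]
    SeqIO.write(records, str(path), "fasta")


def count_codons(seq: CodingSequence) -> CodonCounts:
    """Tally consecutive non-overlapping triplets; the frame is never re-estimated."""
    tally = Counter(seq.sequence[i : i + 3] for i in range(0, len(seq.sequence), 3))
    counts = {c: tally.get(c, 0) for c in ALL_CODONS}
    return CodonCounts(seq.gene_id, counts, seq.n_codons)


def positional_composition(counts: CodonCounts, exclude_stops: bool = True) -> PositionalComposition:
    """GC and purine fractions at codon positions 1-3 from a codon tally.

    Stop codons are excluded by default so the composition describes the
    same 61-codon space the bias statistics operate on.
    """
    total = 0
    gc = [0, 0, 0]
    purine = [0, 0, 0]
    for codon, n in counts.counts.items():
        if n == 0 or (exclude_stops and codon in STOP_CODONS):
            continue
        total += n
        for k, base in enumerate(codon):
            if base in "GC":
                gc[k] += n
            if base in "AG":
                purine[k] += n
    if total == 0:
        raise ValueError(f"{counts.gene_id}: no usable codons; composition undefined")
    return PositionalComposition(
        gc=tuple(g / total for g in gc),
        purine=tuple(p / total for p in purine),
    )


def composition_table(sequences: Iterable[CodingSequence]) -> pd.DataFrame:
    """Per-gene composition summary as a DataFrame (gene_id, n_codons, gc1..purine3)."""
    rows = []
    for seq in sequences:
        comp = positional_composition(count_codons(seq))
        rows.append(
            {
                "gene_id": seq.gene_id,
                "n_codons": seq.n_codons,
                "gc1": comp.gc[0],
                "gc2": comp.gc[1],
                "gc3": comp.gc[2],
                "purine1": comp.purine[0],
                "purine2": comp.purine[1],
                "purine3": comp.purine[2],
            }
        )
    return pd.DataFrame(rows)
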