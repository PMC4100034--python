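"""Relative synonymous codon usage (RSCU) and optimal-codon identification.

RSCU for codon *j* of an amino acid with family size *n* is the observed
count scaled so that uniform usage within the family gives 1 for every
codon::

    RSCU_j = x_j * n / sum_k x_k

Optimal codons are defined from the tRNA pool: within each multi-codon
family the optimal codon is the one decoded by the most abundant tRNA,
where abundance is proxied by genomic tRNA gene copy number. Codons can
also be decoded by inosine-34 tRNAs: ADAT (adenosine deaminase acting on
tRNA) edits A34 to inosine in the tRNAs of eight amino acids (Ala, Arg,
Ile, Leu, Pro, Ser, Thr, Val), letting those tRNAs read C-ending codons.
The default scoring credits the A34 tRNA's copies to the C-ending codon
of each ADAT family; the rule is a pluggable hook.

Single-codon amino acids (Met, Trp) are always excluded, as is any family
whose maximal decoding weight is tied (in the human tRNA pool Glu has two
cognate tRNAs of equal copy number and is excluded on this ground).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pandas as pd

from .genetic_code import (
    AA_THREE_LETTER,
    AA_TO_CODONS,
    ADAT_AMINO_ACIDS,
    CODON_TO_AA,
    SENSE_CODONS,
    SINGLE_CODON_AA,
    is_gc_ending,
    reverse_complement,
)
from .seqio import CodonCounts

#: codon families entering RSCU / optimal-codon analyses (size >= 2)
MULTI_CODON_AA: tuple[str, ...] = tuple(
    sorted(aa for aa in AA_TO_CODONS if aa not in SINGLE_CODON_AA)
)


@dataclass(frozen=True)
class RSCUTable:
    """RSCU values for one gene group; NaN marks unobserved families."""

    group_id: str
    values: Mapping[str, float]

    def __getitem__(self, codon: str) -> float:
        return self.values[codon]


@dataclass(frozen=True)
class OptimalCodonSet:
    """amino_acid -> optimal codon, with exclusions and their reasons."""

    optimal: Mapping[str, str]
    excluded: Mapping[str, str] = field(default_factory=dict)

    @property
    def codons(self) -> tuple[str, ...]:
        return tuple(self.optimal[aa] for aa in sorted(self.optimal))

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted(self.optimal))


def compute_rscu(pooled: CodonCounts, group_id: str | None = None) -> RSCUTable:
    """RSCU over sense codons of multi-codon families from pooled counts.

    Counts are pooled across the group's genes before scaling (not averaged
    per gene), which makes the family-sum identity exact: within an observed
    family of size n the RSCU values sum to n. Families with zero observed
    codons get NaN, not 0.
    """
    sense = pooled.sense_counts()
    values: dict[str, float] = {}
    for aa in MULTI_CODON_AA:
        family = AA_TO_CODONS[aa]
        total = sum(sense.get(c, 0) for c in family)
        for codon in family:
            values[codon] = math.nan if total == 0 else sense.get(codon, 0) * len(family) / total
    return RSCUTable(group_id or pooled.gene_id, values)


def pool_counts(counts: Iterable[CodonCounts], group_id: str) -> CodonCounts:
    """Sum codon counts across a gene group."""
    pooled = {c: 0 for c in SENSE_CODONS}
    extra: dict[str, int] = {}
    for cc in counts:
        for codon, n in cc.counts.items():
            if codon in pooled:
                pooled[codon] += n
            else:
                extra[codon] = extra.get(codon, 0) + n
    pooled.update(extra)
    return CodonCounts(group_id, pooled)


# ---------------------------------------------------------------------------
# tRNA table


def load_trna_table(path: str | Path) -> pd.DataFrame:
    """Read a tRNA copy-number table (TSV: codon, anticodon, copies, adat)."""
    table = pd.read_csv(path, sep="\t", dtype={"codon": str, "anticodon": str})
    validate_trna_table(table)
    return table


def write_trna_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def validate_trna_table(table: pd.DataFrame) -> None:
    required = {"codon", "anticodon", "copies", "adat"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"tRNA table missing columns: {sorted(missing)}")
    if table["codon"].duplicated().any():
        raise ValueError("tRNA table has duplicate codons")
    if (table["copies"] < 0).any():
        raise ValueError("negative tRNA copy number")
    for row in table.itertuples():
        if row.anticodon != reverse_complement(row.codon):
            raise ValueError(f"{row.codon}: anticodon {row.anticodon} is not its reverse complement")
        if row.adat:
            aa = CODON_TO_AA.get(row.codon)
            if row.anticodon[0] != "A" or aa not in ADAT_AMINO_ACIDS:
                raise ValueError(f"{row.codon}: adat flag on a non-A34 or non-ADAT-family tRNA")


def default_adat_rule(codon: str, copies: Mapping[str, int]) -> int:
    """ADAT credit: A34-tRNA copies go to the C-ending codon of ADAT families.

    The A34 tRNA of a codon box is the Watson-Crick cognate of the T-ending
    codon; after inosine editing it also reads the C-ending codon.
    """
    aa = CODON_TO_AA[codon]
    if aa not in ADAT_AMINO_ACIDS or codon[2] != "C":
        return 0
    return copies.get(codon[:2] + "T", 0)


def identify_optimal_codons(
    trna: pd.DataFrame,
    adat_rule: Callable[[str, Mapping[str, int]], int] | None = default_adat_rule,
) -> OptimalCodonSet:
    """Optimal codon per multi-codon family from tRNA copy numbers.

    Decoding weight = copies of the codon's Watson-Crick cognate tRNA plus
    the ADAT contribution from *adat_rule* (pass None to disable). The
    optimal codon is the argmax; families whose maximum is tied are excluded
    with reason ``"tied tRNA counts"``; Met and Trp are excluded as
    single-codon amino acids.
    """
    validate_trna_table(trna)
    copies = dict(zip(trna["codon"], trna["copies"].astype(int)))
    missing = [c for c in SENSE_CODONS if c not in copies]
    if missing:
        raise ValueError(f"tRNA table missing sense codons: {missing}")
    optimal: dict[str, str] = {}
    excluded: dict[str, str] = {}
    for aa in sorted(AA_TO_CODONS):
        family = AA_TO_CODONS[aa]
        if len(family) == 1:
            excluded[aa] = "single-codon"
            continue
        weights = {
            codon: copies[codon] + (adat_rule(codon, copies) if adat_rule else 0)
            for codon in family
        }
        top = max(weights.values())
        winners = [c for c, w in weights.items() if w == top]
        if len(winners) > 1:
            excluded[aa] = "tied tRNA counts"
        else:
            optimal[aa] = winners[0]
    return OptimalCodonSet(optimal, excluded)


# ---------------------------------------------------------------------------
# group comparisons


@dataclass(frozen=True)
class OptimalUsageReport:
    """Pairwise and per-group optimal-codon usage comparisons.

    ``exceeds[(A, B)]`` lists amino acids where group A's optimal-codon RSCU
    strictly exceeds group B's. ``preferential[G]`` lists amino acids where
    the optimal codon attains the strict maximum RSCU within its family in
    group G. ``dropped`` lists amino acids excluded because some group had
    an unobserved (NaN) family.
    """

    exceeds: Mapping[tuple[str, str], tuple[str, ...]]
    preferential: Mapping[str, tuple[str, ...]]
    dropped: tuple[str, ...]

    def exceed_count(self, a: str, b: str) -> int:
        return len(self.exceeds[(a, b)])


def compare_optimal_usage(
    groups: Mapping[str, RSCUTable], optimal: OptimalCodonSet
) -> OptimalUsageReport:
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    analyzable = []
    dropped = []
    for aa in optimal.amino_acids:
        codon = optimal.optimal[aa]
        if any(math.isnan(g.values[codon]) for g in groups.values()):
            dropped.append(aa)
        else:
            analyzable.append(aa)

    exceeds: dict[tuple[str, str], tuple[str, ...]] = {}
    names = list(groups)
    for a in names:
        for b in names:
            if a == b:
                continue
            winners = [
                aa
                for aa in analyzable
                if groups[a].values[optimal.optimal[aa]] > groups[b].values[optimal.optimal[aa]]
            ]
            exceeds[(a, b)] = tuple(winners)

    preferential: dict[str, tuple[str, ...]] = {}
    for name, table in groups.items():
        pref = []
        for aa in analyzable:
            codon = optimal.optimal[aa]
            family = AA_TO_CODONS[aa]
            best = max(table.values[c] for c in family)
            if table.values[codon] == best and sum(table.values[c] == best for c in family) == 1:
                pref.append(aa)
        preferential[name] = tuple(pref)
    return OptimalUsageReport(exceeds, preferential, tuple(dropped))


def count_gc_ending(codons: Iterable[str]) -> int:
    """Number of codons whose third base is G or C."""
    return sum(1 for c in codons if is_gc_ending(c))


def rscu_long_table(
    groups: Mapping[str, RSCUTable], optimal: OptimalCodonSet | None = None
) -> pd.DataFrame:
    """Long-format RSCU export: group_id, amino_acid, codon, rscu, is_optimal."""
    opt_codons = set(optimal.codons) if optimal else set()
    rows = []
    for group_id in sorted(groups):
        table = groups[group_id]
        for codon in sorted(table.values):
            rows.append(
                {
                    "group_id": group_id,
                    "amino_acid": AA_THREE_LETTER[CODON_TO_AA[codon]],
                    "codon": codon,
                    "rscu": table.values[codon],
                    "is_optimal": codon in opt_codons,
                }
            )
    return pd.DataFrame(rows)
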