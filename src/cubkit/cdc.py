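"""The Codon Deviation Coefficient (CDC): a reference-set-free codon usage
bias statistic with bootstrap significance.

The CDC quantifies how far a gene's observed sense-codon usage departs from
the usage expected under its own background nucleotide composition. The
background model factorises each codon position independently into GC
content and purine (A+G) content, so per position ``k``::

    P(G) = gc[k] * purine[k]      P(C) = gc[k] * (1 - purine[k])
    P(A) = (1 - gc[k]) * purine[k]  P(T) = (1 - gc[k]) * (1 - purine[k])

A codon's expected probability is the product over its three positions;
stop codons are removed and the vector renormalised over the 61 sense
codons. The statistic is the cosine distance (1 - cosine similarity)
between observed frequencies and expected probabilities, which lies in
[0, 1]: 0 when usage matches the background exactly, approaching 1 when
usage concentrates where the background puts little mass. Because the
expectation is built from the gene's own composition, no reference gene
set is needed and regional composition (isochore) effects are absorbed
into the null.

Significance is assessed by a parametric bootstrap: pseudo-genes of the
same codon count are drawn i.i.d. from the expected usage and the
add-one-corrected tail probability of the observed CDC is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genetic_code import SENSE_CODONS
from .seqio import CodingSequence, CodonCounts, PositionalComposition, count_codons, positional_composition

#: base index (A=0, C=1, G=2, T=3) of each sense codon at each position
_BASE_INDEX = np.array(
    [["ACGT".index(b) for b in codon] for codon in SENSE_CODONS], dtype=np.intp
)

#: CUB rank edges shared by the five-group classification
CUB_RANK_EDGES: tuple[float, ...] = (0.10, 0.13, 0.16, 0.19)
CUB_RANK_LABELS: tuple[str, ...] = ("low", "medium-low", "medium", "medium-high", "high")


@dataclass(frozen=True)
class ExpectedCodonUsage:
    """Background codon-usage probabilities over the 61 sense codons."""

    probs: np.ndarray  # aligned with SENSE_CODONS

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (len(SENSE_CODONS),) or (p < 0).any():
            raise ValueError("probs must be 61 non-negative values")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"probs sum to {p.sum()}, expected 1")
        object.__setattr__(self, "probs", p)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(SENSE_CODONS, self.probs))


@dataclass(frozen=True)
class CUBResult:
    """Per-gene codon usage bias: CDC value, bootstrap P, composition."""

    gene_id: str
    cdc: float
    p_value: float
    n_codons: int
    gc1: float
    gc2: float
    gc3: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.cdc <= 1.0:
            raise ValueError(f"cdc {self.cdc} outside [0, 1]")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")


def expected_codon_usage(comp: PositionalComposition) -> ExpectedCodonUsage:
    """Expected sense-codon probabilities under the positional GC/purine model."""
    base_probs = np.empty((3, 4))
    for k in range(3):
        g, r = comp.gc[k], comp.purine[k]
        base_probs[k] = ((1 - g) * r, g * (1 - r), g * r, (1 - g) * (1 - r))  # A C G T
    probs = (
        base_probs[0, _BASE_INDEX[:, 0]]
        * base_probs[1, _BASE_INDEX[:, 1]]
        * base_probs[2, _BASE_INDEX[:, 2]]
    )
    total = probs.sum()
    if total <= 0:
        # composition puts all mass on stop codons; fall back to uniform
        probs = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    else:
        probs = probs / total
    return ExpectedCodonUsage(probs)


def _sense_vector(obs: CodonCounts) -> np.ndarray:
    sense = obs.sense_counts()
    return np.array([sense.get(c, 0) for c in SENSE_CODONS], dtype=float)


def cdc_statistic(obs: CodonCounts, exp: ExpectedCodonUsage) -> float:
    """1 - cosine similarity between observed and expected sense-codon usage."""
    x = _sense_vector(obs)
    return _cdc_from_vector(x, exp.probs)


def _cdc_from_vector(x: np.ndarray, p: np.ndarray) -> float:
    nx = np.linalg.norm(x)
    if nx == 0:
        raise ValueError("observed sense-codon vector has zero norm")
    cos = float(x @ p) / (nx * np.linalg.norm(p))
    return float(min(max(1.0 - cos, 0.0), 1.0))


def cdc_pvalue(
    obs: CodonCounts,
    exp: ExpectedCodonUsage,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Parametric-bootstrap tail probability of the observed CDC.

    ``n_boot`` pseudo-genes of the same codon count are drawn i.i.d. from
    *exp*; P = (1 + #{CDC_boot >= CDC_obs}) / (n_boot + 1), never zero.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = cdc_statistic(obs, exp)
    n_sense = int(_sense_vector(obs).sum())
    draws = rng.multinomial(n_sense, exp.probs, size=n_boot).astype(float)
    norms = np.linalg.norm(draws, axis=1)
    cos = draws @ exp.probs / (norms * np.linalg.norm(exp.probs))
    boot = 1.0 - cos
    return float((1 + int((boot >= observed - 1e-15).sum())) / (n_boot + 1))


def assign_cub_rank(cdc: float) -> str:
    """Five-group CUB rank with left-closed/right-open boundaries.

    low < 0.10 <= medium-low < 0.13 <= medium < 0.16 <= medium-high
    < 0.19 <= high.
    """
    if not 0.0 <= cdc <= 1.0:
        raise ValueError(f"cdc {cdc} outside [0, 1]")
    for edge, label in zip(CUB_RANK_EDGES, CUB_RANK_LABELS):
        if cdc < edge:
            return label
    return CUB_RANK_LABELS[-1]


def score_gene(
    seq: CodingSequence, n_boot: int = 1000, seed: int | np.random.Generator = 0
) -> CUBResult:
    """Full per-gene CUB scoring: composition -> expectation -> CDC -> bootstrap P."""
    counts = count_codons(seq)
    comp = positional_composition(counts)
    exp = expected_codon_usage(comp)
    cdc = cdc_statistic(counts, exp)
    p = cdc_pvalue(counts, exp, n_boot=n_boot, seed=seed)
    return CUBResult(seq.gene_id, cdc, p, seq.n_codons, *comp.gc)


def score_genes(
    sequences: Iterable[CodingSequence], n_boot: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Score a collection of genes; one child RNG stream per gene.

    Returns a DataFrame with columns gene_id, n_codons, cdc, p_value,
    gc1..gc3, cub_rank, sorted by gene_id for determinism.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for seq in sorted(sequences, key=lambda s: s.gene_id):
        res = score_gene(seq, n_boot=n_boot, seed=rng.spawn(1)[0])
        rows.append(
            {
                "gene_id": res.gene_id,
                "n_codons": res.n_codons,
                "cdc": res.cdc,
                "p_value": res.p_value,
                "gc1": res.gc1,
                "gc2": res.gc2,
                "gc3": res.gc3,
                "cub_rank": assign_cub_rank(res.cdc),
            }
        )
    return pd.DataFrame(rows)


def filter_significant(cub: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Keep genes whose bootstrap P is below *alpha* (default 0.05)."""
    return cub[cub["p_value"] < alpha].reset_index(drop=True)
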