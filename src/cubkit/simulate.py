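"""Synthetic data with the statistical structure the pipeline assumes.

Three generators, all deterministic given a seed:

* coding sequences whose within-family codon choice is a mixture
  ``(1 - beta) * uniform + beta * point mass on the optimal codon``, so the
  per-gene bias parameter beta in [0, 1] is the ground-truth strength of
  codon preference;
* a genes x tissues RPKM matrix with an expression-invariable (EIG) block,
  an expression-variable (EVG) block, tissue-specific (TS) genes, and
  intermediate-breadth genes, with class mean levels ordered
  EIG >= EVG >= TS;
* a synthetic tRNA copy-number table shaped like a genomic tRNA-database
  codon summary.

The default coupling rule ties beta to expression level only in EIG genes
(log-linear), leaving EVG/TS beta constant, so the downstream
CUB-expression correlation is positive in EIGs and near zero elsewhere —
the qualitative regime the analysis is designed to detect. Exported
ground truth (class, beta, mean expression) supports recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .expression import HUMAN_TISSUES_10
from .genetic_code import AA_TO_CODONS, ADAT_AMINO_ACIDS, CODON_TO_AA, reverse_complement
from .seqio import CodingSequence

#: designated optimal codon per multi-codon amino acid; Glu is deliberately
#: absent (its two tRNAs are tied in the fixture, mirroring the human pool)
OPTIMAL_TARGETS: dict[str, str] = {
    "N": "AAC", "D": "GAC", "C": "TGC", "Q": "CAG", "H": "CAC", "K": "AAG",
    "F": "TTC", "Y": "TAC", "G": "GGC", "V": "GTG", "I": "ATC", "T": "ACC",
    "R": "CGC", "L": "CTG", "S": "TCC", "A": "GCC", "P": "CCC",
}

#: optimal-codon set used by the CDS generator (Glu biased toward GAG)
GENERATOR_OPTIMAL: dict[str, str] = {**OPTIMAL_TARGETS, "E": "GAG", "M": "ATG", "W": "TGG"}

#: average human-protein-like amino-acid composition (fractions)
AA_COMPOSITION: dict[str, float] = {
    "A": 0.070, "R": 0.056, "N": 0.036, "D": 0.047, "C": 0.023,
    "Q": 0.048, "E": 0.071, "G": 0.066, "H": 0.026, "I": 0.043,
    "L": 0.099, "K": 0.057, "M": 0.022, "F": 0.037, "P": 0.063,
    "S": 0.083, "T": 0.053, "W": 0.012, "Y": 0.027, "V": 0.061,
}


def eig_only_coupling(label: str, log10_mean: float) -> float:
    """Default beta rule: log-linear in expression for EIGs, flat elsewhere."""
    if label == "EIG":
        return float(np.clip(0.10 + 0.25 * (log10_mean - 1.0), 0.0, 0.9))
    return 0.15


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition defaults for the synthetic scenario.

    Class sizes follow the default recovery scenario (1,500 genes across a
    10-tissue panel); noise levels put EIG across-tissue variation well
    below EVG (lognormal sigma 0.2 vs 1.2 on the natural-log scale) and
    class mean levels in the order EIG >= EVG >= TS.
    """

    n_eig: int = 200
    n_evg: int = 800
    n_ts_per_tissue: int = 30
    n_other: int = 200
    n_tissues: int = 10
    length_codons: tuple[int, int] = (100, 500)
    sigma_eig: float = 0.2
    sigma_evg: float = 1.2
    sigma_other: float = 0.8
    mean_log10: dict = field(
        default_factory=lambda: {"EIG": 2.2, "EVG": 1.5, "TS": 1.0, "other": 1.2}
    )
    sd_log10: float = 0.3
    expressed_threshold: float = 0.0
    coupling: Callable[[str, float], float] = eig_only_coupling
    seed: int = 0

    @property
    def tissues(self) -> tuple[str, ...]:
        return HUMAN_TISSUES_10[: self.n_tissues]


@dataclass(frozen=True)
class SimulatedData:
    """A full synthetic dataset plus its ground truth."""

    sequences: list[CodingSequence]
    expression: pd.DataFrame
    trna: pd.DataFrame
    truth: pd.DataFrame


def generate_cds_for_gene(
    gene_id: str, n_codons: int, beta: float, rng: np.random.Generator
) -> CodingSequence:
    """One CDS: amino acids from the fixed composition, codons from the
    (1 - beta) uniform / beta optimal mixture, terminal TAA appended."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta {beta} outside [0, 1]")
    aas = list(AA_COMPOSITION)
    probs = np.array(list(AA_COMPOSITION.values()))
    probs = probs / probs.sum()
    chosen = rng.choice(len(aas), size=n_codons, p=probs)
    codons = []
    for idx in chosen:
        aa = aas[idx]
        family = AA_TO_CODONS[aa]
        if len(family) == 1 or rng.random() < beta:
            codons.append(GENERATOR_OPTIMAL[aa])
        else:
            codons.append(family[rng.integers(len(family))])
    return CodingSequence(gene_id, "".join(codons) + "TAA")


def generate_cds(
    config: GeneratorConfig, truth: pd.DataFrame, seed: int | None = None
) -> list[CodingSequence]:
    """CDS for every gene in *truth* (needs columns gene_id, true_beta)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lo, hi = config.length_codons
    out = []
    for row in truth.itertuples():
        n_codons = int(rng.integers(lo, hi + 1))
        out.append(generate_cds_for_gene(row.gene_id, n_codons, row.true_beta, rng))
    return out


def generate_expression(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RPKM matrix and ground truth for the configured class structure.

    Truth columns: gene_id (index), true_class, true_beta, true_mean,
    ts_tissue, true_breadth.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    tissues = list(config.tissues)
    n_t = len(tissues)
    if n_t < 2:
        raise ValueError("need at least 2 tissues")
    specs: list[tuple[str, str]] = []  # (class, ts_tissue)
    specs += [("EIG", "")] * config.n_eig
    specs += [("EVG", "")] * config.n_evg
    for t in tissues:
        specs += [("TS", t)] * config.n_ts_per_tissue
    specs += [("other", "")] * config.n_other

    rows, truth_rows = [], []
    for i, (label, ts_tissue) in enumerate(specs):
        gene_id = f"g{i:05d}"
        log10_mean = rng.normal(config.mean_log10[label], config.sd_log10)
        mean = 10.0 ** log10_mean
        values = np.zeros(n_t)
        if label == "EIG":
            values = mean * np.exp(rng.normal(0.0, config.sigma_eig, n_t))
            breadth = n_t
        elif label == "EVG":
            values = mean * np.exp(rng.normal(0.0, config.sigma_evg, n_t))
            breadth = n_t
        elif label == "TS":
            values[tissues.index(ts_tissue)] = mean
            breadth = 1
        else:
            breadth = int(rng.integers(2, n_t))
            on = rng.choice(n_t, size=breadth, replace=False)
            values[on] = mean * np.exp(rng.normal(0.0, config.sigma_other, breadth))
        beta = config.coupling(label, log10_mean)
        rows.append(values)
        truth_rows.append(
            {
                "gene_id": gene_id,
                "true_class": label,
                "true_beta": beta,
                "true_mean": mean,
                "ts_tissue": ts_tissue,
                "true_breadth": breadth,
            }
        )
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    matrix = pd.DataFrame(rows, index=truth.index, columns=tissues)
    return matrix, truth


def generate_trna_fixture() -> pd.DataFrame:
    """Synthetic tRNA copy-number table over the 61 sense codons.

    Copy numbers are constructed, not measured: within each family the
    tRNA pool is arranged so that the designated optimal codon carries the
    largest decoding weight under the most-abundant-tRNA-plus-ADAT rule,
    Glu's two tRNAs are tied (so the family is excluded), and A34 tRNAs
    exist only in the eight ADAT amino-acid families. The table has the
    shape of a genomic tRNA-database codon summary (codon, anticodon,
    copies, adat) but its numbers are a synthetic stand-in.
    """
    copies: dict[str, int] = {}
    for aa, family in AA_TO_CODONS.items():
        if aa == "E":
            for codon in family:
                copies[codon] = 13
        elif len(family) == 1:
            copies[family[0]] = 10 if aa == "M" else 6
        elif aa in ADAT_AMINO_ACIDS:
            target = OPTIMAL_TARGETS[aa]
            a34_cognate = target[:2] + "T"  # codon read by the A34 tRNA
            for codon in family:
                if codon == target and codon[2] == "C":
                    copies[codon] = 3
                elif codon == target:  # G-ending target (Leu CTG, Val GTG)
                    copies[codon] = 12
                elif codon == a34_cognate:
                    copies[codon] = 8 if target[2] == "C" else 4
                else:
                    copies[codon] = 1
        else:
            target = OPTIMAL_TARGETS[aa]
            for codon in family:
                if codon == target:
                    copies[codon] = 10
                elif codon[2] == "T":
                    copies[codon] = 0  # A34 tRNAs are absent outside ADAT families
                else:
                    copies[codon] = 2
    rows = []
    for codon in sorted(copies):
        anticodon = reverse_complement(codon)
        adat = int(anticodon[0] == "A" and CODON_TO_AA[codon] in ADAT_AMINO_ACIDS)
        rows.append(
            {"codon": codon, "anticodon": anticodon, "copies": copies[codon], "adat": adat}
        )
    return pd.DataFrame(rows)


def generate_dataset(config: GeneratorConfig | None = None) -> SimulatedData:
    """Full synthetic dataset: expression + truth, CDS coupled via beta, tRNA table."""
    config = config or GeneratorConfig()
    matrix, truth = generate_expression(config, seed=config.seed)
    # independent child stream for sequences so the two blocks are decoupled
    sequences = generate_cds(config, truth.reset_index(), seed=config.seed + 1)
    return SimulatedData(sequences, matrix, generate_trna_fixture(), truth)


def small_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """A reduced scenario for quick runs (same structure, fewer genes)."""
    base = GeneratorConfig(
        n_eig=60, n_evg=160, n_ts_per_tissue=6, n_other=40, seed=seed
    )
    return replace(base, **overrides) if overrides else base
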