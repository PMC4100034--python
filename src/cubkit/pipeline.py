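"""End-to-end orchestration: score CUB, classify expression patterns,
compute group RSCU and optimal codons, and run the association suite.

The gene universe is the intersection of FASTA and expression-matrix ids;
asymmetric leftovers are logged. The bootstrap-significance filter
(CUB P < 0.05) is applied exactly once, immediately after scoring, and
every downstream analysis sees only the surviving genes. All randomness
flows from the single configured seed, so a rerun with the same config
reproduces every output byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cdc, rscu, stats
from .expression import ClusteringPolicy, classify_genes, expression_breadth, load_expression_matrix
from .rscu import compare_optimal_usage, identify_optimal_codons, load_trna_table
from .seqio import count_codons, read_cds_fasta

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    fasta: Path
    rpkm: Path
    trna: Path
    outdir: Path
    seed: int
    n_boot: int = 1000
    cub_p_cut: float = 0.05
    expressed_threshold: float = 0.0
    rank_edges: tuple[float, ...] = cdc.CUB_RANK_EDGES
    clustering: ClusteringPolicy = field(default_factory=ClusteringPolicy)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        clustering = ClusteringPolicy(**raw.pop("clustering", {}))
        rank_edges = tuple(raw.pop("rank_edges", cdc.CUB_RANK_EDGES))
        return cls(
            fasta=Path(raw["fasta"]),
            rpkm=Path(raw["rpkm"]),
            trna=Path(raw["trna"]),
            outdir=Path(raw["outdir"]),
            seed=int(raw["seed"]),
            n_boot=int(raw.get("n_boot", 1000)),
            cub_p_cut=float(raw.get("cub_p_cut", 0.05)),
            expressed_threshold=float(raw.get("expressed_threshold", 0.0)),
            rank_edges=rank_edges,
            clustering=clustering,
        )


def validate_config(config: RunConfig) -> list[str]:
    """Collect violations; an empty list means the config is runnable."""
    problems = []
    for name in ("fasta", "rpkm", "trna"):
        path = getattr(config, name)
        if not Path(path).exists():
            problems.append(f"{name} file not found: {path}")
    if list(config.rank_edges) != sorted(set(config.rank_edges)):
        problems.append(f"rank edges not strictly increasing: {config.rank_edges}")
    if not 0 < config.cub_p_cut <= 1:
        problems.append(f"cub_p_cut {config.cub_p_cut} outside (0, 1]")
    if config.n_boot < 100:
        problems.append(f"n_boot {config.n_boot} < 100")
    return problems


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle to outdir.

    Outputs: cub.tsv, classes.tsv, rscu.tsv, optimal_codons.tsv,
    correlations.tsv, breadth_correlations.tsv, contrasts.tsv, summary.txt.
    Returns the in-memory tables keyed by the same names.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sequences = read_cds_fasta(config.fasta)
    matrix = load_expression_matrix(config.rpkm)
    trna = load_trna_table(config.trna)

    fasta_ids = {s.gene_id for s in sequences}
    shared = sorted(fasta_ids & set(matrix.index))
    if not shared:
        raise ValueError("empty intersection between FASTA and expression-matrix gene ids")
    logger.info(
        "gene universe: %d shared (%d FASTA-only, %d matrix-only)",
        len(shared), len(fasta_ids - set(shared)), len(set(matrix.index) - set(shared)),
    )
    sequences = [s for s in sequences if s.gene_id in set(shared)]
    matrix = matrix.loc[shared]

    # --- CUB scoring and the single significance filter
    cub_all = cdc.score_genes(sequences, n_boot=config.n_boot, seed=config.seed)
    cub = cdc.filter_significant(cub_all, alpha=config.cub_p_cut)
    logger.info("CUB P<%.3g filter: %d of %d genes retained", config.cub_p_cut, len(cub), len(cub_all))

    # --- expression classification (all genes; associations use the filtered set)
    classes = classify_genes(matrix, config.expressed_threshold, config.clustering)
    breadth = expression_breadth(matrix, config.expressed_threshold)

    # --- RSCU of high-CUB genes per class, optimal codons, comparisons
    counts = {s.gene_id: count_codons(s) for s in sequences}
    keep = set(cub["gene_id"])
    high = set(cub.loc[cub["cub_rank"] == "high", "gene_id"])
    groups = {}
    for label in ("EIG", "EVG", "TS"):
        members = [g for g in classes.index[classes["label"] == label] if g in high]
        if members:
            pooled = rscu.pool_counts([counts[g] for g in members], f"high_CUB_{label}")
            groups[label] = rscu.compute_rscu(pooled, f"high_CUB_{label}")
    optimal = identify_optimal_codons(trna)
    rscu_table = rscu.rscu_long_table(groups, optimal)
    report = compare_optimal_usage(groups, optimal) if len(groups) >= 2 else None

    # --- associations over the significant set
    cub_sig = cub[cub["gene_id"].isin(keep)]
    correlations = stats.class_tissue_correlations(cub_sig, matrix, classes)
    breadth_corr = stats.breadth_stratified_correlations(
        cub_sig, matrix, breadth.loc[breadth.index.isin(keep)]
    )
    peak = matrix.max(axis=1)
    trend = stats.rank_trend(cub_sig, peak)
    gc3 = stats.gc3_analyses(cub_sig, matrix, classes)

    contrast_rows = []
    for entry in gc3["contrasts"]:
        contrast_rows.append({"comparison": "gc_high_vs_low_cub", **entry})
    if report is not None:
        for (a, b), aas in report.exceeds.items():
            contrast_rows.append(
                {
                    "comparison": "optimal_rscu_exceeds",
                    "class": f"{a}>{b}",
                    "n_amino_acids": len(aas),
                    "amino_acids": ",".join(aas),
                }
            )
        for name, aas in report.preferential.items():
            contrast_rows.append(
                {
                    "comparison": "optimal_preferential_use",
                    "class": name,
                    "n_amino_acids": len(aas),
                    "amino_acids": ",".join(aas),
                }
            )
    contrasts = pd.DataFrame(contrast_rows)

    optimal_df = pd.DataFrame(
        [{"amino_acid": aa, "codon": c, "status": "optimal"} for aa, c in sorted(optimal.optimal.items())]
        + [{"amino_acid": aa, "codon": "", "status": reason} for aa, reason in sorted(optimal.excluded.items())]
    )

    tables = {
        "cub": cub_all,
        "classes": classes.reset_index(),
        "rscu": rscu_table,
        "optimal_codons": optimal_df,
        "correlations": correlations,
        "breadth_correlations": breadth_corr,
        "rank_trend": trend,
        "contrasts": contrasts,
    }
    for name, table in tables.items():
        table.to_csv(outdir / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")

    summary = _summarize(config, cub_all, cub, classes, correlations, optimal, report)
    (outdir / "summary.txt").write_text(summary)
    tables["summary"] = summary
    return tables


def _summarize(config, cub_all, cub, classes, correlations, optimal, report) -> str:
    lines = [
        "cubkit pipeline summary",
        f"seed: {config.seed}   bootstrap replicates: {config.n_boot}",
        f"genes scored: {len(cub_all)}; significant (P < {config.cub_p_cut}): {len(cub)}",
        "class sizes: "
        + ", ".join(f"{k}={v}" for k, v in classes["label"].value_counts().items()),
        f"optimal codons: {len(optimal.optimal)} assigned; excluded: "
        + ", ".join(f"{aa} ({why})" for aa, why in sorted(optimal.excluded.items())),
    ]
    defined = correlations.dropna(subset=["r"])
    for label in ("EIG", "EVG", "TS"):
        sub = defined[defined["class"] == label]
        if len(sub):
            lines.append(
                f"median CUB-expression r in {label}: {sub['r'].median():.3f} "
                f"(over {len(sub)} tissue panels)"
            )
    if report is not None and ("EIG", "EVG") in report.exceeds:
        lines.append(
            f"high-CUB EIG optimal-codon RSCU exceeds EVG in "
            f"{len(report.exceeds[('EIG', 'EVG')])} amino acids"
        )
    return "\n".join(lines) + "\n"
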