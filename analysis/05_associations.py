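#!/usr/bin/env python
"""Association suite: CUB-expression correlations, breadth strata, CUB-rank
expression trend, and GC3 analyses.

Measures, over genes passing the bootstrap significance filter, the
Pearson and Spearman correlations between CDC and log10 RPKM per class
and tissue, the same correlation stratified by expression breadth, the
median expression trend across CUB ranks with adjacent-rank rank-sum
tests, and the GC3 relationships.
"""

import argparse
from pathlib import Path

import pandas as pd

from cubkit.cdc import filter_significant
from cubkit.expression import expression_breadth, load_expression_matrix
from cubkit.stats import (
    breadth_stratified_correlations,
    class_tissue_correlations,
    gc3_analyses,
    rank_trend,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--simdir", type=Path, default=Path("results/sim"))
    parser.add_argument("--cub", type=Path, default=Path("results/cub.tsv"))
    parser.add_argument("--classes", type=Path, default=Path("results/classes.tsv"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    matrix = load_expression_matrix(args.simdir / "rpkm.tsv")
    cub = filter_significant(pd.read_csv(args.cub, sep="\t"))
    classes = pd.read_csv(args.classes, sep="\t", index_col=0)

    panels = []
    for method in ("pearson", "spearman"):
        panels.append(class_tissue_correlations(cub, matrix, classes, method=method))
    corr = pd.concat(panels, ignore_index=True)
    corr.to_csv(args.outdir / "correlations.tsv", sep="\t", index=False, float_format="%.4g")
    med = corr[corr["method"] == "pearson"].dropna(subset=["r"]).groupby("class")["r"].median()
    print("median Pearson r (CDC vs log10 RPKM):", med.round(3).to_dict())

    breadth = expression_breadth(matrix)
    strata = breadth_stratified_correlations(cub, matrix, breadth)
    strata.to_csv(args.outdir / "breadth_correlations.tsv", sep="\t", index=False, float_format="%.4g")
    by_breadth = strata.dropna(subset=["r"]).groupby("breadth")["r"].median()
    print("median r by breadth:", by_breadth.round(3).to_dict())

    trend = rank_trend(cub, matrix.max(axis=1))
    trend.to_csv(args.outdir / "rank_trend.tsv", sep="\t", index=False, float_format="%.4g")
    print("median log10 peak RPKM by CUB rank:")
    print(trend[["cub_rank", "n", "median_log10_rpkm", "p_vs_previous"]].to_string(index=False))

    gc3 = gc3_analyses(cub, matrix, classes)
    pd.DataFrame(gc3["correlations"]).to_csv(
        args.outdir / "gc3_correlations.tsv", sep="\t", index=False, float_format="%.4g"
    )
    for row in gc3["correlations"]:
        print(f"{row['class']} {row['pair']}: r={row['r']:.3f} {row['stars']}")


if __name__ == "__main__":
    main()
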