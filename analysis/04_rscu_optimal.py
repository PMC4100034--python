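#!/usr/bin/env python
"""Optimal codons and RSCU comparison between high-bias gene classes.

Identifies the optimal codon of each multi-codon amino-acid family from
the tRNA table (most abundant cognate tRNA, with the ADAT inosine-34
credit for C-ending codons of the eight ADAT families), pools codon
counts of high-CUB genes per expression class, and compares optimal-codon
RSCU between classes.
"""

import argparse
from pathlib import Path

import pandas as pd

from cubkit.cdc import filter_significant
from cubkit.rscu import (
    compare_optimal_usage,
    compute_rscu,
    count_gc_ending,
    identify_optimal_codons,
    load_trna_table,
    pool_counts,
    rscu_long_table,
)
from cubkit.seqio import count_codons, read_cds_fasta


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--simdir", type=Path, default=Path("results/sim"))
    parser.add_argument("--cub", type=Path, default=Path("results/cub.tsv"))
    parser.add_argument("--classes", type=Path, default=Path("results/classes.tsv"))
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    trna = load_trna_table(args.simdir / "trna.tsv")
    opt = identify_optimal_codons(trna)
    print(f"optimal codons for {len(opt.optimal)} amino acids; "
          f"{count_gc_ending(opt.codons)} GC-ending")
    print("excluded:", ", ".join(f"{aa} ({why})" for aa, why in sorted(opt.excluded.items())))

    cub = filter_significant(pd.read_csv(args.cub, sep="\t"))
    classes = pd.read_csv(args.classes, sep="\t", index_col=0)
    counts = {s.gene_id: count_codons(s) for s in read_cds_fasta(args.simdir / "cds.fasta")}
    high = set(cub.loc[cub["cub_rank"].isin(["medium-high", "high"]), "gene_id"])

    groups = {}
    for label in ("EIG", "EVG", "TS"):
        members = [g for g in classes.index[classes["label"] == label] if g in high]
        if len(members) >= 5:
            groups[label] = compute_rscu(pool_counts([counts[g] for g in members], label), label)
            print(f"high-CUB {label}: {len(members)} genes pooled")

    rscu_long_table(groups, opt).to_csv(args.outdir / "rscu.tsv", sep="\t", index=False, float_format="%.4f")
    if len(groups) >= 2:
        report = compare_optimal_usage(groups, opt)
        for (a, b), aas in sorted(report.exceeds.items()):
            print(f"{a} optimal-codon RSCU exceeds {b} in {len(aas)} amino acids")
        for name, aas in sorted(report.preferential.items()):
            print(f"{name} uses the optimal codon preferentially in {len(aas)} amino acids")


if __name__ == "__main__":
    main()
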