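#!/usr/bin/env python
"""Classify expression patterns and check recovery against ground truth.

Labels every gene as EIG (expression-invariable, the strict housekeeping
definition), EVG (expression-variable), TS (tissue-specific), or other
(intermediate breadth), then scores the labels against the generator's
truth table.
"""

import argparse
from pathlib import Path

import pandas as pd

from cubkit.expression import classify_genes, load_expression_matrix


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--simdir", type=Path, default=Path("results/sim"))
    parser.add_argument("--out", type=Path, default=Path("results/classes.tsv"))
    args = parser.parse_args()

    matrix = load_expression_matrix(args.simdir / "rpkm.tsv")
    classes = classify_genes(matrix)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    classes.reset_index().to_csv(args.out, sep="\t", index=False)

    print("class sizes:", classes["label"].value_counts().to_dict())
    truth_path = args.simdir / "truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t", index_col=0)
        for label in ("EIG", "EVG", "TS", "other"):
            members = truth.index[truth["true_class"] == label]
            rec = (classes.loc[members, "label"] == label).mean()
            print(f"recovery {label}: {100 * rec:.1f}% of {len(members)}")


if __name__ == "__main__":
    main()
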