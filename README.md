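# cubkit

Codon usage bias and translational selection across expression patterns.

Selection for translational efficiency and accuracy biases synonymous
codon choice toward codons read by abundant tRNAs. In multicellular
genomes this selection is weak and entangled with composition (isochore)
effects, and its strength appears to depend not only on how highly a gene
is expressed but on *how* it is expressed: genes transcribed ubiquitously
and consistently across tissues (housekeeping-like) versus variably
expressed or tissue-specific genes. `cubkit` implements the full analysis
for asking that question:

* **CDC** — the Codon Deviation Coefficient, a per-gene codon usage bias
  statistic measured against the gene's own positional GC/purine
  background (no reference gene set), with a parametric-bootstrap
  P-value: CDC = 1 − cos(x, p), where x is the observed sense-codon
  frequency vector and p the expected vector under the composition model.
* **Expression patterns** — classification of a genes × tissues RPKM
  matrix into EIG (expression-invariable, the strict housekeeping
  definition), EVG (expression-variable), TS (tissue-specific), and
  intermediate-breadth genes, via hierarchical clustering of
  mean-centred log-expression profiles.
* **RSCU and optimal codons** — relative synonymous codon usage
  (RSCU_j = x_j · n / Σx per family of size n) of pooled gene groups, and
  optimal-codon identification from tRNA gene copy numbers including the
  ADAT inosine-34 decoding credit.
* **Association statistics** — CUB–expression correlations per class,
  tissue, and expression breadth; CUB-rank expression trends; rank-sum
  contrasts; GC1/GC2/GC3 analyses.
* **Synthetic data** — a generator producing all three inputs (CDS FASTA,
  RPKM matrix, tRNA table) with exported ground truth, so every step is
  testable end to end.

See `docs/methods.md` for the models, defaults, and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```sh
python analysis/01_simulate.py --seed 1       # CDS + RPKM + tRNA + truth
python analysis/02_score_cub.py --seed 1      # CDC + bootstrap P + ranks
python analysis/03_classify_expression.py     # EIG/EVG/TS/other labels
python analysis/04_rscu_optimal.py            # optimal codons, RSCU contrast
python analysis/05_associations.py            # correlations, trends, GC3
```

With seed 1 this prints, among other things:

```
scored 1500 genes -> results/cub.tsv
median CDC 0.1168; significant at P<0.05: 963 (64.2%)
recovery EIG: 100.0% of 200
recovery EVG: 97.5% of 800
recovery TS: 100.0% of 300
optimal codons for 17 amino acids; 17 GC-ending
excluded: E (tied tRNA counts), M (single-codon), W (single-codon)
EIG optimal-codon RSCU exceeds EVG in 17 amino acids
median Pearson r (CDC vs log10 RPKM): {'EIG': 0.442, 'EVG': 0.051, 'TS': -0.055}
EIG gc3_vs_cdc: r=0.348 **
```

Reading the numbers: the generator couples codon bias to expression level
only in the invariable class, and the pipeline recovers exactly that
regime — the expression-pattern classifier reassembles the three classes
from the RPKM matrix alone (≥ 97% per class); the CUB–expression
correlation is clearly positive in EIGs (median Pearson r = 0.44 across
the 10 tissue panels) and near zero in EVGs and TS genes; high-CUB EIGs
out-use the optimal codons relative to EVGs in every one of the 17
analyzable amino acids (Met and Trp have one codon each; Glu's two tRNAs
are tied, so its family has no unique optimum); and because the optimal
codons are GC-ending, GC3 correlates positively with CDC in EIGs.

The same pipeline runs on real data from the command line, given a CDS
FASTA, an RPKM TSV, and a tRNA-table TSV:

```sh
cubkit run-all --config run.yaml
cubkit score --fasta cds.fa --boot 1000 --seed 17 --out cub.tsv
cubkit classify --matrix rpkm.tsv --out classes.tsv
cubkit optimal --trna trna.tsv
```

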