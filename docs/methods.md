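# Methods

## Problem and scope

`cubkit` studies translational selection: the hypothesis that selection on
synonymous codon choice — toward codons matching the abundant tRNAs — acts
more strongly on genes that are expressed ubiquitously and consistently
across tissues (housekeeping-like genes) than on variable or
tissue-specific genes. The package measures per-gene codon usage bias
(CUB), classifies genes by expression pattern from a multi-tissue RPKM
matrix, identifies optimal codons from a tRNA copy-number table, and ties
the three together with RSCU and correlation analyses. A synthetic-data
module generates all three inputs with known ground truth, so the whole
pipeline is exercisable and testable without external downloads.

## Codon usage bias: the Codon Deviation Coefficient

The CUB statistic is the Codon Deviation Coefficient (CDC): the deviation
of a gene's observed sense-codon usage from the usage expected under the
gene's own background nucleotide composition. It requires no reference
gene set, and because the null is built per gene from local composition,
regional GC (isochore) structure is absorbed into the expectation rather
than mistaken for bias.

**Background model.** For codon position k ∈ {1,2,3} let g_k be the GC
fraction and r_k the purine (A+G) fraction among the gene's codons
(stop codons excluded). Position bases are modelled independently with

    P_k(G) = g_k r_k        P_k(C) = g_k (1 − r_k)
    P_k(A) = (1 − g_k) r_k  P_k(T) = (1 − g_k)(1 − r_k)

A codon's probability is the product over its three positions; the three
stop codons are removed and the vector renormalised over the 61 sense
codons. This two-parameter-per-position factorisation reproduces the
gene's marginal GC and purine content exactly while assuming independence
between strong/weak and purine/pyrimidine identity; it is the module's
model, kept behind its own function so it can be swapped wholesale.

**Statistic.** CDC = 1 − cos(x, p), the cosine distance between the
observed sense-codon frequency vector x and the expected vector p. It is
0 when usage matches the background, approaches 1 − 1/√61 ≈ 0.872 for a
point mass against a uniform background, and is invariant to scaling of
the counts.

**Significance.** A parametric bootstrap: n_boot pseudo-genes of the same
codon count are drawn i.i.d. from p, and

    P = (1 + #{CDC_boot ≥ CDC_obs}) / (n_boot + 1)

The add-one correction keeps P strictly positive. Default n_boot = 1000;
a seed is mandatory. Under the null (genes drawn from their own
expectation) these P-values are uniform, which the test suite checks with
a Kolmogorov–Smirnov test, and CDC medians shrink toward 0 with gene
length. Downstream analyses use only genes with P < 0.05.

**Ranks.** Genes are binned into five CUB ranks at fixed CDC edges
0.10 / 0.13 / 0.16 / 0.19. The printed interval endpoints overlap, so the
package fixes a left-closed/right-open convention: a CDC of exactly 0.19
is `high`.

## Expression-pattern classification

From a genes × tissues RPKM matrix (the reference panel has 10 human
tissues), a gene's **breadth** is the number of tissues with RPKM above a
threshold (default 0: any expression counts — the strictest reading of
"expressed in all tissues"; configurable). Breadth 1 is **TS**
(tissue-specific, with the expressing tissue recorded); full breadth is
split into **EIG** (expression-invariable) versus **EVG**
(expression-variable); breadths 2..n−1 are retained as `other` because
breadth-stratified correlations need them.

The EIG/EVG split clusters ubiquitous genes on relative expression:
profiles of log10 RPKM centred on each gene's own mean (so only
across-tissue variation drives distance), hierarchical clustering with
Ward linkage and Euclidean distance, cut into k = 16 clusters; a cluster
is labelled EIG when its members' median across-tissue coefficient of
variation of RPKM is below 0.5, the midpoint on the CV scale between the
two noise regimes the generator emulates (EIG CV ≈ 0.2, EVG CV ≳ 1).

An alternative variant (`ClusteringPolicy(features="rank")`) quantile-bins
each tissue's values into 1001 relative-expression ranks and clusters
rank profiles, labelling by rank CV. This mirrors the classical
relative-expression-group construction but is not the default: quantile
ranks saturate at the top of the distribution, so a highly expressed gene
whose level swings tenfold can keep a near-constant top rank and be
mislabelled invariable. On the default synthetic scenario the centred-log
procedure recovers ≥ 95% of each class; the rank variant does not, for
exactly this reason.

## Optimal codons and RSCU

**RSCU.** For codon j of an amino acid with family size n,
RSCU_j = x_j · n / Σ x, computed from counts pooled across the gene group
(not averaged per gene), which makes the family-sum identity
Σ_j RSCU_j = n exact for every observed family. Unobserved families carry
NaN, never 0. Group RSCU is computed on high-CUB genes per expression
class, matching the contrast the correlation analyses motivate.

**Optimal codons.** Within each multi-codon family, each codon's decoding
weight is the genomic copy number of its Watson–Crick cognate tRNA plus
an ADAT credit: ADAT (adenosine deaminase acting on tRNA) edits A34 to
inosine in the tRNAs of eight amino acids (Ala, Arg, Ile, Leu, Pro, Ser,
Thr, Val), letting the A34 tRNA read C-ending codons, so its copies are
credited to the C-ending codon of those families. The optimal codon is
the argmax; Met and Trp are excluded (single-codon), and any family whose
maximum weight is tied is excluded — in the human pool Glu has two equal
cognate tRNAs, leaving 17 analyzable amino acids. The ADAT credit is a
pluggable hook because the biological rule is only partly determined by
copy-number data; the default is one consistent reading.

**Packaged tRNA table.** The shipped table
(`cubkit.simulate.generate_trna_fixture`) is synthetic: it has the shape
of a genomic tRNA-database codon summary (codon, anticodon, copies, adat)
and is constructed so the decoding-weight rule yields the 17-codon
optimal set with Glu tied and A34 tRNAs present only in ADAT families,
but its copy numbers are constructed values, not measurements.

**Comparisons.** For group pairs the report counts amino acids where one
group's optimal-codon RSCU strictly exceeds the other's, and per group
the amino acids where the optimal codon attains the strict within-family
maximum ("preferential use"); ties count as non-exceeding /
non-preferential, and amino acids with an unobserved family in any group
are dropped and listed.

## Association statistics

Correlations between CDC and log10 RPKM are computed per class and
tissue (Pearson by default, Spearman available), over genes passing the
CUB significance filter; genes with RPKM = 0 in a tissue are excluded
from that tissue's panel rather than pseudo-counted, avoiding arbitrary
offsets. Pearson P-values are the regression F-test (equivalent to the
two-sided t-test on r); strata with n < 3 or a constant variable are
marked undefined, not zero. The same correlation is computed per
(tissue, breadth) stratum, and per CUB rank the median log10 peak RPKM
with two-sided rank-sum tests between adjacent ranks.

Group contrasts use the two-sided Mann–Whitney rank-sum test: exact P by
exhaustive enumeration of all label assignments (midranks for ties) when
both groups have ≤ 8 observations, and the tie-corrected normal
approximation otherwise. Raw P-values carry the conventional star
annotation ('*' < 0.05, '**' < 1e−3, '***' < 1e−10); no multiple-testing
correction is applied, matching the reporting style the analysis mirrors.

## Synthetic-data generator

The generator defines the study conditions the tests run under.

* **Sequences.** Amino acids are drawn from a fixed average-protein-like
  composition; within each family the codon is optimal with probability
  β and uniform otherwise, so β ∈ [0,1] is the ground-truth bias
  strength. Gene lengths are uniform on 100–500 codons; a terminal TAA
  is appended. Because every designated optimal codon is GC-ending,
  raising β raises GC3 — which lets the GC3 analyses recover their
  expected signal by construction.
* **Expression.** 200 EIG (lognormal across tissues, σ = 0.2 on the
  natural-log scale, median level ≈ 160 RPKM), 800 EVG (σ = 1.2, median
  ≈ 32), 30 TS genes per tissue (positive in exactly one tissue, median
  ≈ 10), 200 intermediate-breadth genes — 1,500 genes over 10 tissues,
  with class mean levels ordered EIG ≥ EVG ≥ TS as in the regime being
  emulated.
* **Coupling.** β follows a pluggable rule of class and log-mean
  expression; the default is log-linear in expression for EIGs
  (β ≈ 0.1 + 0.25·(log10 level − 1), clipped to [0, 0.9]) and flat 0.15
  elsewhere. This builds in the qualitative headline the pipeline should
  detect — a positive CUB–expression correlation in EIGs and none in
  EVGs — so end-to-end tests are recovery tests, not discoveries.

All randomness flows from one seed; identical configs give byte-identical
outputs. What the generator does **not** emulate: isochore-scale GC
heterogeneity between genes beyond what β induces, amino-acid composition
differences between genes, length–expression correlations, sequencing
noise in RPKM, and correlated tissue panels. Passing recovery tests
therefore shows the machinery is correct and calibrated under the stated
conditions, not that real human data would give the same numbers.

## Problem sizes and numerics

Default analyses run at 1,500 genes × 10 tissues with 1,000 bootstrap
replicates; the test suite uses a reduced 320-gene scenario and 200–500
replicates where a full run adds nothing. Zero-norm observed vectors and
empty families raise errors rather than returning silent zeros; the CDC
bootstrap comparison uses a 1e−15 slack so replicates exactly equal to
the observed statistic count as extreme; rank-edge and top-n ties are
broken deterministically (left-closed intervals, lexicographic gene id).

## Known limitations

* The CDC background model and bootstrap scheme are this package's
  formulation of a composition-conditioned bias statistic; other CDC
  formulations differ in normalisation details.
* The EIG/EVG split depends on clustering granularity and the CV cut;
  both are exposed, and the defaults were chosen for the generator's
  noise regimes.
* The packaged tRNA table is a synthetic stand-in; analyses of real data
  should substitute a genuine genomic tRNA summary in the same TSV
  schema.
* Real-data headline values (correlation coefficients, class counts)
  depend on the original expression panel and transcript set and are not
  reproducible from this repository; the acceptance script reports the
  synthetic-scenario equivalents it computes itself.
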