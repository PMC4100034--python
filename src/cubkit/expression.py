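"""Expression-pattern classification from a genes x tissues RPKM matrix.

Genes are classed by expression breadth (number of tissues with RPKM above
a threshold, default 0) and, among ubiquitously expressed genes, by the
consistency of their expression across tissues:

* **TS** (tissue-specific): expressed in exactly one tissue.
* **EIG** (expression-invariable gene, the strict housekeeping definition):
  expressed in all tissues at consistent relative levels.
* **EVG** (expression-variable gene): expressed in all tissues at variable
  levels.
* **other**: intermediate breadth (2 .. n_tissues - 1).

The EIG/EVG split works on relative expression: each ubiquitous gene's
profile is centred on its own mean so that only across-tissue variation,
not absolute level, drives the grouping. Profiles are clustered
hierarchically (Ward linkage, Euclidean distance) and clusters whose
median across-tissue coefficient of variation of RPKM falls below
``cv_cut`` are labelled EIG, the rest EVG. By default profiles are
mean-centred log10 RPKM; setting ``features="rank"`` instead clusters
per-tissue quantile-rank profiles (``n_bins`` bins, default 1001) and
labels by rank CV. The rank variant mirrors the classical
relative-expression-group construction but saturates at the top of the
distribution: a highly expressed gene keeps a top rank even when its
level swings tenfold, so rank dispersion under-reports variability for
the most abundant genes. All knobs live in :class:`ClusteringPolicy` and
are package choices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

HUMAN_TISSUES_10 = (
    "testis", "brain", "adipose", "colon", "heart",
    "breast", "kidney", "liver", "lymph_node", "skeletal_muscle",
)


@dataclass(frozen=True)
class ClusteringPolicy:
    """Parameters of the EIG/EVG split. Defaults are documented choices."""

    n_bins: int = 1001
    n_clusters: int = 16
    cv_cut: float = 0.5
    linkage_method: str = "ward"
    features: str = "log"  # "log" (centred log10 RPKM) or "rank" (quantile ranks)


def load_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a TSV expression matrix (first column gene_id, rest tissue RPKM)."""
    m = pd.read_csv(path, sep="\t", index_col=0)
    validate_expression_matrix(m)
    return m


def validate_expression_matrix(m: pd.DataFrame) -> None:
    if m.shape[1] < 2:
        raise ValueError("expression matrix needs at least 2 tissues")
    if m.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    if (m.values < 0).any():
        raise ValueError("negative RPKM values")


def expression_breadth(m: pd.DataFrame, expressed_threshold: float = 0.0) -> pd.Series:
    """Number of tissues in which each gene's RPKM exceeds the threshold."""
    if expressed_threshold < 0:
        raise ValueError("expressed_threshold must be >= 0")
    return (m > expressed_threshold).sum(axis=1)


def classify_ts(m: pd.DataFrame, expressed_threshold: float = 0.0) -> pd.DataFrame:
    """Tissue-specific genes: breadth exactly 1, with the expressing tissue."""
    expressed = m > expressed_threshold
    breadth = expressed.sum(axis=1)
    ts = m.index[breadth == 1]
    tissue = expressed.loc[ts].idxmax(axis=1)
    return pd.DataFrame({"gene_id": ts, "ts_tissue": tissue.values}).set_index("gene_id")


def rank_profiles(sub: pd.DataFrame, n_bins: int = 1001) -> pd.DataFrame:
    """Per-tissue quantile binning of RPKM into 1..n_bins relative-expression ranks."""
    def bin_column(col: pd.Series) -> np.ndarray:
        ranks = col.rank(method="average")  # 1..n
        n = len(col)
        if n == 1:
            return np.ones(1)
        return np.floor((ranks - 1) / (n - 1) * (n_bins - 1)) + 1

    return sub.apply(bin_column, axis=0)


def classify_eig_evg(
    m: pd.DataFrame,
    expressed_threshold: float = 0.0,
    policy: ClusteringPolicy | None = None,
) -> pd.Series:
    """Split ubiquitously expressed genes into EIG and EVG labels.

    Returns a Series (gene_id -> "EIG"/"EVG") over genes expressed in every
    tissue. Deterministic given the policy; invariant to row/column order
    (genes are sorted before clustering).
    """
    policy = policy or ClusteringPolicy()
    breadth = expression_breadth(m, expressed_threshold)
    ubiquitous = sorted(m.index[breadth == m.shape[1]])
    if len(ubiquitous) < 2:
        raise ValueError("need >= 2 ubiquitously expressed genes for EIG/EVG clustering")
    if len(ubiquitous) < policy.n_clusters:
        raise ValueError(
            f"{len(ubiquitous)} ubiquitous genes < {policy.n_clusters} clusters requested"
        )
    sub = m.loc[ubiquitous, sorted(m.columns)]
    if policy.features == "rank":
        ranks = rank_profiles(sub, policy.n_bins)
        profiles = ranks.sub(ranks.mean(axis=1), axis=0)
        cv = ranks.std(axis=1, ddof=0) / ranks.mean(axis=1)
    elif policy.features == "log":
        logm = np.log10(sub)
        profiles = logm.sub(logm.mean(axis=1), axis=0)
        cv = sub.std(axis=1, ddof=0) / sub.mean(axis=1)
    else:
        raise ValueError(f"unknown features {policy.features!r}")
    Z = linkage(profiles.values, method=policy.linkage_method, metric="euclidean")
    clusters = fcluster(Z, t=policy.n_clusters, criterion="maxclust")
    labels = pd.Series("EVG", index=sub.index, name="label")
    for k in np.unique(clusters):
        members = sub.index[clusters == k]
        if cv.loc[members].median() < policy.cv_cut:
            labels.loc[members] = "EIG"
    return labels


def classify_genes(
    m: pd.DataFrame,
    expressed_threshold: float = 0.0,
    policy: ClusteringPolicy | None = None,
) -> pd.DataFrame:
    """Full classification: gene_id, breadth, label (EIG/EVG/TS/other), ts_tissue.

    Every gene receives exactly one label; EIG and EVG partition the
    full-breadth set, TS is breadth 1, other covers the remaining breadths
    (including 0, unexpressed).
    """
    validate_expression_matrix(m)
    breadth = expression_breadth(m, expressed_threshold)
    out = pd.DataFrame({"breadth": breadth, "label": "other", "ts_tissue": ""}, index=m.index)
    ts = classify_ts(m, expressed_threshold)
    out.loc[ts.index, "label"] = "TS"
    out.loc[ts.index, "ts_tissue"] = ts["ts_tissue"]
    eig_evg = classify_eig_evg(m, expressed_threshold, policy)
    out.loc[eig_evg.index, "label"] = eig_evg
    out.index.name = "gene_id"
    return out.sort_index()


def top_n_by_max_rpkm(m: pd.DataFrame, genes: pd.Index | list[str], n: int) -> list[str]:
    """The n genes of a class with the largest per-gene maximum RPKM.

    Ties at the boundary are broken by lexicographic gene id.
    """
    genes = list(genes)
    if n > len(genes):
        raise ValueError(f"n={n} exceeds class size {len(genes)}")
    peak = m.loc[genes].max(axis=1)
    order = sorted(genes, key=lambda g: (-peak[g], g))
    return order[:n]
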