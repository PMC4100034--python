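"""Association statistics: CUB-expression correlations, rank trends,
rank-sum contrasts, and GC-composition analyses.

Correlations between codon usage bias (the CDC) and expression level use
log10 RPKM; genes with zero RPKM in a tissue are excluded from that
tissue's correlation rather than pseudo-counted. Pearson P-values come
from the regression F-test (equivalent to the two-sided t-test on r).
Group contrasts use the two-sided Mann-Whitney rank-sum test, with exact
enumeration of all label assignments for small samples (both groups
<= 8) and the tie-corrected normal approximation otherwise. Raw P-values
are reported with the conventional star annotation ('*' < 0.05,
'**' < 1e-3, '***' < 1e-10); no multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_RANKSUM_MAX_N = 8


@dataclass(frozen=True)
class CorrelationResult:
    """One correlation: subset descriptor, method, r, p, and sample size."""

    subset: str
    method: str
    r: float
    p: float
    n: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r)

    @property
    def stars(self) -> str:
        return p_stars(self.p) if self.defined else ""


def p_stars(p: float) -> str:
    if p < 1e-10:
        return "***"
    if p < 1e-3:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _undefined(subset: str, method: str, n: int) -> CorrelationResult:
    return CorrelationResult(subset, method, math.nan, math.nan, n)


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "pearson", subset: str = ""
) -> CorrelationResult:
    """Pearson or Spearman correlation; undefined marker when n < 3 or a
    variable is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    n = int(x.size)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return _undefined(subset, method, n)
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(subset, method, float(r), float(p), n)


def correlate_cub_expression(
    cub: pd.DataFrame,
    m: pd.DataFrame,
    genes: Iterable[str],
    tissue: str,
    method: str = "pearson",
    subset: str = "",
) -> CorrelationResult:
    """Correlate CDC with log10 RPKM in one tissue over a gene subset.

    *cub* must already be filtered to significant genes (bootstrap
    P < 0.05); genes absent from either table or with zero RPKM in the
    tissue are dropped.
    """
    scores = cub.set_index("gene_id")["cdc"] if "gene_id" in cub.columns else cub["cdc"]
    genes = [g for g in genes if g in scores.index and g in m.index]
    rpkm = m.loc[genes, tissue]
    expressed = rpkm > 0
    genes = list(np.array(genes)[expressed.values])
    if not genes:
        return _undefined(subset or f"{tissue}", method, 0)
    x = scores.loc[genes].values
    y = np.log10(m.loc[genes, tissue].values)
    return correlate(x, y, method=method, subset=subset or tissue)


def class_tissue_correlations(
    cub: pd.DataFrame,
    m: pd.DataFrame,
    classes: pd.DataFrame,
    labels: Sequence[str] = ("EIG", "EVG", "TS"),
    method: str = "pearson",
) -> pd.DataFrame:
    """Per-class, per-tissue CUB vs log10 RPKM correlations.

    For the TS class only genes specific to the given tissue enter that
    tissue's panel; EIG/EVG use their full membership.
    """
    rows = []
    for label in labels:
        members = classes.index[classes["label"] == label]
        for tissue in m.columns:
            if label == "TS":
                subset_genes = classes.index[
                    (classes["label"] == "TS") & (classes["ts_tissue"] == tissue)
                ]
            else:
                subset_genes = members
            res = correlate_cub_expression(
                cub, m, subset_genes, tissue, method=method, subset=f"{label}/{tissue}"
            )
            rows.append(
                {
                    "class": label,
                    "tissue": tissue,
                    "method": method,
                    "n": res.n,
                    "r": res.r,
                    "p": res.p,
                    "stars": res.stars,
                }
            )
    return pd.DataFrame(rows)


def breadth_stratified_correlations(
    cub: pd.DataFrame,
    m: pd.DataFrame,
    breadth: pd.Series,
    method: str = "pearson",
) -> pd.DataFrame:
    """One correlation per (tissue, breadth) over genes of that breadth
    expressed in that tissue. Empty or tiny strata are marked undefined."""
    rows = []
    for b in range(1, m.shape[1] + 1):
        stratum = breadth.index[breadth == b]
        for tissue in m.columns:
            res = correlate_cub_expression(
                cub, m, stratum, tissue, method=method, subset=f"breadth={b}/{tissue}"
            )
            rows.append(
                {
                    "tissue": tissue,
                    "breadth": b,
                    "method": method,
                    "n": res.n,
                    "r": res.r,
                    "p": res.p,
                    "stars": res.stars,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rank-sum machinery


def exact_ranksum_pvalue(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided rank-sum P by exhaustive enumeration of label assignments.

    Enumerates every way of assigning len(a) of the pooled values to group
    A and counts assignments whose rank sum deviates from its mean at
    least as much as observed. Handles ties through midranks. Intended for
    small samples (the caller restricts to n <= 8 per group).
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = np.asarray(a + b)
    ranks = sps.rankdata(pooled)
    n_a = len(a)
    observed = ranks[:n_a].sum()
    mean = ranks.sum() * n_a / len(pooled)
    dev = abs(observed - mean)
    count = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        total += 1
        if abs(ranks[list(idx)].sum() - mean) >= dev - 1e-12:
            count += 1
    return count / total


def group_contrast(a: Sequence[float], b: Sequence[float]) -> dict:
    """Two-sided Mann-Whitney contrast with direction of the larger median.

    Exact enumeration when both groups have <= 8 values; otherwise the
    tie-corrected normal approximation. All-tied input gives P = 1 and no
    direction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if np.ptp(np.concatenate([a, b])) == 0:
        return {"p": 1.0, "direction": "none", "median_a": med_a, "median_b": med_b}
    if a.size <= EXACT_RANKSUM_MAX_N and b.size <= EXACT_RANKSUM_MAX_N:
        p = exact_ranksum_pvalue(a, b)
    else:
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
    if med_a > med_b:
        direction = "A"
    elif med_b > med_a:
        direction = "B"
    else:
        direction = "none"
    return {"p": p, "direction": direction, "median_a": med_a, "median_b": med_b}


def rank_trend(
    cub: pd.DataFrame, expression: pd.Series, rank_order: Sequence[str] | None = None
) -> pd.DataFrame:
    """Median log10 expression per CUB rank and adjacent-rank contrasts.

    *expression* maps gene_id -> RPKM (a single tissue or per-gene peak);
    zero-RPKM genes are dropped. Returns one row per rank with the median
    and the rank-sum P against the previous rank; empty ranks are skipped.
    """
    from .cdc import CUB_RANK_LABELS

    rank_order = list(rank_order or CUB_RANK_LABELS)
    scores = cub.set_index("gene_id") if "gene_id" in cub.columns else cub
    rows = []
    prev_vals: np.ndarray | None = None
    prev_label: str | None = None
    for label in rank_order:
        genes = [
            g
            for g in scores.index[scores["cub_rank"] == label]
            if g in expression.index and expression[g] > 0
        ]
        if not genes:
            continue
        vals = np.log10(expression.loc[genes].values.astype(float))
        row = {"cub_rank": label, "n": len(vals), "median_log10_rpkm": float(np.median(vals))}
        if prev_vals is not None:
            contrast = group_contrast(prev_vals, vals)
            row["p_vs_previous"] = contrast["p"]
            row["previous_rank"] = prev_label
        else:
            row["p_vs_previous"] = math.nan
            row["previous_rank"] = ""
        rows.append(row)
        prev_vals, prev_label = vals, label
    return pd.DataFrame(rows)


def gc3_analyses(
    cub: pd.DataFrame,
    m: pd.DataFrame,
    classes: pd.DataFrame,
    labels: Sequence[str] = ("EIG", "EVG"),
) -> dict:
    """GC3 relationships: per-class (GC3, CDC) and (GC3, log10 peak RPKM)
    Pearson correlations, and high- vs low-CUB contrasts of GC1/GC2/GC3."""
    scores = cub.set_index("gene_id") if "gene_id" in cub.columns else cub
    peak = m.max(axis=1)
    out: dict = {"correlations": [], "contrasts": []}
    for label in labels:
        genes = [
            g for g in classes.index[classes["label"] == label]
            if g in scores.index and g in peak.index and peak[g] > 0
        ]
        sub = scores.loc[genes]
        out["correlations"].append(
            {
                "class": label,
                "pair": "gc3_vs_cdc",
                **_corr_fields(correlate(sub["gc3"], sub["cdc"], subset=label)),
            }
        )
        out["correlations"].append(
            {
                "class": label,
                "pair": "gc3_vs_expression",
                **_corr_fields(
                    correlate(sub["gc3"], np.log10(peak.loc[genes].values), subset=label)
                ),
            }
        )
        high = sub[sub["cub_rank"] == "high"]
        low = sub[sub["cub_rank"] == "low"]
        if len(high) and len(low):
            for col in ("gc1", "gc2", "gc3"):
                contrast = group_contrast(high[col].values, low[col].values)
                out["contrasts"].append(
                    {"class": label, "position": col, **contrast}
                )
    return out


def _corr_fields(res: CorrelationResult) -> dict:
    return {"n": res.n, "r": res.r, "p": res.p, "stars": res.stars}
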