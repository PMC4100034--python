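"""Correlation and rank-sum machinery against independent small-sample oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cubkit.stats import (
    breadth_stratified_correlations,
    correlate,
    correlate_cub_expression,
    exact_ranksum_pvalue,
    gc3_analyses,
    group_contrast,
    p_stars,
    rank_trend,
)


class TestCorrelate:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        res = correlate(x, 2 * x)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-10

    def test_antimonotone_spearman(self):
        x = np.array([1.0, 2, 3, 5, 9])
        res = correlate(x, -(x**3), method="spearman")
        assert res.r == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = correlate(x, y)
        oracle = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert res.r == pytest.approx(oracle, abs=1e-12)

    def test_pearson_affine_invariance(self, rng):
        x, y = rng.normal(size=15), rng.normal(size=15)
        assert correlate(x, y).r == pytest.approx(correlate(3 * x + 7, 0.5 * y - 2).r, abs=1e-12)

    def test_spearman_monotone_transform_invariance(self, rng):
        x = rng.uniform(1, 10, 15)
        y = rng.uniform(1, 10, 15)
        a = correlate(x, y, method="spearman").r
        b = correlate(np.log(x), y**3, method="spearman").r
        assert a == pytest.approx(b, abs=1e-12)

    @pytest.mark.parametrize("x,y", [([1, 2], [3, 4]), ([1, 1, 1], [1, 2, 3])])
    def test_undefined_cases(self, x, y):
        res = correlate(x, y)
        assert not res.defined

    def test_pearson_p_equals_regression_f_test(self, rng):
        """The two-sided P on r equals the F-test of the one-predictor
        linear fit."""
        x, y = rng.normal(size=25), rng.normal(size=25)
        res = correlate(x, y)
        slope = sps.linregress(x, y)
        assert res.p == pytest.approx(slope.pvalue, rel=1e-9)


class TestZeroRpkmPolicy:
    def test_zero_expression_genes_excluded(self):
        cub = pd.DataFrame(
            {"gene_id": ["a", "b", "c", "d"], "cdc": [0.1, 0.2, 0.3, 0.4]}
        )
        m = pd.DataFrame({"t": [1.0, 0.0, 10.0, 100.0]}, index=["a", "b", "c", "d"])
        res = correlate_cub_expression(cub, m, ["a", "b", "c", "d"], "t")
        assert res.n == 3  # gene b dropped, not pseudo-counted


class TestExactRanksum:
    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (2, 6), (8, 8)])
    def test_matches_scipy_exact_without_ties(self, n1, n2, rng):
        a = rng.normal(size=n1)
        b = rng.normal(size=n2)
        ours = exact_ranksum_pvalue(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_three_vs_three_enumeration(self):
        """All C(6,3)=20 label assignments of {1..6}: rank sum of {4,5,6}
        deviates maximally, so only the two extreme assignments qualify."""
        assert exact_ranksum_pvalue([4, 5, 6], [1, 2, 3]) == pytest.approx(2 / 20)

    def test_handles_ties_via_midranks(self):
        p = exact_ranksum_pvalue([1, 1, 2], [2, 3, 3])
        assert 0 < p <= 1


class TestGroupContrast:
    def test_identical_groups_no_direction(self):
        res = group_contrast([1.0, 1.0, 1.0], [1.0, 1.0])
        assert res["p"] == 1.0
        assert res["direction"] == "none"

    def test_strong_shift_detected_at_n200(self, rng):
        a = rng.normal(1.5, 1, 200)
        b = rng.normal(0, 1, 200)
        res = group_contrast(a, b)
        assert res["p"] < 1e-3
        assert res["direction"] == "A"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_contrast([], [1.0])

    def test_small_samples_use_exact_path(self):
        a, b = [1.0, 2.0, 7.0], [3.0, 4.0, 5.0]
        assert group_contrast(a, b)["p"] == pytest.approx(exact_ranksum_pvalue(a, b))


class TestRankTrend:
    def make_cub(self, ranks, genes):
        return pd.DataFrame({"gene_id": genes, "cub_rank": ranks, "cdc": 0.1})

    def test_monotone_coupling_gives_increasing_medians(self, rng):
        genes, ranks, rpkm = [], [], {}
        for i, (label, level) in enumerate(
            [("low", 1), ("medium-low", 10), ("medium", 100), ("medium-high", 1000), ("high", 10000)]
        ):
            for j in range(30):
                g = f"g{i}_{j}"
                genes.append(g)
                ranks.append(label)
                rpkm[g] = level * np.exp(rng.normal(0, 0.1))
        trend = rank_trend(self.make_cub(ranks, genes), pd.Series(rpkm))
        med = trend["median_log10_rpkm"].tolist()
        assert med == sorted(med)
        assert (trend["p_vs_previous"].dropna() < 1e-3).all()

    def test_empty_ranks_skipped(self):
        cub = self.make_cub(["low", "high"], ["a", "b"])
        trend = rank_trend(cub, pd.Series({"a": 5.0, "b": 9.0}))
        assert trend["cub_rank"].tolist() == ["low", "high"]
        assert trend.loc[1, "previous_rank"] == "low"


class TestBreadthStratified:
    def test_permuted_cub_centres_near_zero(self, rng):
        n = 400
        genes = [f"g{i:03d}" for i in range(n)]
        m = pd.DataFrame(
            10 ** rng.uniform(0, 3, (n, 4)), index=genes, columns=list("wxyz")
        )
        breadth = pd.Series(4, index=m.index)
        cub = pd.DataFrame({"gene_id": genes, "cdc": rng.permutation(np.linspace(0.05, 0.3, n))})
        table = breadth_stratified_correlations(cub, m, breadth)
        defined = table.dropna(subset=["r"])
        assert abs(defined["r"].mean()) < 0.1
        assert (defined["breadth"] == 4).all()

    def test_tiny_stratum_undefined(self):
        m = pd.DataFrame({"t1": [1.0, 2.0], "t2": [0.0, 1.0]}, index=["a", "b"])
        cub = pd.DataFrame({"gene_id": ["a", "b"], "cdc": [0.1, 0.2]})
        table = breadth_stratified_correlations(cub, m, pd.Series({"a": 1, "b": 2}))
        assert table["r"].isna().all()


class TestGc3Analyses:
    def test_small_fixed_table_matches_covariance_oracle(self):
        genes = [f"g{i}" for i in range(6)]
        cub = pd.DataFrame(
            {
                "gene_id": genes,
                "cdc": [0.05, 0.1, 0.15, 0.2, 0.25, 0.3],
                "gc3": [0.3, 0.4, 0.45, 0.55, 0.6, 0.7],
                "gc1": 0.5,
                "gc2": 0.5,
                "cub_rank": ["low", "low", "medium", "medium", "high", "high"],
            }
        )
        m = pd.DataFrame({"t": [1, 10, 20, 50, 100, 200.0]}, index=genes)
        classes = pd.DataFrame({"label": ["EIG"] * 6, "ts_tissue": ""}, index=genes)
        out = gc3_analyses(cub, m, classes, labels=("EIG",))
        row = next(r for r in out["correlations"] if r["pair"] == "gc3_vs_cdc")
        oracle = np.corrcoef(cub["gc3"], cub["cdc"])[0, 1]
        assert row["r"] == pytest.approx(oracle, abs=1e-12)
        contrast = [c for c in out["contrasts"] if c["position"] == "gc3"]
        assert contrast and contrast[0]["direction"] == "A"  # high CUB has higher GC3

    def test_constant_gc3_undefined(self):
        genes = ["a", "b", "c", "d"]
        cub = pd.DataFrame(
            {"gene_id": genes, "cdc": [0.1, 0.2, 0.3, 0.4], "gc3": 0.5, "gc1": 0.4,
             "gc2": 0.3, "cub_rank": "low"}
        )
        m = pd.DataFrame({"t": [1.0, 2, 3, 4]}, index=genes)
        classes = pd.DataFrame({"label": ["EVG"] * 4, "ts_tissue": ""}, index=genes)
        out = gc3_analyses(cub, m, classes, labels=("EVG",))
        assert all(math.isnan(r["r"]) for r in out["correlations"])


@pytest.mark.parametrize(
    "p,stars", [(0.2, ""), (0.04, "*"), (1e-4, "**"), (1e-11, "***")]
)
def test_p_stars(p, stars):
    assert p_stars(p) == stars
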