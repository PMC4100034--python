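"""RSCU, optimal-codon identification, and group comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cubkit.genetic_code import AA_TO_CODONS, SENSE_CODONS
from cubkit.rscu import (
    MULTI_CODON_AA,
    compare_optimal_usage,
    compute_rscu,
    count_gc_ending,
    default_adat_rule,
    identify_optimal_codons,
    pool_counts,
    validate_trna_table,
)
from cubkit.seqio import CodonCounts


class TestComputeRscu:
    def test_alanine_family_direct_formula(self):
        """Ala counts {GCA:2, GCC:6} with family size 4 and total 8:
        RSCU = count * 4 / 8."""
        table = compute_rscu(CodonCounts("g", {"GCA": 2, "GCC": 6}))
        assert table["GCC"] == pytest.approx(3.0)
        assert table["GCA"] == pytest.approx(1.0)
        assert table["GCG"] == 0.0
        assert table["GCT"] == 0.0

    def test_uniform_family_usage_is_one(self):
        counts = {c: 5 for c in AA_TO_CODONS["L"]}
        table = compute_rscu(CodonCounts("g", counts))
        for c in AA_TO_CODONS["L"]:
            assert table[c] == pytest.approx(1.0)

    def test_unobserved_family_is_nan_not_zero(self):
        table = compute_rscu(CodonCounts("g", {"GCA": 1}))
        assert math.isnan(table["TTT"])
        assert table["GCA"] == pytest.approx(4.0)

    @settings(deadline=None, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_family_sum_identity(self, seed):
        """Within any observed family the RSCU values sum to the family size."""
        rng = np.random.default_rng(seed)
        counts = {c: int(k) for c, k in zip(SENSE_CODONS, rng.integers(0, 40, 61))}
        table = compute_rscu(CodonCounts("g", {c: k for c, k in counts.items() if k}))
        for aa in MULTI_CODON_AA:
            family = AA_TO_CODONS[aa]
            if sum(counts[c] for c in family) > 0:
                assert sum(table[c] for c in family) == pytest.approx(len(family))

    def test_invariant_to_group_split(self, rng):
        """Pooling two halves then RSCU equals RSCU of the single pool."""
        a = {c: int(k) for c, k in zip(SENSE_CODONS, rng.integers(0, 9, 61))}
        b = {c: int(k) for c, k in zip(SENSE_CODONS, rng.integers(0, 9, 61))}
        merged = pool_counts([CodonCounts("a", a), CodonCounts("b", b)], "grp")
        direct = CodonCounts("grp", {c: a[c] + b[c] for c in SENSE_CODONS})
        t1, t2 = compute_rscu(merged), compute_rscu(direct)
        for c in t1.values:
            assert t1[c] == pytest.approx(t2[c]) or (math.isnan(t1[c]) and math.isnan(t2[c]))


class TestIdentifyOptimalCodons:
    def test_most_abundant_trna_wins(self, trna_fixture):
        """Phe: the TTC-cognate tRNA dominates and TTT has no cognate, so
        TTC is optimal."""
        row = trna_fixture.set_index("codon")
        assert row.loc["TTC", "copies"] > row.loc["TTT", "copies"]
        opt = identify_optimal_codons(trna_fixture)
        assert opt.optimal["F"] == "TTC"

    def test_tied_glutamate_family_excluded(self, trna_fixture):
        opt = identify_optimal_codons(trna_fixture)
        assert opt.excluded["E"] == "tied tRNA counts"
        assert "E" not in opt.optimal

    def test_single_codon_amino_acids_excluded(self, trna_fixture):
        opt = identify_optimal_codons(trna_fixture)
        assert opt.excluded["M"] == "single-codon"
        assert opt.excluded["W"] == "single-codon"

    def test_row_order_invariance(self, trna_fixture, rng):
        shuffled = trna_fixture.sample(frac=1.0, random_state=7).reset_index(drop=True)
        assert identify_optimal_codons(shuffled).optimal == identify_optimal_codons(trna_fixture).optimal

    def test_adat_credit_changes_winner(self, trna_fixture):
        """Disabling the ADAT credit moves Ile's optimum from ATC (read by
        the inosine tRNA) to ATT (most abundant Watson-Crick cognate)."""
        with_adat = identify_optimal_codons(trna_fixture)
        without = identify_optimal_codons(trna_fixture, adat_rule=None)
        assert with_adat.optimal["I"] == "ATC"
        assert without.optimal["I"] == "ATT"

    def test_missing_codon_rejected(self, trna_fixture):
        with pytest.raises(ValueError):
            identify_optimal_codons(trna_fixture.iloc[:-5])

    def test_fixture_validates(self, trna_fixture):
        validate_trna_table(trna_fixture)

    def test_adat_rule_credits_c_ending_only(self, trna_fixture):
        copies = dict(zip(trna_fixture["codon"], trna_fixture["copies"]))
        assert default_adat_rule("GCC", copies) == copies["GCT"]
        assert default_adat_rule("GCA", copies) == 0  # not C-ending
        assert default_adat_rule("AAC", copies) == 0  # Asn is not an ADAT family


class TestCompareOptimalUsage:
    def test_identical_tables_exceed_nowhere(self, trna_fixture, rng):
        counts = {c: int(k) for c, k in zip(SENSE_CODONS, rng.integers(1, 30, 61))}
        t = compute_rscu(CodonCounts("x", counts), "A")
        t2 = compute_rscu(CodonCounts("x", counts), "B")
        opt = identify_optimal_codons(trna_fixture)
        report = compare_optimal_usage({"A": t, "B": t2}, opt)
        assert report.exceeds[("A", "B")] == ()
        assert report.exceeds[("B", "A")] == ()

    def test_biased_group_exceeds_in_known_amino_acids(self, trna_fixture):
        """A group with all mass on optimal codons exceeds a uniform group in
        every analyzable amino acid, and uses each optimal codon
        preferentially."""
        opt = identify_optimal_codons(trna_fixture)
        biased = {c: 0 for c in SENSE_CODONS}
        for aa, codon in opt.optimal.items():
            biased[codon] = 10
        uniform = {c: 5 for c in SENSE_CODONS}
        groups = {
            "biased": compute_rscu(CodonCounts("x", {c: k for c, k in biased.items() if k}), "biased"),
            "flat": compute_rscu(CodonCounts("x", uniform), "flat"),
        }
        report = compare_optimal_usage(groups, opt)
        analyzable = set(opt.amino_acids) - set(report.dropped)
        assert set(report.exceeds[("biased", "flat")]) == analyzable
        assert set(report.preferential["biased"]) == analyzable
        assert report.preferential["flat"] == ()  # all-ties are non-preferential

    def test_undefined_families_are_dropped_and_listed(self, trna_fixture):
        opt = identify_optimal_codons(trna_fixture)
        partial = {c: 5 for c in SENSE_CODONS if c[0] != "T"}  # Phe/Tyr/Cys families absent
        groups = {
            "A": compute_rscu(CodonCounts("x", partial), "A"),
            "B": compute_rscu(CodonCounts("x", {c: 3 for c in SENSE_CODONS}), "B"),
        }
        report = compare_optimal_usage(groups, opt)
        assert "F" in report.dropped and "Y" in report.dropped and "C" in report.dropped
        for aas in report.exceeds.values():
            assert not set(aas) & set(report.dropped)

    def test_single_group_rejected(self, trna_fixture):
        opt = identify_optimal_codons(trna_fixture)
        t = compute_rscu(CodonCounts("x", {c: 1 for c in SENSE_CODONS}), "A")
        with pytest.raises(ValueError):
            compare_optimal_usage({"A": t}, opt)


@pytest.mark.parametrize(
    "codons,expected",
    [(("AAA", "AAT"), 0), (("GGC",), 1), (("AAC", "GAC", "GTG"), 3)],
)
def test_count_gc_ending(codons, expected):
    assert count_gc_ending(codons) == expected
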