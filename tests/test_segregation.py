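"""Pearson chi-square segregation testing and group comparisons."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from spikesplit import (
    ChiSquareResult,
    RatioLibrary,
    SegregationCounts,
    group_comparison,
    pearson_chi2,
    projection_consistency,
    ratio_battery,
)


def chi2_exact(observed, ratio):
    """Independent oracle: chi-square with exact rational expectations."""
    n = sum(observed)
    total = sum(ratio)
    expectations = [Fraction(n) * r / total for r in ratio]
    return float(sum(Fraction((o * total - n * r) ** 2, 1) / (Fraction(n) * r * total) for o, r in zip(observed, ratio)))


# classical worked splits for this cross (observed, ratio name, chi2 to 3 d.p.)
WORKED_SPLITS = [
    ((125, 54), "3:1", 2.549),  # tetraaristatum
    ((144, 28), "13:3", 0.689),  # spike color
    ((133, 46), "3:1", 0.047),  # awnedness type
    ((175, 10), "15:1", 0.225),  # glume teeth
]


class TestPearsonChi2:
    @pytest.mark.parametrize("observed,name,expected_chi2", WORKED_SPLITS)
    def test_worked_splits_to_three_decimals(self, library, observed, name, expected_chi2):
        res = pearson_chi2(SegregationCounts("trait", observed), library.get(name))
        assert round(res.chi2, 3) == expected_chi2
        assert not res.rejected

    @pytest.mark.parametrize("observed,name,_", WORKED_SPLITS)
    def test_matches_exact_rational_oracle(self, library, observed, name, _):
        model = library.get(name)
        res = pearson_chi2(SegregationCounts("trait", observed), model)
        assert res.chi2 == pytest.approx(chi2_exact(observed, model.ratio), rel=1e-12)

    @pytest.mark.parametrize("observed,name,_", WORKED_SPLITS)
    def test_matches_scipy_chisquare(self, library, observed, name, _):
        model = library.get(name)
        res = pearson_chi2(SegregationCounts("trait", observed), model)
        n = sum(observed)
        p = model.ratio[0] / sum(model.ratio)
        ref = stats.chisquare(observed, f_exp=[n * p, n * (1 - p)])
        assert res.chi2 == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_zero_when_observed_equals_expected(self, library):
        res = pearson_chi2(SegregationCounts("t", (75, 25)), library.get("3:1"))
        assert res.chi2 == 0.0
        assert res.p_value == 1.0

    def test_scales_linearly_with_n_at_fixed_proportions(self, library):
        model = library.get("3:1")
        base = pearson_chi2(SegregationCounts("t", (70, 30)), model).chi2
        for k in (2, 5, 10):
            scaled = pearson_chi2(SegregationCounts("t", (70 * k, 30 * k)), model).chi2
            assert scaled == pytest.approx(k * base, rel=1e-9)

    def test_zero_total_raises(self, library):
        with pytest.raises(ValueError, match="positive"):
            pearson_chi2(SegregationCounts("t", (0, 0)), library.get("3:1"))

    def test_continuity_correction_reduces_statistic(self, library):
        counts = SegregationCounts("t", (125, 54))
        plain = pearson_chi2(counts, library.get("3:1"))
        corrected = pearson_chi2(counts, library.get("3:1"), continuity_correction=True)
        assert corrected.chi2 < plain.chi2

    def test_majority_first_orientation(self):
        c = SegregationCounts.from_unordered("t", [46, 133])
        assert c.observed == (133, 46)

    @settings(derandomize=True, max_examples=80)
    @given(
        dom=st.integers(min_value=0, max_value=2000),
        rec=st.integers(min_value=0, max_value=2000),
        name=st.sampled_from(["3:1", "13:3", "15:1", "61:3", "63:1"]),
    )
    def test_result_invariants(self, dom, rec, name):
        if dom + rec == 0:
            return
        res = pearson_chi2(SegregationCounts("t", (dom, rec)), RatioLibrary().get(name))
        assert res.chi2 >= 0
        assert 0.0 <= res.p_value <= 1.0
        critical = stats.chi2.ppf(1 - res.alpha, res.df)
        assert res.rejected == (res.chi2 > critical)


class TestRatioBattery:
    def test_monogenic_split_screened_against_battery(self, library):
        results = ratio_battery(
            SegregationCounts("awnedness", (133, 46)), library.subset(["3:1", "13:3", "15:1"])
        )
        assert [r.model_name for r in results] == ["3:1", "13:3", "15:1"]
        by_model = {r.model_name: r for r in results}
        assert round(by_model["3:1"].chi2, 3) == 0.047
        assert not by_model["3:1"].rejected

    def test_near_exact_expectation(self, library):
        (res,) = ratio_battery(SegregationCounts("t", (140, 47)), library.subset(["3:1"]))
        assert res.chi2 < 0.01
        assert not res.rejected

    def test_even_split_rejects_fifteen_to_one(self, library):
        (res,) = ratio_battery(SegregationCounts("t", (50, 50)), library.subset(["15:1"]))
        assert res.rejected
        assert res.chi2 > stats.chi2.ppf(0.95, 1)

    def test_empty_library_raises(self):
        with pytest.raises(ValueError, match="empty"):
            ratio_battery(SegregationCounts("t", (75, 25)), RatioLibrary(entries=[]))


def _result(trait, model, chi2, alpha=0.05):
    critical = float(stats.chi2.ppf(1 - alpha, 1))
    return ChiSquareResult(
        trait=trait,
        model_name=model,
        chi2=chi2,
        df=1,
        p_value=float(stats.chi2.sf(chi2, 1)),
        alpha=alpha,
        rejected=chi2 > critical,
        observed=(0, 0),
        expected=(1.0, 1.0),
    )


class TestProjectionConsistency:
    @pytest.mark.parametrize(
        "chi2s,expected",
        [
            ((1.0, 2.0, 0.5, 3.0), True),
            ((1.0, 2.0, 5.0, 3.0), False),
            ((0.0, 0.0, 0.0, 0.0), True),
        ],
    )
    def test_consistent_iff_no_projection_rejects(self, chi2s, expected):
        results = [_result("SAA", "3:1", c) for c in chi2s]
        verdict = projection_consistency(results)
        assert verdict.consistent is expected

    def test_requires_exactly_four(self):
        with pytest.raises(ValueError, match="4"):
            projection_consistency([_result("SAA", "3:1", 1.0)] * 3)

    def test_mismatched_labels_raise(self):
        results = [_result("SAA", "3:1", 1.0)] * 3 + [_result("SA", "3:1", 1.0)]
        with pytest.raises(ValueError, match="share one trait"):
            projection_consistency(results)


class TestGroupComparison:
    def test_identical_groups(self):
        values = list(range(20)) * 2
        labels = ["a"] * 20 + ["b"] * 20
        cmp = group_comparison(values, labels)
        assert cmp.means["a"] == cmp.means["b"]
        assert cmp.pairwise_p[("a", "b")] > 0.9

    def test_widely_separated_groups(self):
        rng = np.random.default_rng(5)
        values = np.concatenate([rng.normal(0, 1, 50), rng.normal(10, 1, 50)])
        labels = ["low"] * 50 + ["high"] * 50
        cmp = group_comparison(values, labels)
        assert cmp.anova_p < 1e-3
        assert cmp.pairwise_p[("low", "high")] < 1e-3
        assert cmp.means["high"] - cmp.means["low"] == pytest.approx(10, abs=0.6)

    def test_three_ordered_disjoint_groups(self):
        # awnless < awned < tetraaristatum, non-overlapping supports
        values = np.concatenate([np.linspace(0, 1, 10), np.linspace(5, 6, 10), np.linspace(10, 11, 10)])
        labels = ["awnless"] * 10 + ["awned"] * 10 + ["tetraaristatum"] * 10
        cmp = group_comparison(values, labels)
        assert cmp.anova_p < 1e-4
        assert all(p < 0.01 for p in cmp.pairwise_p.values())
        assert cmp.means["awnless"] < cmp.means["awned"] < cmp.means["tetraaristatum"]

    def test_undersized_group_raises(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            group_comparison([1.0, 2.0, 3.0], ["a", "a", "b"])

    def test_single_group_raises(self):
        with pytest.raises(ValueError, match="two groups"):
            group_comparison([1.0, 2.0], ["a", "a"])
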