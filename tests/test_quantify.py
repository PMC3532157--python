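"""Normalization, the t-test, fold changes and the summary arithmetic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from solidsage import (
    abundance_rank,
    category_summary,
    coverage_estimate,
    de_scan,
    fold_change,
    gene_capture,
    gene_content,
    normalize_tpm,
    percent_of_mapped,
    unpaired_t,
)
from solidsage.quantify import ExpressionMatrix


def make_matrix(counts: dict, ctrl="Eminus", trt="Eplus", unit="tpm"):
    """ExpressionMatrix from tag -> six raw counts (3 ctrl + 3 trt)."""
    cols = [f"{ctrl}:{i}" for i in (1, 2, 3)] + [f"{trt}:{i}" for i in (1, 2, 3)]
    df = pd.DataFrame(counts, index=cols).T
    totals = df.sum(axis=0).astype(float)
    scale = 1e6 if unit == "tpm" else 100.0
    return ExpressionMatrix(df, df / totals * scale, totals, unit)


class TestNormalization:
    def test_tpm_examples(self):
        assert normalize_tpm(0, 1_000_000) == 0
        assert normalize_tpm(50, 2_000_000) == 25

    def test_tpm_zero_denominator(self):
        with pytest.raises(ValueError):
            normalize_tpm(5, 0)

    def test_tpm_recovers_true_proportion(self, rng):
        # an abundant tag at true proportion 0.012 in a million-tag library
        count = rng.binomial(1_000_000, 0.012)
        tpm = normalize_tpm(count, 1_000_000)
        sd = np.sqrt(1e6 * 0.012 * 0.988)
        assert abs(tpm - 12_000) < 3 * sd

    def test_percent_examples(self):
        assert percent_of_mapped(43199, 43199) == 100
        assert percent_of_mapped(1012, 10000) == pytest.approx(10.12)
        with pytest.raises(ValueError):
            percent_of_mapped(1, 0)

    def test_percents_sum_to_100(self, rng):
        counts = rng.integers(1, 500, 40)
        total = counts.sum()
        assert sum(percent_of_mapped(c, total) for c in counts) == pytest.approx(100)


class TestUnpairedT:
    def test_identical_groups(self):
        assert unpaired_t([5, 5, 5], [5, 5, 5]) == (0.0, 1.0)

    def test_textbook_example(self):
        t, p = unpaired_t([10, 11, 12], [20, 21, 22])
        assert abs(t) == pytest.approx(12.247, abs=0.001)
        assert p == pytest.approx(2.6e-4, rel=0.02)

    def test_agrees_with_scipy_oracle(self, rng):
        for _ in range(20):
            a = rng.normal(10, 2, size=3)
            b = rng.normal(12, 3, size=3)
            t, p = unpaired_t(a, b)
            t_ref, p_ref = stats.ttest_ind(b, a, equal_var=True)
            assert t == pytest.approx(t_ref)
            assert p == pytest.approx(p_ref)

    def test_degenerate_zero_variance_unequal_means(self):
        t, p = unpaired_t([1, 1, 1], [2, 2, 2])
        assert np.isinf(t) and t > 0
        assert p == 0.0

    def test_group_size_guard(self):
        with pytest.raises(ValueError):
            unpaired_t([1], [2, 3])


class TestFoldChange:
    def test_equal_means(self):
        assert fold_change(5, 5) == 1

    def test_printed_range_convention(self):
        assert fold_change(10, 74) == pytest.approx(7.4)
        assert fold_change(72, 10) == pytest.approx(-7.2)

    def test_antisymmetry(self, rng):
        for _ in range(50):
            a, b = rng.uniform(0.1, 100, 2)
            assert fold_change(a, b) == pytest.approx(-fold_change(b, a))
            assert abs(fold_change(a, b)) == pytest.approx(abs(fold_change(b, a)))

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            fold_change(0, 0)


class TestDeScan:
    def test_identical_replicates_not_significant(self):
        m = make_matrix({"CATG" + "A" * 23: [10, 10, 10, 10, 10, 10]})
        result = de_scan(m, "Eminus", "Eplus")
        assert not result["significant"].any()

    def test_clear_effect_flagged_with_direction(self):
        tag_up = "CATG" + "A" * 23
        tag_null = "CATG" + "C" * 23
        tag_bg = "CATG" + "T" * 23  # balances column totals so tag_null is truly null
        up = [10, 11, 12, 48, 50, 52]
        null = [100, 101, 99, 100, 102, 98]
        bg = [200 - a - b for a, b in zip(up, null)]
        m = make_matrix({tag_up: up, tag_null: null, tag_bg: bg})
        result = de_scan(m, "Eminus", "Eplus")
        assert bool(result.loc[tag_up, "significant"])
        assert result.loc[tag_up, "fold_change"] > 1
        assert not bool(result.loc[tag_null, "significant"])
        # sorted by p-value
        assert list(result.index)[0] == tag_up

    def test_zero_group_mean_floored(self):
        tag = "CATG" + "G" * 23
        other = "CATG" + "C" * 23
        m = make_matrix({tag: [0, 0, 0, 30, 32, 31], other: [50, 50, 50, 20, 20, 20]})
        result = de_scan(m, "Eminus", "Eplus")
        assert bool(result.loc[tag, "floored"])
        assert np.isfinite(result.loc[tag, "fold_change"])
        assert result.loc[tag, "fold_change"] > 1

    def test_type_one_error_near_nominal(self, rng):
        # 1000 null tags: same sampling distribution in both groups
        names = ["CATG" + np.base_repr(i, 4).zfill(23).translate(str.maketrans("0123", "ACGT")) for i in range(1000)]
        data = {name: rng.poisson(100, size=6) + 1 for name in names}
        m = make_matrix(data)
        result = de_scan(m, "Eminus", "Eplus")
        rate = result["significant"].mean()
        assert 0.03 <= rate <= 0.07

    def test_bonferroni_option_is_stricter(self, rng):
        names = ["CATG" + np.base_repr(i, 4).zfill(23).translate(str.maketrans("0123", "ACGT")) for i in range(200)]
        data = {name: rng.poisson(100, size=6) + 1 for name in names}
        m = make_matrix(data)
        raw = de_scan(m, "Eminus", "Eplus")
        adj = de_scan(m, "Eminus", "Eplus", correction="bonferroni")
        assert adj["significant"].sum() <= raw["significant"].sum()


class TestAbundanceRank:
    table4_like = pd.Series(
        {"A": 10.12, "B": 6.34, "C": 4.60, "D": 2.60, "E": 2.58, "F": 0.005}
    )

    def test_threshold_and_order(self):
        result = abundance_rank(self.table4_like, threshold=0.01)
        assert list(result.table.index) == ["A", "B", "C", "D", "E"]
        assert result.count == 5
        assert result.total_share == pytest.approx(26.24)

    def test_threshold_zero_returns_all(self):
        assert abundance_rank(self.table4_like, threshold=0).count == 6

    def test_empty_input(self):
        result = abundance_rank(pd.Series(dtype=float))
        assert result.count == 0 and result.total_share == 0

    def test_cumulative_column(self):
        result = abundance_rank(self.table4_like)
        assert result.table["cumulative_percent"].iloc[-1] == pytest.approx(
            result.total_share
        )


class TestSummaryArithmetic:
    def test_gene_capture(self):
        assert gene_capture(6298, 9440) == 67
        assert gene_capture(9440, 9440) == 100
        assert gene_capture(0, 9440) == 0

    def test_gene_content(self):
        assert gene_content(41000, 3) == 123000

    def test_coverage(self):
        assert coverage_estimate(68817, 41000, 3) == 56
        assert coverage_estimate(123000, 41000, 3) == 100
        assert coverage_estimate(10000, 41000, 3) == 8

    def test_guards(self):
        with pytest.raises(ValueError):
            gene_capture(1, 0)
        with pytest.raises(ValueError):
            coverage_estimate(0, 41000, 3)


class TestCategorySummary:
    def test_round_half_away_from_zero(self):
        # 9 of 72 up-regulated = 12.5% -> 13% under the report convention
        rows = [{"tag": f"t{i}", "category": "Photosynthesis", "direction": "up"} for i in range(9)]
        rows += [{"tag": f"u{i}", "category": "Other", "direction": "up"} for i in range(63)]
        summary = category_summary(pd.DataFrame(rows))
        photo = summary[summary["category"] == "Photosynthesis"].iloc[0]
        assert photo["up_n"] == 9
        assert photo["up_pct"] == 13

    def test_single_category_is_100(self):
        df = pd.DataFrame([{"tag": "t", "category": "X", "direction": "down"}])
        summary = category_summary(df)
        assert summary[summary["category"] == "X"].iloc[0]["down_pct"] == 100

    def test_totals_row(self):
        rows = [{"tag": f"t{i}", "category": "A", "direction": "up"} for i in range(3)]
        rows += [{"tag": f"d{i}", "category": "B", "direction": "down"} for i in range(5)]
        summary = category_summary(pd.DataFrame(rows))
        total = summary[summary["category"] == "Total"].iloc[0]
        assert total["up_n"] == 3 and total["down_n"] == 5

    def test_unlabelled_become_no_match(self):
        df = pd.DataFrame(
            [
                {"tag": "t1", "category": None, "direction": "up"},
                {"tag": "t2", "category": "", "direction": "up"},
            ]
        )
        summary = category_summary(df)
        row = summary[summary["category"] == "No match"].iloc[0]
        assert row["up_n"] == 2

    def test_bad_direction_rejected(self):
        df = pd.DataFrame([{"tag": "t", "category": "A", "direction": "sideways"}])
        with pytest.raises(ValueError):
            category_summary(df)
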