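"""BMI arithmetic, frequency/percentile tables, weight-status classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bqrbmi.descriptive import (
    EMDHS_HOUSEHOLDS_INTERVIEWED,
    EMDHS_HOUSEHOLDS_OCCUPIED,
    EMDHS_2019_FREQUENCIES,
    classify_weight_status,
    classify_with_cutoffs,
    compute_bmi,
    frequency_table,
    normality_report,
    percentile_table,
    response_rate_percent,
)

# printed one-decimal percentages of the 2019 EMDHS categorical summary
EXPECTED_PERCENTAGES = {
    "toilet_facility": {"improved": 20.1, "unimproved": 79.9},
    "water_source": {"improved": 61.5, "unimproved": 38.5},
    "birth_type": {"singleton": 97.7, "multiple": 2.3},
    "sex": {"male": 51.1, "female": 48.9},
    "maternal_education": {"no_formal": 54.7, "primary": 31.4, "secondary_plus": 13.8},
    "wealth_index": {
        "poorest": 33.9, "poorer": 17.4, "middle": 13.9, "richer": 13.0, "richest": 21.8,
    },
    "religion": {"orthodox": 28.5, "protestant": 18.5, "muslim": 51.0, "others": 2.0},
    "residence": {"urban": 23.1, "rural": 76.9},
    "marital_status": {"not_married": 6.8, "married": 93.2},
    "breastfeeding": {"ever_not_current": 54.3, "never": 4.2, "still": 41.4},
    "n_under_five": {"lt2": 38.0, "two": 44.7, "three_plus": 17.3},
    "household_size": {"le4": 27.3, "5_9": 65.5, "ge10": 7.2},
}


class TestComputeBmi:
    @pytest.mark.parametrize("w,h,expected", [(10, 0.8, 15.625), (12, 1.0, 12.0)])
    def test_formula(self, w, h, expected):
        assert compute_bmi(w, h) == pytest.approx(expected)

    def test_doubling_height_quarters_bmi(self):
        assert compute_bmi(10, 1.6) == pytest.approx(compute_bmi(10, 0.8) / 4)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            compute_bmi(0, 1.0)
        with pytest.raises(ValueError):
            compute_bmi(10, -0.5)


class TestFrequencyTable:
    @pytest.mark.parametrize("variable", sorted(EMDHS_2019_FREQUENCIES))
    def test_reproduces_survey_percentages(self, variable):
        counts = EMDHS_2019_FREQUENCIES[variable]
        column = [cat for cat, k in counts.items() for _ in range(k)]
        table = frequency_table(column)
        got = dict(zip(table["category"], table["percentage"]))
        assert got == EXPECTED_PERCENTAGES[variable]
        assert table["count"].sum() == 5323

    def test_single_category(self):
        table = frequency_table(["a"] * 10)
        assert table["percentage"].tolist() == [100.0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            frequency_table([])

    @given(st.lists(st.sampled_from("abcd"), min_size=1, max_size=300))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_percentages_sum_to_hundred(self, column):
        table = frequency_table(column)
        assert table["percentage"].sum() == pytest.approx(100.0, abs=0.1 * len(table))


def test_response_rate_matches_survey_arithmetic():
    assert response_rate_percent(EMDHS_HOUSEHOLDS_INTERVIEWED, EMDHS_HOUSEHOLDS_OCCUPIED) == 99
    with pytest.raises(ValueError):
        response_rate_percent(10, 0)


class TestPercentileTable:
    def test_linear_interpolation_median(self):
        table = percentile_table(np.arange(1, 101))
        assert table.values[2] == pytest.approx(50.5)

    def test_constant_vector(self):
        table = percentile_table(np.full(40, 7.0))
        assert np.all(table.values == 7.0)

    def test_normal_tail_quantile(self):
        draws = np.random.default_rng(61).standard_normal(100_000)
        table = percentile_table(draws)
        assert table.values[-1] == pytest.approx(1.6449, abs=0.02)

    def test_values_non_decreasing(self):
        draws = np.random.default_rng(62).exponential(size=500)
        assert np.all(np.diff(percentile_table(draws).values) >= 0)

    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_sort_and_interpolate_oracle(self, values):
        table = percentile_table(values)
        x = np.sort(np.asarray(values, dtype=float))
        n = x.size
        for level, got in zip(table.levels, table.values):
            pos = (n - 1) * level / 100.0
            lo, frac = int(np.floor(pos)), pos - np.floor(pos)
            expected = x[lo] if lo == n - 1 else x[lo] * (1 - frac) + x[lo + 1] * frac
            assert got == pytest.approx(expected, rel=1e-9, abs=1e-9)


class TestWeightStatus:
    def test_fixed_survey_cutoffs(self):
        cutoffs = (12.92, 17.06, 18.27)
        labels = classify_with_cutoffs([12.5, 17.5, 18.27, 15.0], cutoffs)
        assert labels == ["underweight", "overweight", "obese", "normal"]

    def test_partition_fractions_on_continuous_sample(self):
        draws = np.random.default_rng(63).normal(15.5, 1.6, 100_000)
        labels, cutoffs = classify_weight_status(draws)
        counts = {c: labels.count(c) for c in set(labels)}
        n = len(labels)
        assert counts["underweight"] / n == pytest.approx(0.05, abs=0.005)
        assert counts["normal"] / n == pytest.approx(0.80, abs=0.005)
        assert counts["overweight"] / n == pytest.approx(0.10, abs=0.005)
        assert counts["obese"] / n == pytest.approx(0.05, abs=0.005)
        assert sum(counts.values()) == n
        assert cutoffs[0] < cutoffs[1] < cutoffs[2]

    def test_boundary_values_single_classification(self):
        cutoffs = (12.0, 17.0, 18.0)
        assert classify_with_cutoffs([12.0], cutoffs) == ["normal"]  # lower-inclusive
        assert classify_with_cutoffs([17.0], cutoffs) == ["overweight"]
        assert classify_with_cutoffs([18.0], cutoffs) == ["obese"]  # at or above p95

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            classify_weight_status(np.arange(5.0))


class TestNormalityReport:
    def test_normal_sample_low_skewness(self):
        draws = np.random.default_rng(64).standard_normal(100_000)
        assert abs(normality_report(draws)["skewness"]) < 0.1

    def test_qq_pairs_near_identity_for_normal_sample(self):
        draws = np.random.default_rng(65).standard_normal(5000)
        report = normality_report(draws)
        inner = slice(50, -50)  # extreme order statistics are noisy
        gap = np.abs(report["qq_sample"][inner] - report["qq_theoretical"][inner])
        assert gap.max() < 0.15

    def test_lognormal_sample_right_skewed(self):
        draws = np.exp(np.random.default_rng(66).standard_normal(20_000))
        assert normality_report(draws)["skewness"] > 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            normality_report(np.full(100, 2.0))

    def test_histogram_counts_cover_sample(self):
        draws = np.random.default_rng(67).standard_normal(1000)
        report = normality_report(draws)
        assert report["bin_counts"].sum() == 1000
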