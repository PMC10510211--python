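"""Robust outlier trimming, replicate aggregation and comparison stats."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paretodock import (
    DomainError,
    ScoreObservation,
    aggregate,
    compare_conditions,
    rout_outliers,
    sidak_adjust,
)


def observations(ligand, condition, scores):
    return [
        ScoreObservation(ligand, condition, i + 1, s)
        for i, s in enumerate(scores)
    ]


class TestRoutOutliers:
    def test_gross_failure_among_tight_replicates_is_flagged(self):
        retained, flagged = rout_outliers(
            [-9.0, -9.1, -8.9, -8.95, -9.05, -3.0], q=0.01
        )
        assert flagged == [-3.0]
        assert sorted(retained) == [-9.1, -9.05, -9.0, -8.95, -8.9]

    def test_identical_values_never_flagged(self):
        retained, flagged = rout_outliers([-9.0, -9.0, -9.0])
        assert flagged == []
        assert retained == [-9.0, -9.0, -9.0]

    def test_below_three_values_retained_without_testing(self, caplog):
        with caplog.at_level("WARNING"):
            retained, flagged = rout_outliers([-9.0, -3.0])
        assert retained == [-9.0, -3.0] and flagged == []
        assert "retaining all" in caplog.text

    def test_invalid_q_rejected(self):
        with pytest.raises(DomainError):
            rout_outliers([-9.0, -9.1, -8.9], q=1.5)

    def test_partition_is_conserved(self):
        values = [-9.0, -9.3, -8.7, -2.0, -15.5, -9.1]
        retained, flagged = rout_outliers(values)
        assert sorted(retained + flagged) == sorted(values)

    def test_clean_gaussian_flag_rate_near_nominal_q(self):
        # n = 6 tight replicates: flagging anything should stay rare.
        rng = np.random.default_rng(2024)
        n_flagged = 0
        for _ in range(1000):
            values = rng.normal(-9.0, 0.1, 6)
            _, flagged = rout_outliers(values, q=0.01)
            n_flagged += bool(flagged)
        assert n_flagged / 1000 <= 0.05

    def test_planted_six_kcal_displacement_always_caught(self):
        rng = np.random.default_rng(7)
        caught = 0
        for _ in range(1000):
            values = list(rng.normal(-9.0, 0.3, 6))
            values[2] += 6.0  # failed run: far weaker apparent binding
            _, flagged = rout_outliers(values, q=0.01)
            caught += values[2] in flagged
        assert caught / 1000 >= 0.99


class TestAggregate:
    def test_closed_form_mean_sd_sem(self):
        obs = observations("ligA", "neutral", [-9.0, -9.1, -8.9])
        (agg,) = aggregate(obs)
        assert agg.mean_magnitude == pytest.approx(9.0)
        assert agg.sd == pytest.approx(0.1)
        assert agg.sem == pytest.approx(0.1 / math.sqrt(3))
        assert (agg.n_total, agg.n_used, agg.n_outliers) == (3, 3, 0)

    def test_single_replicate_group_warns_and_zeroes_spread(self, caplog):
        with caplog.at_level("WARNING"):
            (agg,) = aggregate(observations("ligA", "acidic", [-7.5]))
        assert agg.mean_magnitude == 7.5
        assert agg.sd == agg.sem == 0.0
        assert agg.n_used == 1

    def test_outlier_removed_before_averaging(self):
        obs = observations(
            "ligA", "neutral", [-9.0, -9.1, -8.9, -8.95, -9.05, -3.0]
        )
        (agg,) = aggregate(obs)
        assert agg.n_outliers == 1
        assert agg.outlier_values == [-3.0]
        assert agg.mean_magnitude == pytest.approx(9.0)
        assert agg.n_used + agg.n_outliers == agg.n_total

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            aggregate([])

    @settings(derandomize=True, max_examples=50)
    @given(
        scores=st.lists(
            st.floats(-12.0, -4.0, allow_nan=False), min_size=3, max_size=8
        ),
        seed=st.integers(0, 2**16),
    )
    def test_permutation_invariance(self, scores, seed):
        rng = np.random.default_rng(seed)
        shuffled = list(rng.permutation(scores))
        (a,) = aggregate(observations("L", "c", scores))
        (b,) = aggregate(observations("L", "c", shuffled))
        assert a.mean_magnitude == pytest.approx(b.mean_magnitude)
        assert a.n_outliers == b.n_outliers


class TestCompareConditions:
    def test_identical_samples_give_zero_statistic_unit_p(self):
        result = compare_conditions([9.0, 9.1, 8.9], [9.0, 9.1, 8.9])
        assert result.statistic == 0.0
        assert result.p_value == pytest.approx(1.0)

    def test_paired_zero_differences_give_unit_p(self):
        result = compare_conditions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0],
                                    paired=True)
        assert result.kind == "paired_t"
        assert result.p_value == 1.0

    def test_clear_shift_is_significant_unpaired(self):
        result = compare_conditions([9.0, 9.1, 8.9], [8.6, 8.7, 8.5])
        assert result.kind == "unpaired_t"
        assert result.p_value < 0.05
        # closed form: mean diff 0.4, pooled sd 0.1, 4 df
        assert result.statistic == pytest.approx(0.4 / (0.1 * math.sqrt(2 / 3)))

    def test_paired_requires_equal_lengths(self):
        with pytest.raises(DomainError):
            compare_conditions([1.0, 2.0], [1.0, 2.0, 3.0], paired=True)

    def test_insufficient_n_rejected(self):
        with pytest.raises(DomainError):
            compare_conditions([1.0], [1.0, 2.0])


class TestSidak:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(0.01, 4, 1 - 0.99**4), (0.3, 1, 0.3), (0.0, 10, 0.0), (1.0, 3, 1.0)],
    )
    def test_known_values(self, p, m, expected):
        assert sidak_adjust(p, m) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100)
    @given(p=st.floats(0.0, 1.0), m=st.integers(1, 50))
    def test_monotone_and_at_least_identity(self, p, m):
        adj = sidak_adjust(p, m)
        assert adj >= p - 1e-15
        assert adj <= 1.0
        assert sidak_adjust(p, m + 1) >= adj - 1e-15
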