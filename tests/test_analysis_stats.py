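import numpy as np
import pandas as pd
import pytest

from foci.analysis_stats import (
    InductionCount,
    adjust_pvalues,
    aggregate_count_summary,
    fold_change,
    group_comparison,
    induction_frequency,
    mean_induction_frequency,
    volume_movement_regression,
)
from foci.exceptions import ValidationError
from foci.trajectory_io import CountTable


def ols_oracle(x, y):
    """Normal-equations OLS, independent of scipy's fitting path."""
    A = np.column_stack([np.asarray(x, float), np.ones(len(x))])
    return np.linalg.solve(A.T @ A, A.T @ np.asarray(y, float))


class TestVolumeMovementRegression:
    def test_exact_line_r_squared_one(self):
        x = np.arange(10.0)
        res = volume_movement_regression(x, 3.0 * x - 1.0)
        assert res.slope == pytest.approx(3.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_response_slope_zero(self):
        res = volume_movement_regression(np.arange(5.0), np.full(5, 2.0))
        assert res.slope == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(0.0)

    def test_agrees_with_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.random(30)
        y = 0.4 - 1.2 * x + rng.normal(0, 0.1, 30)
        res = volume_movement_regression(x, y)
        slope, intercept = ols_oracle(x, y)
        assert res.slope == pytest.approx(slope, abs=1e-9)
        assert res.intercept == pytest.approx(intercept, abs=1e-9)

    def test_sigma_decreasing_with_volume_gives_negative_slope(self):
        """Fixture mimicking the size/mobility relation: larger foci move
        less, so the sigma-vs-volume slope is negative."""
        from foci.movement_model import fit_markov_model
        from foci.synthetic_data import SimulationParams, simulate_trajectory

        vols, sigmas = [], []
        for i, (v, s) in enumerate([(0.2, 0.5), (0.5, 0.35), (1.0, 0.2), (2.0, 0.1)]):
            for rep in range(3):
                params = SimulationParams(
                    gamma_true=0.0, sigma_true=s, n_steps=200, boundary="none",
                    seed=10 * i + rep,
                )
                fit = fit_markov_model(simulate_trajectory(params))
                vols.append(v)
                sigmas.append(fit.sigma)
        res = volume_movement_regression(vols, sigmas)
        assert res.slope < 0

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValidationError):
            volume_movement_regression(np.ones(5), np.arange(5.0))


class TestAggregateCountSummary:
    @staticmethod
    def table(counts, group="wt"):
        return CountTable(
            pd.DataFrame(
                {
                    "cell_id": [f"c{i}" for i in range(len(counts))],
                    "group": group,
                    "count": counts,
                }
            )
        )

    def test_three_quarters_single(self):
        (s,) = aggregate_count_summary(self.table([1, 1, 1, 2])).values()
        assert s.percent_single == pytest.approx(75.0)

    def test_all_singletons(self):
        (s,) = aggregate_count_summary(self.table([1] * 6)).values()
        assert s.percent_single == pytest.approx(100.0)
        assert s.mean_count == pytest.approx(1.0)

    def test_seven_of_nine(self):
        (s,) = aggregate_count_summary(self.table([1, 1, 1, 1, 1, 1, 1, 2, 3])).values()
        assert s.percent_single == pytest.approx(77.8, abs=0.05)
        assert s.distribution == {1: 7, 2: 1, 3: 1}

    def test_single_plus_multiple_is_hundred(self):
        (s,) = aggregate_count_summary(self.table([1, 2, 2, 3, 1])).values()
        assert s.percent_single + s.percent_multiple == pytest.approx(100.0)


class TestGroupComparison:
    def test_identical_samples_ks_statistic_zero(self):
        a = np.arange(10.0)
        assert group_comparison(a, a, "ks").statistic == pytest.approx(0.0)

    def test_constant_shift_paired_t_degenerate(self):
        a = np.arange(5.0)
        with pytest.raises(ValidationError, match="degenerate"):
            group_comparison(a, a + 1.0, "paired_t")

    def test_paired_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            group_comparison(np.arange(4.0), np.arange(5.0), "paired_t")

    def test_welch_equal_means_agrees_with_permutation_oracle(self):
        """Welch's t on equal-mean samples: large p, close to a
        permutation-test p-value on the same small samples."""
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 12)
        b = rng.normal(0, 2, 12)
        b = b - b.mean() + a.mean()  # force equal means
        res = group_comparison(a, b, "welch_t")
        assert res.p_value > 0.9
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        perm_rng = np.random.default_rng(0)
        hits = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm = perm_rng.permutation(pooled)
            hits += abs(perm[:12].mean() - perm[12:].mean()) >= obs
        assert res.p_value == pytest.approx(hits / n_perm, abs=0.1)

    def test_ks_detects_spread_change(self):
        rng = np.random.default_rng(3)
        narrow = rng.normal(0, 1, 200)
        wide = rng.normal(0, 3, 200)
        assert group_comparison(narrow, wide, "ks").p_value < 1e-5


class TestInductionFrequency:
    def test_wildtype_scale(self):
        ic = induction_frequency(60, 100, 100)
        assert ic.frequency == pytest.approx(0.006)

    def test_zero_colonies_zero_frequency(self):
        assert induction_frequency(0, 100).frequency == 0.0

    def test_zero_cfu_rejected(self):
        with pytest.raises(ValidationError):
            induction_frequency(10, 0)

    def test_fold_change_near_two_and_a_half(self):
        hi = induction_frequency(140, 100, 100)  # 0.014
        wt = induction_frequency(60, 100, 100)  # 0.006
        assert fold_change(hi, wt) == pytest.approx(2.333, abs=0.001)

    def test_linear_in_colonies_inverse_in_cfu(self):
        base = induction_frequency(30, 100).frequency
        assert induction_frequency(60, 100).frequency == pytest.approx(2 * base)
        assert induction_frequency(30, 200).frequency == pytest.approx(base / 2)

    def test_outlier_exclusion_option(self):
        reps = [
            InductionCount(60, 100),  # 0.006
            InductionCount(80, 100),  # 0.008
            InductionCount(2500, 100),  # 0.25 outlier
        ]
        assert mean_induction_frequency(reps) == pytest.approx((0.006 + 0.008 + 0.25) / 3)
        assert mean_induction_frequency(reps, exclude_above=0.1) == pytest.approx(0.007)

    def test_holm_adjustment_monotone(self):
        p = [0.01, 0.04, 0.03, 0.5]
        adj = adjust_pvalues(p, "holm")
        assert np.all(adj >= np.asarray(p))
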