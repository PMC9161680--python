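"""Mixed models, circular-shift permutation, and repeated-measures ANOVA."""

import warnings

import numpy as np
import pytest
from scipy import stats

from thetaburst.inference import (
    circular_shift_permutation,
    fit_categorical_lmm,
    fit_intercept_lmm,
    lrt_fixed_effect,
    session_quartile_anova,
)


def _quiet(fn, *args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fn(*args, **kwargs)


class TestCircularShift:
    def test_null_composition_matches_hand_enumeration(self):
        """Oracle: explicit loops over every shift of y and of reversed y."""
        x = np.array([1.0, 2.0, 4.0, 3.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        result = circular_shift_permutation(x, y)
        null_oracle = []
        for k in range(1, 4):
            null_oracle.append(stats.pearsonr(x, np.roll(y, k)).statistic)
        for k in range(4):
            null_oracle.append(stats.pearsonr(x, np.roll(y[::-1], k)).statistic)
        assert result.null.size == 7  # (n-1) + n
        assert np.allclose(np.sort(result.null), np.sort(null_oracle))
        n_ge = sum(v >= result.observed for v in null_oracle)
        assert result.p_value == pytest.approx((1 + n_ge) / 8)

    def test_perfect_alignment_attains_minimum_p(self):
        x = np.arange(10.0)
        result = circular_shift_permutation(x, x)
        assert result.observed == pytest.approx(1.0)
        assert result.p_value == pytest.approx(1.0 / (1 + 19))

    def test_add_one_correction_keeps_p_positive(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            r = circular_shift_permutation(rng.standard_normal(8), rng.standard_normal(8))
            assert 0 < r.p_value <= 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            circular_shift_permutation(np.arange(3.0), np.arange(3.0))
        with pytest.raises(ValueError):
            circular_shift_permutation(np.arange(5.0), np.arange(4.0))
        with pytest.raises(ValueError, match="constant"):
            circular_shift_permutation(np.ones(6), np.arange(6.0))


class TestInterceptLmm:
    def test_constant_data_recovers_constant(self):
        values = np.full(60, 2.5)
        subj = np.repeat(np.arange(6), 10)
        res = _quiet(fit_intercept_lmm, values, subj)
        assert res.fixed_effects.loc["Intercept", "estimate"] == pytest.approx(2.5, abs=1e-6)

    def test_zero_random_variance_reduces_to_one_sample_t(self):
        """Without group structure in the data, the LMM collapses to the
        ordinary mean and its standard error (within 2%)."""
        rng = np.random.default_rng(8)
        values = rng.standard_normal(400) + 0.4
        subj = np.repeat(np.arange(40), 10)
        res = _quiet(fit_intercept_lmm, values, subj)
        mean, se = values.mean(), values.std(ddof=1) / np.sqrt(values.size)
        assert res.fixed_effects.loc["Intercept", "estimate"] == pytest.approx(mean, rel=0.02)
        assert res.fixed_effects.loc["Intercept", "se"] == pytest.approx(se, rel=0.02)

    def test_mixed_effect_recovery_coverage(self):
        """95% CI covers the true population mean in >= 90% of seeded runs."""
        covered = 0
        n_rep = 30
        for rep in range(n_rep):
            rng = np.random.default_rng(200 + rep)
            mu, n_sub, n_sess, n_el = 0.2, 12, 2, 20
            subj = np.repeat(np.arange(n_sub), n_sess * n_el)
            sess = np.repeat(np.arange(n_sub * n_sess), n_el)
            y = (
                mu
                + np.repeat(rng.normal(0, 0.3, n_sub), n_sess * n_el)
                + np.repeat(rng.normal(0, 0.2, n_sub * n_sess), n_el)
                + rng.standard_normal(subj.size)
            )
            res = _quiet(fit_intercept_lmm, y, subj, sess)
            fe = res.fixed_effects.loc["Intercept"]
            covered += fe["ci_low"] <= mu <= fe["ci_high"]
        assert covered >= int(0.9 * n_rep) - 2

    def test_wald_scale_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(120) + 0.3
        subj = np.repeat(np.arange(6), 20)
        z1 = _quiet(fit_intercept_lmm, y, subj).intercept_z
        z2 = _quiet(fit_intercept_lmm, 10 * y, subj).intercept_z
        assert z1 == pytest.approx(z2, rel=1e-6)
        assert np.sign(z1) == 1.0

    def test_needs_two_subjects(self):
        with pytest.raises(ValueError, match="subjects"):
            fit_intercept_lmm(np.arange(10.0), np.zeros(10))


class TestCategoricalLmm:
    def test_known_level_shifts_recovered(self):
        rng = np.random.default_rng(5)
        levels = [3, 4, 5, 6, 7, 8]
        values, factor, subj = [], [], []
        for i, lv in enumerate(levels):
            values.append(rng.standard_normal(60) + 0.5 * i)
            factor += [lv] * 60
            subj.append(np.tile(np.arange(6), 10))
        res = _quiet(
            fit_categorical_lmm, np.concatenate(values), factor, np.concatenate(subj)
        )
        assert len(res.contrasts) == 15
        row = res.contrasts[(res.contrasts.level_a == 3) & (res.contrasts.level_b == 8)]
        assert row["estimate"].iloc[0] == pytest.approx(2.5, abs=0.3)

    def test_single_level_raises(self):
        with pytest.raises(ValueError, match="levels"):
            fit_categorical_lmm(np.arange(10.0), [5] * 10, np.repeat([0, 1], 5))

    def test_sparse_level_raises(self):
        factor = [3] * 9 + [4]
        with pytest.raises(ValueError, match="fewer than 2"):
            fit_categorical_lmm(np.arange(10.0), factor, np.repeat([0, 1], 5))

    def test_holm_adjustment_monotone(self):
        rng = np.random.default_rng(6)
        values = rng.standard_normal(120)
        factor = np.repeat([3, 4, 5], 40)
        subj = np.tile(np.repeat([0, 1, 2, 3], 10), 3)
        res = _quiet(fit_categorical_lmm, values, factor, subj, holm=True)
        assert np.all(res.contrasts["p_holm"] >= res.contrasts["p"] - 1e-12)


class TestLrt:
    def test_constant_covariate_null_result(self):
        res = lrt_fixed_effect(np.arange(20.0), np.ones(20), np.repeat([0, 1], 10))
        assert res.chi2 == 0.0 and res.p_value == 1.0 and res.slope == 0.0

    def test_strong_slope_detected(self):
        rng = np.random.default_rng(9)
        n_sub, n_el = 8, 25
        subj = np.repeat(np.arange(n_sub), n_el)
        x = rng.standard_normal(subj.size)
        y = 0.5 * x + np.repeat(rng.normal(0, 0.3, n_sub), n_el) + rng.standard_normal(subj.size)
        res = _quiet(lrt_fixed_effect, y, x, subj)
        assert res.chi2 > 0
        assert res.p_value < 0.01
        assert res.slope == pytest.approx(0.5, abs=0.2)

    def test_statistic_nonnegative_under_null(self):
        rng = np.random.default_rng(10)
        subj = np.repeat(np.arange(6), 15)
        for rep in range(3):
            y = rng.standard_normal(90)
            x = rng.standard_normal(90)
            res = _quiet(lrt_fixed_effect, y, x, subj)
            assert res.chi2 >= 0.0


class TestQuartileAnova:
    def _drifting(self, slope, seed=0, n_sub=6, n_trial=80):
        rng = np.random.default_rng(seed)
        times = np.tile(np.linspace(0, 24 * 60, n_trial), n_sub)
        subj = np.repeat(np.arange(n_sub), n_trial)
        values = slope * (times / times.max()) + rng.standard_normal(times.size)
        return times, values, subj

    def test_identical_quartile_means_give_zero_f(self):
        times = np.tile(np.arange(8.0), 3)
        values = np.tile(np.repeat([1.0, 2.0], 4), 3)  # same pattern every subject
        values = np.tile([5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.0], 3)
        subj = np.repeat(np.arange(3), 8)
        f, p, _ = session_quartile_anova(times, values + subj.astype(float).repeat(1), subj)
        assert f == 0.0 and p == 1.0

    def test_matches_hand_rm_anova(self):
        """Oracle: statsmodels AnovaRM on the subject x quartile means."""
        times, values, subj = self._drifting(1.0, seed=3)
        f, p, table = session_quartile_anova(times, values, subj)
        import pandas as pd
        from statsmodels.stats.anova import AnovaRM

        long = table.reset_index().melt(
            id_vars="index", var_name="quartile", value_name="value"
        )
        res = AnovaRM(long, "value", "index", within=["quartile"]).fit()
        assert f == pytest.approx(float(res.anova_table["F Value"].iloc[0]))
        assert p == pytest.approx(float(res.anova_table["Pr > F"].iloc[0]))

    def test_linear_drift_detected(self):
        times, values, subj = self._drifting(2.0, seed=4)
        f, p, _ = session_quartile_anova(times, values, subj)
        assert p < 0.05

    def test_incomplete_subject_dropped_with_warning(self):
        times = np.concatenate([np.tile(np.arange(8.0), 2), np.arange(2.0)])
        values = np.concatenate([np.ones(16), np.zeros(2)])
        subj = np.concatenate([np.repeat([0, 1], 8), [2, 2]])
        values[:8] += 0.1 * np.arange(8)
        with pytest.warns(UserWarning, match="missing|span"):
            f, p, table = session_quartile_anova(times, values, subj)
        assert 2 not in table.index

    def test_needs_two_complete_subjects(self):
        with pytest.raises(ValueError, match="2 complete"):
            session_quartile_anova(np.arange(8.0), np.ones(8), np.zeros(8))
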