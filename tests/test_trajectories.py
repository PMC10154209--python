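import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from braakstager.loess import loess
from braakstager.trajectories import (
    AbnormalityScaler,
    StageTrajectorySmoother,
    build_domain_composites,
    fit_stage_trajectory,
    half_max_stage,
    scale_to_abnormality,
    zscore_to_reference,
)


def _brute_force_local_linear(x, y, x_eval, span):
    """Independent dense oracle: tricube-weighted np.polyfit per grid point."""
    n = x.size
    q = max(2, int(np.ceil(span * n)))
    out = np.empty(len(x_eval))
    for j, x0 in enumerate(x_eval):
        d = np.abs(x - x0)
        dq = np.sort(d)[q - 1]
        mask = d <= dq
        w = (1 - (d[mask] / dq) ** 3) ** 3 if dq > 0 else np.ones(mask.sum())
        coeffs = np.polyfit(x[mask], y[mask], deg=1, w=np.sqrt(np.clip(w, 1e-300, None)))
        out[j] = np.polyval(coeffs, x0)
    return out


class TestLoess:
    def test_linear_data_reproduces_ols_line(self):
        x = np.linspace(0, 6, 40)
        y = 2.0 * x + 1.0
        fit = loess(x, y, np.arange(7.0), span=1.0)
        np.testing.assert_allclose(fit.fitted, 2.0 * np.arange(7) + 1.0, atol=1e-6)

    def test_constant_values_give_constant_curve(self):
        x = np.repeat(np.arange(7.0), 3)
        y = np.full_like(x, 4.2)
        fit = loess(x, y, np.arange(7.0), span=0.75)
        np.testing.assert_allclose(fit.fitted, 4.2, atol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        x = np.sort(rng.uniform(0, 6, 60))
        y = np.sin(x) + rng.normal(0, 0.1, 60)
        grid = np.linspace(0.5, 5.5, 11)
        fit = loess(x, y, grid, span=0.6)
        oracle = _brute_force_local_linear(x, y, grid, span=0.6)
        np.testing.assert_allclose(fit.fitted, oracle, atol=1e-8)

    def test_noiseless_sigmoid_fit_is_monotone(self):
        x = np.repeat(np.arange(7.0), 5)
        y = 1 / (1 + np.exp(-(x - 3.0)))
        fit = loess(x, y, np.arange(7.0), span=0.75)
        assert np.all(np.diff(fit.fitted) >= -1e-3)

    def test_cross_check_against_statsmodels_lowess(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(4)
        x = np.sort(rng.uniform(0, 6, 80))
        y = 0.5 * x**2 + rng.normal(0, 0.3, 80)
        ours = loess(x, y, x, span=0.5).fitted
        theirs = statsmodels.nonparametric.lowess(y, x, frac=0.5, it=0, return_sorted=False)
        assert np.median(np.abs(ours - theirs)) < 0.05

    def test_single_populated_stage_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_stage_trajectory([1.0, 2.0, 3.0], [2, 2, 2])

    def test_band_widens_with_noise(self):
        rng = np.random.default_rng(1)
        x = np.repeat(np.arange(7.0), 10)
        quiet = loess(x, x + rng.normal(0, 0.01, x.size), np.arange(7.0))
        loud = loess(x, x + rng.normal(0, 1.0, x.size), np.arange(7.0))
        assert loud.se.mean() > quiet.se.mean()


class TestZscore:
    def test_reference_population_has_zero_mean_unit_sd(self, rng):
        values = rng.normal(10, 3, 100)
        mask = np.zeros(100, dtype=bool)
        mask[:40] = True
        z = zscore_to_reference(values, mask)
        assert z[mask].mean() == pytest.approx(0.0, abs=1e-12)
        assert z[mask].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_example(self):
        values = np.array([10.0, 8.0, 12.0, 13.0])
        mask = np.array([True, True, True, False])
        z = zscore_to_reference(values, mask)
        # reference mean 10, sd 2 -> z(13) = 1.5, by independent two-pass arithmetic
        assert z[3] == pytest.approx(1.5)

    def test_zero_reference_sd_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            zscore_to_reference(np.array([1.0, 1.0, 2.0]), np.array([True, True, False]))


class TestScaling:
    def test_already_scaled_values_unchanged(self):
        np.testing.assert_allclose(scale_to_abnormality([0.0, 5.0, 10.0]), [0, 5, 10])

    def test_two_point_minmax(self):
        np.testing.assert_allclose(scale_to_abnormality([2.0, 4.0]), [0, 10])

    def test_lower_is_abnormal_flips(self):
        scaled = scale_to_abnormality([1.0, 3.0, 5.0], direction="lower")
        assert scaled[0] == 10.0 and scaled[2] == 0.0

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            scale_to_abnormality([2.0, 2.0, 2.0])

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100))
    def test_zscore_then_scale_affine_invariant(self, a, b):
        rng = np.random.default_rng(0)
        raw = rng.normal(20, 4, 50)
        mask = np.zeros(50, dtype=bool)
        mask[:20] = True
        base = scale_to_abnormality(zscore_to_reference(raw, mask))
        transformed = scale_to_abnormality(zscore_to_reference(a * raw + b, mask))
        np.testing.assert_allclose(base, transformed, atol=1e-8)

    def test_scaler_estimator_roundtrip(self):
        scaler = AbnormalityScaler(direction="lower").fit([1.0, 3.0, 5.0])
        out = scaler.transform([1.0, 5.0])
        np.testing.assert_allclose(out, [10.0, 0.0])
        assert scaler.get_params() == {"direction": "lower"}


class TestComposites:
    def _frame(self):
        return pd.DataFrame(
            {
                "logical_memory_immediate": [10.0, 10.0, 12.0, 8.0],
                "logical_memory_delayed": [20.0, 22.0, 19.0, 21.0],
                "trails_b_time": [60.0, 80.0, 70.0, 90.0],
                "digit_span_backward": [7.0, 5.0, 6.0, 4.0],
            }
        )

    def test_reference_mean_scores_give_zero_composites(self):
        df = pd.DataFrame(
            {
                "logical_memory_immediate": [10.0, 12.0, 11.0],
                "logical_memory_delayed": [18.0, 22.0, 20.0],
            }
        )
        mask = np.array([True, True, False])
        comp = build_domain_composites(df, mask)
        assert comp["memory"].iloc[2] == pytest.approx(0.0)  # 11 and 20 are the ref means

    def test_opposite_z_scores_average_to_zero(self):
        df = pd.DataFrame(
            {
                "ravlt_immediate": [10.0, 14.0, 14.0],
                "ravlt_delayed": [10.0, 14.0, 10.0],
            }
        )
        mask = np.array([True, True, False])
        comp = build_domain_composites(df, mask)
        # subject 2: z = (+1, -1)/sqrt(2)-scaled pair with equal magnitude, mean 0
        assert comp["memory"].iloc[2] == pytest.approx(0.0)

    def test_slow_trails_b_lowers_executive_composite(self):
        df = self._frame()
        mask = np.array([True, True, True, False])
        comp = build_domain_composites(df, mask)
        # subject 3 is slower than the reference mean on trails-B and weaker
        # on digit span: composite must be negative
        assert comp["executive"].iloc[3] < 0

    def test_all_domain_tests_missing_gives_missing_composite(self):
        df = self._frame()
        df.loc[3, ["trails_b_time", "digit_span_backward"]] = np.nan
        mask = np.array([True, True, True, False])
        comp = build_domain_composites(df, mask)
        assert np.isnan(comp["executive"].iloc[3])


class TestSmootherEstimator:
    def test_fit_exposes_grid_curve_band(self, rng):
        stages = rng.integers(0, 7, 120)
        values = stages + rng.normal(0, 0.3, 120)
        sm = StageTrajectorySmoother(span=0.75).fit(stages, values)
        assert sm.grid_.shape == (7,)
        lo, hi = sm.band_
        assert np.all(lo <= sm.curve_) and np.all(sm.curve_ <= hi)
        np.testing.assert_allclose(sm.predict(sm.grid_), sm.curve_)


def test_cdr_stage_table_counts():
    from braakstager.trajectories import cdr_stage_table

    table = cdr_stage_table([0.0, 0.0, 0.5, 1.0], [0, 0, 3, 5])
    assert table.loc[0, 0.0] == 2
    assert table.loc[3, 0.5] == 1
    assert int(table.to_numpy().sum()) == 4


class TestHalfMax:
    def test_interpolated_crossing(self):
        grid = np.arange(7.0)
        curve = np.array([0, 0, 0, 2, 8, 10, 10.0])
        # dynamic range 0..10, half-max 5 crossed between stages 3 and 4
        assert 3 < half_max_stage(grid, curve) < 4

    def test_flat_curve_has_no_crossing(self):
        assert np.isnan(half_max_stage(np.arange(7.0), np.zeros(7)))
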