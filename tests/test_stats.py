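import numpy as np
import pytest
from scipy import stats as sps

from braakstager.stats import (
    assumption_diagnostics,
    brown_forsythe_anova,
    compare_positivity_proportions,
    compare_stages,
    compute_eyo,
    dunnett_contrasts,
    eyo_stage_association,
)


class TestBrownForsythe:
    def test_separated_groups_reject(self, rng):
        groups = [rng.normal(m, 1, 30) for m in (0, 0, 5)]
        res = brown_forsythe_anova(groups)
        assert res.pvalue < 1e-6

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2 observations"):
            brown_forsythe_anova([np.array([1.0]), np.array([1.0, 2.0])])

    def test_statistic_matches_hand_formula(self, rng):
        groups = [rng.normal(0, s, n) for s, n in ((1, 8), (2, 12), (0.5, 20))]
        res = brown_forsythe_anova(groups)
        n = np.array([g.size for g in groups])
        m = np.array([g.mean() for g in groups])
        v = np.array([g.var(ddof=1) for g in groups])
        grand = np.concatenate(groups).mean()
        expected = (n * (m - grand) ** 2).sum() / ((1 - n / n.sum()) * v).sum()
        assert res.statistic == pytest.approx(expected, rel=1e-12)


def test_assumption_diagnostics_flag_unequal_spread(rng):
    """Bartlett's test detects grossly unequal group s.d. values; the
    diagnostics are informational and never block the analysis."""
    groups = [rng.normal(0, 1, 40), rng.normal(0, 5, 40)]
    diag = assumption_diagnostics(groups)
    assert diag["bartlett_pvalue"] < 0.01
    assert len(diag["anderson_darling_statistics"]) == 2


class TestDunnett:
    def test_two_groups_degenerate_to_welch(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.7, 2, 17)
        res = dunnett_contrasts([a, b])
        welch = sps.ttest_ind(b, a, equal_var=False).pvalue
        assert abs(res["p_adjusted"].iloc[0] - welch) < 1e-6

    def test_adjusted_at_least_unadjusted(self, rng):
        groups = [rng.normal(0, 1, 15) for _ in range(5)]
        res = dunnett_contrasts(groups, n_mc=5_000, rng=np.random.default_rng(1))
        assert (res["p_adjusted"] >= res["p_unadjusted"] - 1e-12).all()

    def test_large_shift_detected_with_high_power(self):
        """A 3-s.d. shifted group (n=20/group) is flagged in nearly all replicates."""
        rng = np.random.default_rng(42)
        hits = 0
        reps = 200
        for _ in range(reps):
            groups = [rng.standard_normal(20) for _ in range(4)]
            groups.append(rng.normal(3.0, 1.0, 20))
            res = dunnett_contrasts(groups, n_mc=2_000, rng=np.random.default_rng(rng.integers(2**31)))
            hits += res["p_adjusted"].iloc[-1] < 0.05
        assert hits / reps >= 0.95

    def test_seeded_adjustment_reproducible(self, rng):
        groups = [rng.normal(m, 1, 10) for m in (0, 0.5, 1.0)]
        a = dunnett_contrasts(groups, rng=np.random.default_rng(7))
        b = dunnett_contrasts(groups, rng=np.random.default_rng(7))
        assert np.array_equal(a["p_adjusted"], b["p_adjusted"])


class TestCompareStages:
    def test_empty_reference_rejected(self, rng):
        values = rng.normal(size=20)
        stages = np.repeat([1, 2], 10)
        with pytest.raises(ValueError, match="stage 0"):
            compare_stages(values, stages)

    def test_contrast_index_is_stage(self, rng):
        values = np.concatenate([rng.normal(m, 1, 15) for m in (0, 1, 3)])
        stages = np.repeat([0, 2, 4], 15)
        res = compare_stages(values, stages, n_mc=2_000, rng=np.random.default_rng(0))
        assert list(res.contrasts.index) == [2, 4]
        assert res.contrasts.loc[4, "estimate"] > res.contrasts.loc[2, "estimate"]


class TestProportions:
    def test_identical_proportions_give_zero_chi2(self):
        status = np.array([True] * 5 + [False] * 5 + [True] * 5 + [False] * 5)
        stages = np.repeat([0, 1], 10)
        res = compare_positivity_proportions(status, stages, [(0, 1)])
        assert res["chi2"].iloc[0] == pytest.approx(0.0)
        assert res["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_perfect_separation_chi2_is_twenty(self):
        status = np.array([True] * 10 + [False] * 10)
        stages = np.repeat([0, 1], 10)
        res = compare_positivity_proportions(status, stages, [(0, 1)])
        assert res["chi2"].iloc[0] == pytest.approx(20.0, abs=1e-12)

    def test_zero_margin_suggests_exact_test(self):
        status = np.array([True] * 10)
        stages = np.repeat([0, 1], 5)
        with pytest.raises(ValueError, match="exact test"):
            compare_positivity_proportions(status, stages, [(0, 1)])

    def test_null_rejection_rate_near_alpha(self):
        """Independence-generated 2x2 tables reject at roughly the nominal rate."""
        rng = np.random.default_rng(3)
        rejections = 0
        reps = 2_000
        for _ in range(reps):
            status = rng.random(80) < 0.5
            stages = np.repeat([0, 1], 40)
            try:
                res = compare_positivity_proportions(status, stages, [(0, 1)])
            except ValueError:
                continue
            rejections += res["pvalue"].iloc[0] < 0.05
        assert 0.03 < rejections / reps < 0.07


class TestEyo:
    @pytest.mark.parametrize("age,onset,expected", [(40, 45, -5), (45, 45, 0), (50, 45, 5)])
    def test_arithmetic(self, age, onset, expected):
        assert compute_eyo(age, onset) == expected

    def test_missing_parental_onset_propagates(self):
        out = compute_eyo(np.array([40.0, 50.0]), np.array([np.nan, 45.0]))
        assert np.isnan(out[0]) and out[1] == 5.0

    def test_perfect_ordering_gives_rho_one(self):
        stages = np.arange(7)
        eyo = np.linspace(-10, 5, 7)
        rho, p = eyo_stage_association(eyo, stages, n_permutations=500, rng=np.random.default_rng(0))
        assert rho == pytest.approx(1.0)
        assert p < 0.01

    def test_reversed_ordering_gives_rho_minus_one(self):
        stages = np.arange(7)
        eyo = np.linspace(5, -10, 7)
        rho, _ = eyo_stage_association(eyo, stages, n_permutations=200, rng=np.random.default_rng(0))
        assert rho == pytest.approx(-1.0)

    def test_constant_stage_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            eyo_stage_association([1.0, 2.0, 3.0], [2, 2, 2])
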