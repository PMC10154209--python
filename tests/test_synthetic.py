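import numpy as np
import pandas as pd
import pytest

import braakstager as bs
from braakstager.synthetic import GeneratorConfig, _composite_means


class TestCalibrationSample:
    def test_same_seed_identical_tables(self, small_config):
        a = bs.generate_calibration_sample(small_config)
        b = bs.generate_calibration_sample(small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_large_sample_means_match_config(self):
        cfg = GeneratorConfig(seed=5)
        df = bs.generate_calibration_sample(cfg, n=1000)
        suvr = df[[f"suvr_braak{i}" for i in range(1, 7)]].to_numpy()
        se = cfg.baseline_suvr_sd / np.sqrt(1000)
        assert np.all(np.abs(suvr.mean(axis=0) - cfg.baseline_suvr_mean) < 3 * se)

    def test_zero_noise_collapses_to_mean(self):
        cfg = GeneratorConfig(seed=5, baseline_suvr_sd=0.0)
        df = bs.generate_calibration_sample(cfg, n=10)
        suvr = df[[f"suvr_braak{i}" for i in range(1, 7)]].to_numpy()
        assert np.all(suvr == cfg.baseline_suvr_mean)

    def test_single_record_rejected(self, small_config):
        with pytest.raises(ValueError, match="n >= 2"):
            bs.generate_calibration_sample(small_config, n=1)


class TestCrossSection:
    def test_reproducible_and_schema_complete(self, small_config, small_cohort):
        again = bs.generate_cross_section(small_config)
        pd.testing.assert_frame_equal(small_cohort, again)
        for col in ("suvr_braak1", "suvr_meta_roi", "suvr_amyloid", "csf_ptau217",
                    "mmse", "cdr", "true_stage", "true_amyloid_positive"):
            assert col in small_cohort.columns

    def test_truth_columns_hidden_from_pipeline_view(self, small_cohort):
        view = bs.pipeline_view(small_cohort)
        assert "true_stage" not in view.columns
        assert "true_amyloid_positive" not in view.columns

    def test_hierarchical_construction_means_are_prefix(self):
        cfg = GeneratorConfig(seed=1)
        stages = np.arange(7)
        means = _composite_means(cfg, stages)
        for t in range(7):
            affected = means[t] > cfg.baseline_suvr_mean
            assert list(affected) == [s < t for s in range(6)]

    def test_composite_mean_larger_once_stage_reached(self):
        cfg = GeneratorConfig(seed=1)
        means = _composite_means(cfg, np.arange(7))
        for s in range(1, 7):
            below = means[:s, s - 1]
            at_or_after = means[s:, s - 1]
            assert at_or_after.min() > below.max()

    def test_low_noise_patterns_all_conformant(self):
        """With jitter 0 and noise far below the regime separation, every
        generated positivity pattern is a prefix pattern: the generator's
        construction is hierarchical."""
        cfg = GeneratorConfig(
            seed=9, n_cu=40, n_mci=20, n_ad=15,
            baseline_suvr_sd=0.01, abnormal_suvr_sd=0.01,
        )
        # threshold placed between the unaffected and abnormal regimes
        t = np.full(6, (cfg.baseline_suvr_mean + cfg.abnormal_suvr_mean) / 2)
        cutoffs = bs.StageCutoffs(t, 0.0, 2, t, np.zeros(6))
        cohort = bs.generate_cross_section(cfg)
        assignments = [
            bs.assign_stage(row, cutoffs)
            for row in cohort[[f"suvr_braak{i}" for i in range(1, 7)]].to_numpy()
        ]
        assert all(a.conformant for a in assignments)
        stages = np.array([a.stage for a in assignments])
        assert np.array_equal(stages, cohort["true_stage"].to_numpy())

    def test_degenerate_prior_stages_everyone_six(self):
        prior = [0, 0, 0, 0, 0, 0, 1.0]
        cfg = GeneratorConfig(
            seed=2, n_cu=20, n_mci=0, n_ad=0,
            baseline_suvr_sd=0.01, abnormal_suvr_sd=0.01, n_calibration=30,
            stage_prior_by_dx={"CU": prior, "MCI": prior, "AD": prior},
        )
        cal = bs.generate_calibration_sample(cfg)
        cohort = bs.generate_cross_section(cfg)
        stages = bs.BraakStager().fit(cal).predict(cohort)
        assert np.all(stages == 6)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError, match="prior"):
            GeneratorConfig(seed=1, stage_prior_by_dx={"CU": [1.0], "MCI": [1.0], "AD": [1.0]})


class TestLongitudinal:
    def test_identity_kernel_keeps_stages(self, small_cohort):
        cfg = GeneratorConfig(
            seed=123, n_cu=60, n_mci=25, n_ad=20,
            stay_prob=1.0, advance_prob=0.0, regress_prob=0.0,
            n_followup_1y=40, n_followup_2y=25, n_followup_both=15,
        )
        fu = bs.generate_longitudinal(cfg, small_cohort)
        truth = small_cohort.set_index("subject_id")["true_stage"]
        assert np.array_equal(
            fu["true_stage"].to_numpy(), truth.loc[fu["subject_id"]].to_numpy()
        )

    def test_followup_design_counts(self, small_config, small_cohort):
        fu = bs.generate_longitudinal(small_config, small_cohort)
        counts = fu["visit"].value_counts()
        assert counts["year1"] == small_config.n_followup_1y
        assert counts["year2"] == small_config.n_followup_2y
        both = set(fu.loc[fu.visit == "year1", "subject_id"]) & set(
            fu.loc[fu.visit == "year2", "subject_id"]
        )
        assert len(both) == small_config.n_followup_both

    def test_amyloid_negative_never_advance_past_gate(self):
        cfg = GeneratorConfig(
            seed=77, n_cu=300, n_mci=300, n_ad=300,
            amyloid_p_pos_by_stage=[0.5] * 7,  # plenty of Abeta- at high stages
            n_followup_1y=900, n_followup_2y=0, n_followup_both=0,
        )
        cohort = bs.generate_cross_section(cfg)
        fu = bs.generate_longitudinal(cfg, cohort)
        truth = cohort.set_index("subject_id")
        base = truth.loc[fu["subject_id"], "true_stage"].to_numpy()
        apos = truth.loc[fu["subject_id"], "true_amyloid_positive"].to_numpy()
        progressed = fu["true_stage"].to_numpy() > base
        gated = (~apos) & (base >= cfg.gate_stage)
        assert gated.sum() > 0  # the stratum exists
        assert progressed[gated].sum() == 0

    def test_missing_truth_columns_rejected(self, small_config, small_cohort):
        with pytest.raises(ValueError, match="ground-truth"):
            bs.generate_longitudinal(small_config, bs.pipeline_view(small_cohort))

    def test_seeded_reproducibility_including_csv_bytes(self, small_config, small_cohort, tmp_path):
        a = bs.generate_longitudinal(small_config, small_cohort)
        b = bs.generate_longitudinal(small_config, small_cohort)
        pd.testing.assert_frame_equal(a, b)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.to_csv(pa, index=False)
        b.to_csv(pb, index=False)
        assert pa.read_bytes() == pb.read_bytes()
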