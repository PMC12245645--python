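"""Folds, metrics, curation, baseline inputs, balanced sampling, pipelines."""

import numpy as np
import pytest

from paoxi.core import SampleRecord, SpectralImage, StudyDataset
from paoxi.evaluation import (
    BaselineVariant,
    assemble_baseline_input,
    classify_and_score,
    curation_check,
    loso_folds,
    regression_metrics,
    run_full_pipeline,
    sample_balanced_batch,
    train_baseline,
)
from paoxi.oximetry import ROIParams, UnmixConfig
from paoxi.phantom import attenuation_model


class TestFolds:
    def test_ten_subjects_ten_folds(self):
        ds = StudyDataset([], [f"S{i}" for i in range(10)])
        folds = loso_folds(ds)
        assert len(folds) == 10

    def test_partition_property(self, small_study):
        folds = loso_folds(small_study)
        held = [f.held_out_subject for f in folds]
        assert sorted(held) == sorted(small_study.subjects)
        for f in folds:
            assert f.held_out_subject not in f.train_subjects
            assert set(f.train_subjects) | {f.held_out_subject} == set(small_study.subjects)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            loso_folds(StudyDataset([], ["only"]))


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m["r_squared"] == pytest.approx(1.0)
        assert m["slope"] == pytest.approx(1.0)
        assert m["intercept"] == pytest.approx(0.0)

    def test_hand_ols(self):
        m = regression_metrics([2.0, 12.0, 22.0], [0.0, 10.0, 20.0])
        assert m["slope"] == pytest.approx(1.0)
        assert m["intercept"] == pytest.approx(2.0)
        assert m["r_squared"] == pytest.approx(1.0)

    def test_constant_prediction_r2_zero(self):
        m = regression_metrics([10.0, 10.0, 10.0], [0.0, 10.0, 20.0])
        assert m["r_squared"] == 0.0
        assert m["slope"] == 0.0

    def test_zero_variance_gt_flagged(self):
        m = regression_metrics([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert np.isnan(m["r_squared"])


class TestClassification:
    def test_strict_boundary(self):
        m = classify_and_score([29.9, 30.0], [29.9, 30.0])
        assert m["tp"] == 1 and m["tn"] == 1 and m["fp"] == 0 and m["fn"] == 0

    def test_confusion_ratios(self):
        # 46 true hypoxia detected, 8 missed, 28 normoxia kept, 2 false alarms
        gts = [20.0] * 54 + [50.0] * 30
        preds = [20.0] * 46 + [40.0] * 8 + [50.0] * 28 + [10.0] * 2
        m = classify_and_score(preds, gts)
        assert m["sensitivity"] == pytest.approx(46 / 54, abs=1e-12)
        assert m["specificity"] == pytest.approx(28 / 30, abs=1e-12)
        assert round(m["sensitivity"], 3) == 0.852
        assert round(m["specificity"], 3) == 0.933

    def test_perfect(self):
        m = classify_and_score([10.0, 50.0], [10.0, 50.0])
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0

    def test_missing_class_flagged(self):
        m = classify_and_score([50.0, 60.0], [50.0, 60.0])
        assert np.isnan(m["sensitivity"])
        assert m["specificity"] == 1.0


class TestCuration:
    def _sample(self, o2):
        img = SpectralImage(np.ones((21, 8, 8)))
        return SampleRecord(img, "S", 1.0, o2, (2, 2))

    def test_healthy_start_passes(self):
        ok, _ = curation_check([self._sample(45.0), self._sample(20.0)])
        assert ok

    def test_hypoxic_start_flagged(self):
        ok, reason = curation_check([self._sample(22.0), self._sample(45.0)])
        assert not ok and "below" in reason

    def test_empty_subject_flagged(self):
        ok, reason = curation_check([])
        assert not ok and "no samples" in reason


@pytest.fixture(scope="module")
def study_cfg(small_study):
    from paoxi.phantom import PhantomConfig

    cfg = PhantomConfig(image_h=32, image_w=48, sss_depth_mm=6.0,
                        sss_depth_jitter_mm=1.0, skin_band_depth_px=2,
                        curvature_rise_mm=2.0)
    return UnmixConfig(compensation=attenuation_model(cfg), region_h=16, region_w=20)


class TestBaselineInputs:
    def test_channel_counts(self, small_study, study_cfg):
        s = small_study.samples[0]
        assert assemble_baseline_input(s, BaselineVariant("M1")).shape[0] == 21
        assert assemble_baseline_input(s, BaselineVariant("M2"), cfg=study_cfg).shape[0] == 1
        assert assemble_baseline_input(s, BaselineVariant("M3"), cfg=study_cfg).shape[0] == 22

    def test_m4_patch_shape(self, small_study, study_cfg):
        s = small_study.samples[0]
        out = assemble_baseline_input(s, BaselineVariant("M4"), cfg=study_cfg)
        assert out.shape == (22, 20, 20)

    def test_m2_zero_outside_window(self, small_study, study_cfg):
        s = small_study.samples[0]
        out = assemble_baseline_input(s, BaselineVariant("M2"), cfg=study_cfg)[0]
        x, y = s.sss_xy
        h, w = out.shape
        outside = np.ones_like(out, dtype=bool)
        y0, x0 = max(0, y - 8), max(0, x - 10)
        outside[y0:y0 + 16, x0:x0 + 20] = False
        assert np.all(out[outside] == 0)

    def test_m1_needs_no_annotation(self, small_study):
        out = assemble_baseline_input(small_study.samples[0], BaselineVariant("M1"))
        assert out.min() >= 0 and out.max() <= 1

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            BaselineVariant("M5")


class TestBalancedSampling:
    def test_frequency_near_half(self):
        y = np.array([10.0] * 70 + [50.0] * 30)  # 70% hypoxic
        rng = np.random.default_rng(0)
        idx = sample_balanced_batch(y, 10000, rng)
        frac_hyp = np.mean(y[idx] < 30)
        assert frac_hyp == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            sample_balanced_batch(np.array([10.0, 12.0]), 4, np.random.default_rng(0))


class TestBaselineTraining:
    def test_loss_decreases(self, small_study, study_cfg):
        reg = train_baseline(BaselineVariant("M4"), small_study.samples, study_cfg,
                             epochs=30, learning_rate=1e-3, seed=0)
        assert reg.loss_history_[-1] < reg.loss_history_[0]

    def test_zero_epochs_returns_untrained(self, small_study, study_cfg):
        reg = train_baseline(BaselineVariant("M4"), small_study.samples, study_cfg,
                             epochs=0, seed=0)
        assert reg.loss_history_ == []


class TestPipeline:
    def test_gt_mode_noiseless_recovers(self, noiseless_study, matched_unmix_cfg):
        roi = ROIParams(a=0, b=0, c=4, d=4, sigma=1.0)
        m = run_full_pipeline(noiseless_study, "gt", matched_unmix_cfg, roi=roi)
        assert m.r_squared > 0.99
        assert m.n_failed == 0
        assert len(m.predictions) == len(noiseless_study)

    def test_fold_count_equals_subject_count(self, noiseless_study, matched_unmix_cfg):
        roi = ROIParams(a=0, b=0, c=4, d=4, sigma=1.0)
        m = run_full_pipeline(noiseless_study, "gt", matched_unmix_cfg, roi=roi)
        assert m.predictions["fold"].nunique() == len(noiseless_study.subjects)

    def test_each_sample_used_once(self, noiseless_study, matched_unmix_cfg):
        roi = ROIParams(a=0, b=0, c=4, d=4, sigma=1.0)
        m = run_full_pipeline(noiseless_study, "gt", matched_unmix_cfg, roi=roi)
        assert len(m.predictions) == len(noiseless_study.samples)

    def test_unknown_mode_rejected(self, noiseless_study, matched_unmix_cfg):
        with pytest.raises(ValueError):
            run_full_pipeline(noiseless_study, "M9", matched_unmix_cfg)

    def test_two_step_mode_runs_end_to_end(self, small_study, study_cfg):
        roi = ROIParams(a=0, b=0, c=3, d=3, sigma=1.0)
        m = run_full_pipeline(
            small_study, "two-step", study_cfg, roi=roi, seed=1,
            localizer_kwargs=dict(levels=2, base_features=4, epochs=1,
                                  learning_rate=1e-3, dropout_p=0.2))
        assert len(m.predictions) == len(small_study.samples)
        # an untrained-ish localiser may read anywhere, but the plumbing must
        # deliver a numeric or flagged reading for every sample
        assert m.predictions["pred"].notna().sum() + m.n_failed == len(m.predictions)

    def test_roi_readout_beats_end_to_end_regression(self, small_study, study_cfg):
        # the anatomy-guided ROI readout tracks the blood-gas truth far
        # better than a briefly trained whole-image CNN regressor
        roi = ROIParams(a=0, b=0, c=3, d=3, sigma=1.0)
        two_step = run_full_pipeline(small_study, "gt", study_cfg, roi=roi)
        m1 = run_full_pipeline(small_study, "M1", study_cfg, roi=roi, seed=0,
                               baseline_kwargs=dict(epochs=20, learning_rate=1e-3))
        assert two_step.r_squared > m1.r_squared
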