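import dataclasses

import numpy as np
import pandas as pd
import pytest

from mmcurate import agreement, postprocess, scoring
from mmcurate.schema import UNSPECIFIED
from mmcurate.simulate import (AccuracyCoeffs, CorruptionConfig,
                               DEFAULT_IRR_TARGETS, ScenarioConfig,
                               calibrate_disagreement, crossing_scenario,
                               simulate_annotators, simulate_corpus,
                               simulate_timeline_events, substream,
                               workflow_accuracy, _simulate_field_irr)


class TestDeterminism:
    def test_identical_config_and_seed_reproduce_bundle(self, small_cfg):
        b1 = simulate_corpus(small_cfg, seed=11)
        b2 = simulate_corpus(small_cfg, seed=11)
        pd.testing.assert_frame_equal(b1.truth, b2.truth)
        pd.testing.assert_frame_equal(b1.annotator_a, b2.annotator_a)
        pd.testing.assert_frame_equal(b1.notes, b2.notes)
        assert b1.payloads == b2.payloads

    def test_different_seed_differs(self, small_cfg):
        b1 = simulate_corpus(small_cfg, seed=11)
        b2 = simulate_corpus(small_cfg, seed=12)
        assert not b1.truth["value"].equals(b2.truth["value"])

    def test_timeline_stream_deterministic(self, small_cfg):
        e1, i1 = simulate_timeline_events(small_cfg, seed=4)
        e2, i2 = simulate_timeline_events(small_cfg, seed=4)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(i1, i2)


class TestCorpus:
    def test_even_split_into_dev_and_test(self, default_result):
        notes = default_result.bundle.notes
        assert len(notes) == 250
        assert (notes["split"] == "dev").sum() == 125
        assert (notes["split"] == "test").sum() == 125

    def test_point_mass_prior(self):
        cfg = ScenarioConfig(
            n_patients=20,
            class_priors={"mm_status": {"Remission": 1.0}})
        bundle = simulate_corpus(cfg, seed=1)
        vals = bundle.truth.loc[bundle.truth.field_id == "mm_status", "value"]
        assert (vals == "Remission").all()

    def test_invalid_priors_rejected(self):
        cfg = ScenarioConfig(class_priors={"mm_status": {"Remission": 0.5}})
        with pytest.raises(ValueError):
            simulate_corpus(cfg, seed=0)

    def test_sparse_field_excluded_in_pipeline(self, default_result):
        assert len(default_result.retained_catalog) == 12
        assert default_result.excluded_fields[0][0] == "flt_response_date"


class TestAnnotators:
    def test_zero_rate_copies_truth(self, catalog, small_cfg):
        bundle_truth = simulate_corpus(small_cfg, seed=2).truth
        a, b, arb = simulate_annotators(
            bundle_truth, {s.field_id: 0.0 for s in catalog}, catalog, seed=2)
        assert a["value"].tolist() == bundle_truth["value"].tolist()
        assert b["value"].tolist() == bundle_truth["value"].tolist()

    def test_unit_rate_never_matches_truth(self, catalog, small_cfg):
        truth = simulate_corpus(small_cfg, seed=2).truth
        a, _, _ = simulate_annotators(
            truth, {"mm_status": 1.0}, catalog, seed=2)
        mask = truth.field_id == "mm_status"
        assert (a.loc[mask, "value"].to_numpy()
                != truth.loc[mask, "value"].to_numpy()).all()

    def test_invalid_rate_rejected(self, catalog, small_cfg):
        truth = simulate_corpus(small_cfg, seed=2).truth
        with pytest.raises(ValueError):
            simulate_annotators(truth, {"mm_status": 1.5}, catalog, seed=2)


class TestCalibration:
    def test_bisection_hits_irr_target(self, by_id):
        """Calibrated rate reproduces IRR-F1 0.8 within ±0.02 at n=125."""
        spec = by_id["transplant_status"]
        rate = calibrate_disagreement(spec, 0.80, n=125, seed=21)
        cfg = ScenarioConfig()
        achieved = np.mean([
            _simulate_field_irr(spec, rate, cfg, cfg.priors(), 125,
                                substream(77, "calibration", extra=k), "irr_f1")
            for k in range(64)])
        assert achieved == pytest.approx(0.80, abs=0.02)

    @pytest.mark.parametrize("target", [0.55, 0.75, 0.95])
    def test_converges_across_target_range(self, by_id, target):
        spec = by_id["mm_status"]
        cfg = ScenarioConfig()
        rate = calibrate_disagreement(spec, target, n=125, seed=5,
                                      reps=24, iters=16)
        achieved = np.mean([
            _simulate_field_irr(spec, rate, cfg, cfg.priors(), 125,
                                substream(88, "calibration", extra=k), "irr_f1")
            for k in range(48)])
        assert achieved == pytest.approx(target, abs=0.03)

    def test_alpha_calibration_to_acceptable_agreement(self, catalog):
        """Fields calibrated to alpha 0.8 average within ±0.05 at n=125."""
        cfg = ScenarioConfig()
        priors = cfg.priors()
        fields = [s for s in catalog if s.field_id != "flt_response_date"]
        achieved = []
        for spec in fields:
            rate = calibrate_disagreement(spec, 0.80, metric="alpha", n=125,
                                          reps=16, iters=14, seed=31,
                                          cfg=cfg, priors=priors)
            vals = [_simulate_field_irr(spec, rate, cfg, priors, 125,
                                        substream(99, "calibration", extra=k),
                                        "alpha") for k in range(8)]
            achieved.append(np.nanmean(vals))
        assert np.mean(achieved) == pytest.approx(0.80, abs=0.05)

    def test_default_rates_reproduce_difficulty_ladder(self, default_result):
        irr = default_result.bundle.irr_by_field
        for fid, target in DEFAULT_IRR_TARGETS.items():
            assert irr[fid] == pytest.approx(target, abs=0.07)


class TestExtractor:
    def test_high_accuracy_no_corruption_scores_high(self, catalog):
        cfg = ScenarioConfig(
            n_patients=250,
            coeffs=AccuracyCoeffs(a0=0.99, a_irr=0.0, a_size=0.0, a_prompt=0.0,
                                  type_effects={}),
            corruption=CorruptionConfig(malformed_json=0.0, out_of_range=0.0,
                                        brand_name=0.0, bad_date=0.0),
            workflows=("70B-CoT",))
        bundle = simulate_corpus(cfg, seed=9)
        assert (bundle.accuracy.to_numpy() == 0.99).all()
        preds = postprocess.postprocess_payloads(bundle.payloads, catalog,
                                                 period=cfg.period)
        table = scoring.score_workflows(preds, bundle.truth, catalog)
        f1 = scoring.primary_f1(table)
        # scored F1 tracks the closed-form expected accuracy
        assert f1["f1"].mean() == pytest.approx(0.99, abs=0.05)
        exact = (preds.set_index(["note_id", "field_id"])["value"]
                 == bundle.truth.set_index(["note_id", "field_id"])["value"])
        assert exact.mean() == pytest.approx(0.99, abs=0.01)

    def test_total_malformation_without_repairs_yields_unspecified(self, catalog):
        cfg = ScenarioConfig(
            n_patients=20,
            corruption=CorruptionConfig(malformed_json=1.0,
                                        malformed_kind_weights=(0, 0, 1)),
            workflows=("8B-ZSL",))
        bundle = simulate_corpus(cfg, seed=3)
        preds = postprocess.postprocess_payloads(bundle.payloads, catalog,
                                                 max_attempts=1,
                                                 period=cfg.period)
        assert (preds["value"] == UNSPECIFIED).all()
        assert (preds["status"] == "failed").all()

    def test_accuracy_model_coefficients(self):
        irr = {"f": 0.7}
        from mmcurate.schema import FieldSpec
        spec = FieldSpec("f", "c", "binary", ("Yes", "No", UNSPECIFIED))
        acc = workflow_accuracy(irr, ("8B-ZSL", "70B-ZSL", "8B-CoT", "70B-CoT"),
                                AccuracyCoeffs(), [spec])
        base = -0.10 + 1.0 * 0.7 + 0.04  # a0 + irr + binary offset
        assert acc.loc["f", "8B-ZSL"] == pytest.approx(base)
        assert acc.loc["f", "70B-ZSL"] == pytest.approx(base + 0.13)
        assert acc.loc["f", "8B-CoT"] == pytest.approx(base + 0.08)
        assert acc.loc["f", "70B-CoT"] == pytest.approx(base + 0.21)

    def test_accuracy_clipped(self):
        from mmcurate.schema import FieldSpec
        spec = FieldSpec("f", "c", "binary", ("Yes", "No", UNSPECIFIED))
        acc = workflow_accuracy({"f": 1.0}, ("70B-CoT",),
                                AccuracyCoeffs(a0=0.5), [spec])
        assert acc.loc["f", "70B-CoT"] == 0.99


class TestCrossingScenario:
    def test_zsl_slope_steeper_and_crossing_in_range(self):
        from mmcurate.pipeline import run_pipeline
        res = run_pipeline(crossing_scenario(), seed=3)
        fits = res.trend["fits"].set_index("workflow_id")
        assert fits.loc["70B-ZSL", "slope"] > fits.loc["70B-CoT", "slope"]
        assert fits.loc["8B-ZSL", "slope"] > fits.loc["8B-CoT", "slope"]
        cross = res.trend["crossings"]
        pair = cross[(cross.workflow_a == "70B-CoT")
                     & (cross.workflow_b == "70B-ZSL")]
        assert len(pair) == 1
        assert 0.6 <= pair.iloc[0]["irr_at_crossing"] <= 0.9


class TestTimelineStream:
    def test_newly_diagnosed_clusters_at_index(self, default_result):
        summary = default_result.timeline_summary
        s = summary.set_index("label")
        assert abs(s.loc["Newly diagnosed", "median_offset"]) < \
            abs(s.loc["Relapsed", "median_offset"])
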