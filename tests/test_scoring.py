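import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mmcurate.schema import UNSPECIFIED
from mmcurate.scoring import (DATE_BUFFERS, field_f1, macro_f1, primary_f1,
                              score_workflows, spearman_rho,
                              weighted_f1_dates, wide_matrix)


class TestMacroF1:
    def test_perfect(self):
        assert macro_f1(["A", "B", "A"], ["A", "B", "A"]) == 1.0

    def test_hand_confusion_matrix(self):
        # F1(A) = 2/3 (1 TP, 1 FP, 0 FN); F1(B) = 4/5 (2 TP, 0 FP, 1 FN)
        val = macro_f1(["A", "A", "B", "B"], ["A", "B", "B", "B"])
        assert val == pytest.approx((2 / 3 + 4 / 5) / 2)

    def test_no_true_positives(self):
        assert macro_f1([UNSPECIFIED] * 3, ["A"] * 3) == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            macro_f1([], [])

    @settings(derandomize=True, max_examples=60)
    @given(data=st.data())
    def test_invariant_under_label_permutation(self, data):
        labels = ["A", "B", "C"]
        n = data.draw(st.integers(3, 12))
        pred = data.draw(st.lists(st.sampled_from(labels), min_size=n, max_size=n))
        truth = data.draw(st.lists(st.sampled_from(labels), min_size=n, max_size=n))
        perm = data.draw(st.permutations(labels))
        mapping = dict(zip(labels, perm))
        base = macro_f1(pred, truth)
        mapped = macro_f1([mapping[p] for p in pred], [mapping[t] for t in truth])
        assert base == pytest.approx(mapped, abs=1e-12)


def _pairs(items):
    return [(lbl, dt.date.fromisoformat(d) if d else None) for lbl, d in items]


class TestWeightedDateF1:
    def test_exact_match_any_buffer(self):
        p = _pairs([("Date", "2020-01-05")])
        assert weighted_f1_dates(p, p, 0) == 1.0
        assert weighted_f1_dates(p, p, 180) == 1.0

    def test_within_buffer_counts(self):
        pred = _pairs([("Date", "2020-01-10")])
        truth = _pairs([("Date", "2020-01-05")])
        assert weighted_f1_dates(pred, truth, 7) == 1.0
        assert weighted_f1_dates(pred, truth, 0) == 0.0

    def test_unspecified_class_scored(self):
        pred = _pairs([("Date", "2020-01-10"), (UNSPECIFIED, None)])
        truth = _pairs([("Date", "2020-01-10"), (UNSPECIFIED, None)])
        assert weighted_f1_dates(pred, truth, 7) == 1.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            weighted_f1_dates([], [], 7)

    @settings(derandomize=True, max_examples=40)
    @given(seed=st.integers(0, 10_000))
    def test_monotone_in_buffer(self, seed):
        rng = np.random.default_rng(seed)
        base = dt.date(2020, 6, 1)
        def draw():
            out = []
            for _ in range(12):
                if rng.random() < 0.25:
                    out.append((UNSPECIFIED, None))
                else:
                    out.append(("Date", base + dt.timedelta(
                        days=int(rng.integers(-200, 200)))))
            return out
        pred, truth = draw(), draw()
        vals = [weighted_f1_dates(pred, truth, b) for b in (0,) + DATE_BUFFERS]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))


class TestSpearman:
    def test_identity(self):
        assert spearman_rho([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_reversed(self):
        assert spearman_rho([4, 3, 2, 1], [1, 2, 3, 4]) == pytest.approx(-1.0)

    def test_ties_match_pearson_on_ranks(self):
        pred = [1.0, 2.0, 2.0, 3.0, 5.0]
        truth = [2.0, 1.0, 4.0, 4.0, 5.0]
        expected = stats.pearsonr(stats.rankdata(pred),
                                  stats.rankdata(truth)).statistic
        assert spearman_rho(pred, truth) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_not_computable(self):
        assert np.isnan(spearman_rho([1, 1, 1], [1, 2, 3]))


class TestDrugSetScoring:
    def test_exact_set_mode(self, by_id):
        spec = by_id["flt_regimen"]
        pred = ["bortezomib|lenalidomide", UNSPECIFIED]
        truth = ["bortezomib|lenalidomide", UNSPECIFIED]
        assert field_f1(pred, truth, spec) == 1.0

    def test_per_ingredient_mode_partial_credit(self, by_id):
        spec = by_id["flt_regimen"]
        pred = ["bortezomib|dexamethasone"]
        truth = ["bortezomib|lenalidomide"]
        assert field_f1(pred, truth, spec) == 0.0  # exact-set: miss
        micro = field_f1(pred, truth, spec, drug_mode="per-ingredient")
        assert micro == pytest.approx(0.5)  # 1 TP, 1 FP, 1 FN


def _label_table(rows):
    return pd.DataFrame(rows, columns=["note_id", "patient_id", "field_id",
                                       "source", "value"]).astype(object)


class TestScoreWorkflows:
    def _tables(self, by_id):
        notes = [f"N{i}" for i in range(6)]
        statuses = ["Relapsed", "Remission", "Newly diagnosed",
                    "Relapsed", "Refractory", "Remission"]
        dates = ["2021-01-01", UNSPECIFIED, "2021-03-01",
                 "2021-04-01", "2021-05-01", UNSPECIFIED]
        ref, preds = [], []
        for n, s, d in zip(notes, statuses, dates):
            ref += [(n, "P", "mm_status", "consensus", s),
                    (n, "P", "mm_diagnosis_date", "consensus", d)]
            for wf in ("8B-ZSL", "70B-CoT"):
                preds += [(n, "P", "mm_status", wf, s),
                          (n, "P", "mm_diagnosis_date", wf, d)]
        return _label_table(preds), _label_table(ref)

    def test_perfect_predictions_score_one(self, by_id, catalog):
        preds, ref = self._tables(by_id)
        table = score_workflows(preds, ref, catalog)
        f1_rows = table[table.metric_name.isin(["macro_f1", "weighted_f1"])]
        assert (f1_rows["value"] == 1.0).all()
        # date field scored at every buffer, plus spearman
        date_rows = table[(table.field_id == "mm_diagnosis_date")
                          & (table.workflow_id == "8B-ZSL")]
        assert sorted(date_rows[date_rows.metric_name == "weighted_f1"]
                      .buffer_days) == sorted(DATE_BUFFERS)
        assert "spearman_rho" in set(date_rows.metric_name)

    def test_unknown_field_rejected(self, catalog):
        preds = _label_table([("N1", "P", "bogus", "wf", "x")])
        ref = _label_table([("N1", "P", "bogus", "consensus", "x")])
        with pytest.raises(KeyError):
            score_workflows(preds, ref, catalog)

    def test_deterministic(self, by_id, catalog):
        preds, ref = self._tables(by_id)
        t1 = score_workflows(preds, ref, catalog)
        t2 = score_workflows(preds, ref, catalog)
        pd.testing.assert_frame_equal(t1, t2)

    def test_primary_f1_and_wide_matrix_shapes(self, by_id, catalog):
        preds, ref = self._tables(by_id)
        table = score_workflows(preds, ref, catalog)
        f1 = primary_f1(table)
        assert set(f1.columns) == {"workflow_id", "field_id", "f1", "n"}
        assert len(f1) == 4  # 2 workflows x 2 fields
        wm = wide_matrix(table)
        assert wm.shape == (2, 2)
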