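import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mmcurate.drivers import (LLAMA_WORKFLOWS, _term_columns, anova_f1,
                              build_design, field_type_of, posthoc,
                              trendlines)
from mmcurate.schema import builtin_catalog

from oracles import sequential_ss


def synthetic_design(n_fields=12, seed=0, size_eff=0.1, prompt_eff=0.05,
                     irr_slope=1.0, noise=0.03):
    rng = np.random.default_rng(seed)
    irr = rng.uniform(0.6, 0.9, n_fields)
    types = [["numeric", "binary", "categorical"][i % 3] for i in range(n_fields)]
    rows = []
    for i in range(n_fields):
        for wf in LLAMA_WORKFLOWS:
            size, prompt = wf.split("-")
            f1 = (0.0 + irr_slope * irr[i] + size_eff * (size == "70B")
                  + prompt_eff * (prompt == "CoT") + rng.normal(0, noise))
            rows.append((wf, f"f{i}", f1, size, prompt, types[i], irr[i]))
    return pd.DataFrame(rows, columns=["workflow_id", "field_id", "f1",
                                       "model_size", "prompt_style",
                                       "field_type", "irr_f1"])


class TestBuildDesign:
    def _inputs(self, n_fields):
        catalog = [s for s in builtin_catalog() if s.field_id != "flt_response_date"]
        catalog = catalog[:n_fields]
        rows = [(wf, s.field_id, 0.5 + 0.01 * i)
                for i, s in enumerate(catalog) for wf in LLAMA_WORKFLOWS]
        f1 = pd.DataFrame(rows, columns=["workflow_id", "field_id", "f1"])
        irr = pd.DataFrame({"field_id": [s.field_id for s in catalog],
                            "split": "combined",
                            "irr_f1": np.linspace(0.6, 0.9, len(catalog))})
        return f1, irr, catalog

    def test_twelve_fields_give_48_rows(self):
        f1, irr, catalog = self._inputs(12)
        design = build_design(f1, irr, catalog)
        assert len(design) == 48
        assert design.groupby("workflow_id").size().eq(12).all()

    def test_two_fields_give_8_rows(self):
        f1, irr, catalog = self._inputs(2)
        assert len(build_design(f1, irr, catalog)) == 8

    def test_duplicate_observation_rejected(self):
        f1, irr, catalog = self._inputs(2)
        dup = pd.concat([f1, f1.iloc[[0]]], ignore_index=True)
        with pytest.raises(ValueError):
            build_design(dup, irr, catalog)

    def test_missing_score_rejected(self):
        f1, irr, catalog = self._inputs(2)
        with pytest.raises(ValueError):
            build_design(f1.iloc[:-1], irr, catalog)

    def test_field_type_mapping(self, by_id):
        assert field_type_of(by_id["ecog_score"]) == "numeric"
        assert field_type_of(by_id["mm_diagnosis_date"]) == "numeric"
        assert field_type_of(by_id["emd_presence"]) == "binary"
        assert field_type_of(by_id["flt_regimen"]) == "categorical"


class TestAnova:
    def test_matches_projection_oracle(self):
        for seed in range(5):
            design = synthetic_design(seed=seed, n_fields=6)
            table = anova_f1(design)
            order = ["model_size", "prompt_style", "irr_f1", "field_type"]
            blocks = [_term_columns(design, t) for t in order]
            ss, rss = sequential_ss(design["f1"].to_numpy(), blocks)
            got = table.set_index("term")
            for t, s in zip(order, ss):
                assert got.loc[t, "sum_sq"] == pytest.approx(s, abs=1e-9)
            assert got.loc["Residuals", "sum_sq"] == pytest.approx(rss, abs=1e-9)

    def test_eta_squared_sums_to_one(self):
        table = anova_f1(synthetic_design())
        assert table["eta_sq"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (table["eta_sq"] >= 0).all()

    def test_design_determined_degrees_of_freedom(self):
        table = anova_f1(synthetic_design(n_fields=12)).set_index("term")
        assert table.loc["Residuals", "df"] == 42
        assert table.loc["field_type", "df"] == 2

    def test_constant_response_rejected(self):
        design = synthetic_design()
        design["f1"] = 0.5
        with pytest.raises(ValueError):
            anova_f1(design)


class TestPosthoc:
    def test_recovers_injected_effects(self):
        design = synthetic_design(seed=1, size_eff=0.13, prompt_eff=0.08,
                                  irr_slope=1.0, noise=0.02)
        table = posthoc(design)["table"].set_index("driver")
        assert table.loc["model_size_70B_vs_8B", "estimate"] == pytest.approx(
            0.13, abs=0.03)
        assert table.loc["prompt_style_CoT_vs_ZSL", "estimate"] == pytest.approx(
            0.08, abs=0.03)
        assert table.loc["irr_f1", "estimate"] == pytest.approx(1.0, abs=0.2)
        assert table.loc["model_size_70B_vs_8B", "test"] == "paired t-test"
        assert table.loc["irr_f1", "test"] == "OLS"

    def test_null_effect_gives_zero_estimate(self):
        design = synthetic_design(seed=2, size_eff=0.1)
        # make CoT identical to ZSL within each (field, size)
        zsl = design[design.prompt_style == "ZSL"].set_index(
            ["field_id", "model_size"])["f1"]
        design["f1"] = [zsl[(r.field_id, r.model_size)]
                        for r in design.itertuples(index=False)]
        table = posthoc(design)["table"].set_index("driver")
        assert table.loc["prompt_style_CoT_vs_ZSL", "estimate"] == 0.0
        assert table.loc["prompt_style_CoT_vs_ZSL", "p_value"] == pytest.approx(1.0)

    def test_tukey_covers_all_type_pairs(self):
        tukey = posthoc(synthetic_design())["tukey"]
        assert len(tukey) == 3  # binary/categorical/numeric pairwise


class TestTrendlines:
    def _line_design(self, slopes_intercepts):
        rows = []
        xs = np.linspace(0.6, 0.9, 7)
        for wf, (m, b) in slopes_intercepts.items():
            for i, x in enumerate(xs):
                rows.append((wf, f"f{i}", b + m * x, "8B", "ZSL", "binary", x))
        return pd.DataFrame(rows, columns=["workflow_id", "field_id", "f1",
                                           "model_size", "prompt_style",
                                           "field_type", "irr_f1"])

    def test_crossing_point_algebra(self):
        design = self._line_design({"w1": (1.0, 0.0), "w2": (0.375, 0.5)})
        out = trendlines(design)
        cross = out["crossings"]
        assert len(cross) == 1
        assert cross.iloc[0]["irr_at_crossing"] == pytest.approx(0.8)

    def test_parallel_lines_no_crossing(self):
        design = self._line_design({"w1": (1.0, 0.0), "w2": (1.0, 0.2)})
        assert trendlines(design)["crossings"].empty

    def test_identical_lines_no_unique_crossing(self):
        design = self._line_design({"w1": (1.0, 0.1), "w2": (1.0, 0.1)})
        assert trendlines(design)["crossings"].empty

    def test_crossing_outside_observed_range_suppressed(self):
        # lines intersect at x = 0.5, below the observed IRR range [0.6, 0.9]
        design = self._line_design({"w1": (1.0, 0.0), "w2": (0.5, 0.25)})
        assert trendlines(design)["crossings"].empty
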