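"""Well aggregation, Dunnett/Sidak comparisons, secretion arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from granule_sizer import (
    PlateDesign,
    ReleaseModel,
    aggregate_wells,
    detect_size_selection,
    fold_inhibition,
    one_way_dunnett,
    percent_released,
    sidak_adjust,
    two_way_sidak,
)
from granule_sizer.synthgen import simulate_truth_statistics


def image_frame(rows):
    return pd.DataFrame(rows, columns=["condition", "well",
                                       "long_area_fraction", "wpb_per_cell"])


class TestAggregateWells:
    def test_simple_mean(self):
        df = image_frame([("c", "w1", f, 10.0) for f in (0.2, 0.3, 0.4)])
        out = aggregate_wells(df)
        assert out.loc[0, "mean_long_area_fraction"] == pytest.approx(0.3)
        assert out.loc[0, "n_images"] == 3

    def test_flagged_images_excluded(self):
        df = image_frame([("c", "w1", 0.2, 1.0), ("c", "w1", np.nan, 1.0),
                          ("c", "w1", 0.4, 1.0)])
        out = aggregate_wells(df)
        assert out.loc[0, "mean_long_area_fraction"] == pytest.approx(0.3)

    def test_well_count_matches_design(self):
        design = PlateDesign(conditions=("a", "b"), wells_per_condition=16,
                             fields_per_well=9)
        df = simulate_truth_statistics(design, seed=0)
        out = aggregate_wells(df)
        assert (out.groupby("condition").size() == 16).all()

    def test_field_order_invariance(self):
        rng = np.random.default_rng(0)
        rows = [("c", f"w{w}", rng.random(), rng.random())
                for w in range(4) for _ in range(9)]
        df = image_frame(rows)
        shuffled = df.sample(frac=1.0, random_state=1)
        a = aggregate_wells(df)
        b = aggregate_wells(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_all_flagged_well_dropped(self):
        df = image_frame([("c", "w1", np.nan, np.nan), ("c", "w2", 0.5, 1.0)])
        out = aggregate_wells(df)
        assert list(out["well"]) == ["w2"]


class TestDunnett:
    def test_missing_control_raises(self):
        with pytest.raises(ValueError, match="control"):
            one_way_dunnett({"a": [1, 2, 3]}, "ctrl")

    def test_identical_data_gives_p_one(self):
        vals = {"ctrl": [1.0] * 5, "a": [1.0] * 5, "b": [1.0] * 5}
        res = one_way_dunnett(vals, "ctrl", n_mc=2000, seed=0)
        assert all(r.p_adjusted == 1.0 for r in res)
        assert all(r.t_statistic == 0.0 for r in res)

    def test_two_group_reduction_to_t_test(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        res = one_way_dunnett({"ctrl": a, "trt": b}, "ctrl",
                              n_mc=40000, seed=5)[0]
        _, p = stats.ttest_ind(b, a, equal_var=True)
        se_mc = math.sqrt(p * (1 - p) / 40000)
        assert abs(res.p_adjusted - p) <= 3 * se_mc

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(11)
        vals = {k: rng.normal(0, 1, 6) for k in ("ctrl", "a", "b", "c")}
        for r in one_way_dunnett(vals, "ctrl", n_mc=5000, seed=1):
            assert r.p_adjusted >= r.p_raw

    def test_cross_check_against_scipy_dunnett(self):
        # independent implementation of the same adjustment
        rng = np.random.default_rng(7)
        groups = {"ctrl": rng.normal(0, 1, 10), "a": rng.normal(0.8, 1, 10),
                  "b": rng.normal(-0.3, 1, 10)}
        ours = one_way_dunnett(groups, "ctrl", n_mc=200000, seed=2)
        ref = stats.dunnett(groups["a"], groups["b"],
                            control=groups["ctrl"])
        for r, p_ref in zip(ours, ref.pvalue):
            assert r.p_adjusted == pytest.approx(p_ref, abs=0.01)


class TestSidak:
    def test_closed_form(self):
        assert sidak_adjust(0.05, 3) == pytest.approx(0.142625)

    def test_single_contrast_identity(self):
        assert sidak_adjust(0.2, 1) == pytest.approx(0.2)

    def test_dominance(self):
        rng = np.random.default_rng(0)
        for p in rng.random(50):
            for m in (1, 2, 5):
                assert sidak_adjust(float(p), m) >= p - 1e-12


class TestTwoWay:
    @staticmethod
    def _layout(rng, effect=0.0):
        rows = []
        for cond in ("luc", "vwf"):
            for trt in ("none", "cce"):
                mu = effect if (cond, trt) == ("luc", "cce") else 0.0
                for _ in range(6):
                    rows.append({"condition": cond, "treatment": trt,
                                 "value": rng.normal(mu, 1.0)})
        return pd.DataFrame(rows)

    def test_empty_cell_raises(self):
        df = self._layout(np.random.default_rng(0))
        df = df[~((df.condition == "luc") & (df.treatment == "cce"))]
        with pytest.raises(ValueError, match="luc"):
            two_way_sidak(df, [(("luc", "none"), ("luc", "cce"))])

    def test_detects_cell_effect(self):
        df = self._layout(np.random.default_rng(1), effect=3.0)
        contrasts = [(("luc", "none"), ("luc", "cce")),
                     (("vwf", "none"), ("vwf", "cce"))]
        anova, res = two_way_sidak(df, contrasts)
        assert res[0].p_adjusted < 0.01
        assert res[1].p_adjusted > 0.05
        assert {"C(A)", "C(B)", "C(A):C(B)", "Residual"} <= set(anova.index)

    def test_null_familywise_error_within_binomial_band(self):
        rng = np.random.default_rng(12)
        contrasts = [(("luc", "none"), ("luc", "cce")),
                     (("vwf", "none"), ("vwf", "cce")),
                     (("luc", "none"), ("vwf", "none"))]
        reps, hits = 400, 0
        for _ in range(reps):
            _, res = two_way_sidak(self._layout(rng), contrasts)
            hits += any(r.p_adjusted < 0.05 for r in res)
        upper = stats.binom.ppf(0.995, reps, 0.05) / reps
        assert hits / reps <= upper


class TestSecretionTables:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["condition", "inhibitor",
                                           "releasate", "lysate"])

    def test_percent_released_examples(self):
        t = self._table([("a", False, 20, 80), ("b", False, 0, 50),
                         ("c", False, 50, 50)])
        assert list(percent_released(t)) == [20.0, 0.0, 50.0]

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError):
            percent_released(self._table([("a", False, -1, 2)]))
        with pytest.raises(ValueError):
            percent_released(self._table([("a", False, 0, 0)]))

    def test_fold_inhibition_examples(self):
        t = self._table([("pma", True, 50, 100), ("pma", False, 100, 100),
                         ("hist", True, 30, 70), ("hist", False, 30, 70),
                         ("comb", True, 60, 40), ("comb", False, 50, 50)])
        f = fold_inhibition(t)
        assert f["pma"] == pytest.approx((50 / 150) / (100 / 200))
        assert f["hist"] == pytest.approx(1.0)
        assert f["comb"] == pytest.approx(0.6 / 0.5)

    def test_fold_inhibition_raw_releasate(self):
        t = self._table([("pma", True, 50, 100), ("pma", False, 100, 100)])
        f = fold_inhibition(t, use_percent_released=False)
        assert f["pma"] == pytest.approx(0.5)

    def test_unpaired_condition_raises(self):
        t = self._table([("pma", True, 50, 100)])
        with pytest.raises(ValueError, match="pma"):
            fold_inhibition(t)


class TestDetectSizeSelection:
    def test_control_vs_itself_non_selective(self):
        design = PlateDesign(conditions=("ctrl", "same"),
                             wells_per_condition=8, fields_per_well=9)
        models = {"ctrl": ReleaseModel.random_release(0.4),
                  "same": ReleaseModel.random_release(0.4)}
        df = simulate_truth_statistics(design, release_models=models, seed=4)
        wells = aggregate_wells(df)
        out = detect_size_selection(wells, control="ctrl", n_mc=4000, seed=0)
        assert list(out["verdict"]) == ["non-selective"]

    def test_strong_long_selection_detected(self):
        design = PlateDesign(conditions=("ctrl", "stim"),
                             wells_per_condition=16, fields_per_well=9)
        models = {"stim": ReleaseModel(p_base=0.1, p_max=0.8,
                                       midpoint_length=2.0, steepness=0.3)}
        df = simulate_truth_statistics(design, release_models=models, seed=4)
        wells = aggregate_wells(df)
        out = detect_size_selection(wells, control="ctrl", n_mc=4000, seed=0)
        assert out.loc[0, "verdict"] == "long-selective"
        assert out.loc[0, "fraction_estimate"] < 0
        # counts fell too and are reported alongside
        assert out.loc[0, "count_estimate"] < 0

    def test_short_selection_verdict_from_rising_fraction(self):
        # losing many short granules raises the long-area fraction
        rng = np.random.default_rng(8)
        rows = ([{"condition": "ctrl", "well": f"c{w}",
                  "mean_long_area_fraction": rng.normal(0.20, 0.01),
                  "mean_wpb_per_cell": rng.normal(25, 1)} for w in range(16)]
                + [{"condition": "stim", "well": f"s{w}",
                    "mean_long_area_fraction": rng.normal(0.30, 0.01),
                    "mean_wpb_per_cell": rng.normal(18, 1)} for w in range(16)])
        out = detect_size_selection(pd.DataFrame(rows), control="ctrl",
                                    n_mc=4000, seed=0)
        assert out.loc[0, "verdict"] == "short-selective"
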