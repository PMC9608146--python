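import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import stainquant as sq
from stainquant.errors import AggregationError


def _rec(dr):
    return sq.QuantRecord(
        image_id="x", area_fraction_1=1.0, area_fraction_2=2.0, dr=dr,
        threshold_1=0, threshold_2=0, method="t",
    )


class TestAggregateDonor:
    def test_constant_balanced_design(self):
        wells = {f"w{i}": [_rec(0.5)] * 4 for i in range(3)}
        assert sq.aggregate_donor(wells) == 0.5

    def test_nested_mean_of_distinct_wells(self):
        wells = {
            "w1": [_rec(0.2)] * 4,
            "w2": [_rec(0.4)] * 4,
            "w3": [_rec(0.6)] * 4,
        }
        assert sq.aggregate_donor(wells) == pytest.approx(0.4)

    def test_unbalanced_design_equals_mean_of_well_means_not_grand_mean(self):
        wells = {
            "w1": [_rec(v) for v in (0.2, 0.2, 0.4, 0.4)],
            "w2": [_rec(v) for v in (0.6, 0.8, 0.6, 0.8)],
            "w3": [_rec(v) for v in (1.0, 2.0)],
        }
        nested = sq.aggregate_donor(wells)
        well_means = [0.3, 0.7, 1.5]
        grand = np.mean([0.2, 0.2, 0.4, 0.4, 0.6, 0.8, 0.6, 0.8, 1.0, 2.0])
        assert nested == pytest.approx(np.mean(well_means))
        assert nested != pytest.approx(grand)

    def test_undefined_drs_excluded_with_warning(self):
        wells = {"w1": [_rec(0.4), _rec(math.nan)]}
        with pytest.warns(UserWarning, match="undefined"):
            assert sq.aggregate_donor(wells) == 0.4

    def test_all_undefined_is_aggregation_error(self):
        with pytest.raises(AggregationError):
            sq.aggregate_donor({"w1": [_rec(math.nan)]})


class TestNormalization:
    def test_ratio(self):
        assert sq.normalized_dr(0.6, 0.4) == pytest.approx(1.5)

    def test_equal_means_is_neutral_unity(self):
        assert sq.normalized_dr(0.37, 0.37) == 1.0

    def test_zero_control_is_undefined(self):
        assert math.isnan(sq.normalized_dr(0.5, 0.0))

    def test_fallback_pools_other_donors(self):
        assert sq.fallback_control([0.2, 0.3, 0.4]) == pytest.approx(0.3)
        assert sq.fallback_control([0.5]) == 0.5

    def test_fallback_without_other_controls_errors(self):
        with pytest.raises(AggregationError):
            sq.fallback_control([])

    @pytest.mark.parametrize(
        "drn,label",
        [
            (0.86, "below-control"),
            (1.46, "above-control"),
            (0.75, "below-control"),
            (1.0, "neutral"),
            (0.0, "below-control"),
        ],
    )
    def test_classification_thresholds(self, drn, label):
        assert sq.classify_dr_normalized(drn) == label

    def test_undefined_classification_skipped(self):
        assert sq.classify_dr_normalized(math.nan) is None


class TestPellet:
    def test_circle_area(self):
        assert sq.ellipse_area(2, 2) == pytest.approx(math.pi)

    def test_three_by_two_ellipse(self):
        assert sq.ellipse_area(3, 2) == pytest.approx(1.5 * math.pi)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(ValueError):
            sq.ellipse_area(3, 0)
        with pytest.raises(ValueError):
            sq.ellipse_area(1, 2)  # major must be >= minor

    def test_manual_measurement_carries_axes(self):
        m = sq.manual_pellet_area("s1", 2.0, 1.0)
        assert m.mode == "manual-ellipse"
        assert m.area_mm2 == pytest.approx(0.5 * math.pi)

    def test_auto_area_of_rendered_two_by_one_mm_pellet(self, basis):
        # 10 um/px: a 2 x 1 mm ellipse has semi-axes 100 x 50 px
        scene = sq.SyntheticScene(
            260, 260,
            [sq.Ellipse(130, 130, 50, 100, stain=1, concentration=0.8),
             sq.Ellipse(130, 130, 30, 60, stain=2, concentration=0.5)],
            pixel_size_um=10.0,
            seed=3,
        )
        img, _ = sq.render_stained_image(scene, basis)
        m = sq.auto_pellet_area(img, basis)
        assert m.mode == "auto-mask"
        assert m.area_mm2 == pytest.approx(0.5 * math.pi, rel=0.03)

    def test_blank_section_measures_zero_with_warning(self, basis):
        img = sq.RGBImage(np.full((32, 32, 3), 255, dtype=np.uint8), pixel_size_um=10)
        with pytest.warns(UserWarning, match="empty"):
            m = sq.auto_pellet_area(img, basis)
        assert m.area_mm2 == 0.0

    def test_largest_connected_component_wins(self, basis):
        scene = sq.SyntheticScene(
            100, 100,
            [sq.Disk(30, 30, 18, stain=1, concentration=0.8),   # ~1017 px
             sq.Disk(80, 80, 4, stain=1, concentration=0.8)],   # ~49 px
            pixel_size_um=1000.0,  # 1 mm/px so area == pixel count in mm^2
            seed=0,
        )
        img, truth = sq.render_stained_image(scene, basis)
        big = int(np.count_nonzero(
            (np.arange(100)[:, None] - 30) ** 2 + (np.arange(100)[None, :] - 30) ** 2 <= 18**2
        ))
        m = sq.auto_pellet_area(img, basis)
        assert m.area_mm2 == pytest.approx(big, rel=0.02)
        assert m.area_mm2 < np.count_nonzero(truth.mask1)  # small blob excluded


class TestRmAnova:
    def test_constant_nonzero_differences_degenerate_to_infinite_f(self):
        with pytest.warns(UserWarning, match="interaction"):
            res = sq.rm_anova_two_condition([(0.5, 0.3)] * 4)
        assert math.isinf(res.f_statistic)
        assert res.p_value == 0.0

    def test_identical_conditions_give_null_f(self):
        res = sq.rm_anova_two_condition([(0.4, 0.4), (0.7, 0.7), (0.2, 0.2)])
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    def test_f_equals_squared_paired_t_on_worked_example(self):
        pairs = [(0.6, 0.4), (0.5, 0.45), (0.7, 0.5), (0.55, 0.5)]
        res = sq.rm_anova_two_condition(pairs)
        arr = np.asarray(pairs)
        t = stats.ttest_rel(arr[:, 0], arr[:, 1])
        assert res.f_statistic == pytest.approx(t.statistic**2, abs=1e-8)
        assert res.p_value == pytest.approx(t.pvalue, abs=1e-10)
        assert res.df_num == 1 and res.df_den == 3

    def test_agrees_with_pingouin_univariate_rm_anova(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.normal(size=(6, 2)) + rng.normal(size=(6, 1))
        res = sq.rm_anova_two_condition([tuple(p) for p in x])
        frame = pd.DataFrame(
            {
                "donor": np.repeat(np.arange(6), 2),
                "condition": np.tile(["diff", "ctrl"], 6),
                "dr": x.ravel(),
            }
        )
        ref = pingouin.rm_anova(
            data=frame, dv="dr", within="condition", subject="donor"
        )
        assert res.f_statistic == pytest.approx(float(ref["F"][0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_unc"][0]), rel=1e-9)

    def test_incomplete_donors_excluded_with_warning(self):
        pairs = {"a": (0.5, 0.4), "b": (0.6, 0.45), "c": (math.nan, 0.4), "d": (0.7, 0.6)}
        with pytest.warns(UserWarning, match="excluded"):
            res = sq.rm_anova_two_condition(pairs)
        assert res.n_donors == 3
        assert res.excluded_donors == ("c",)

    def test_fewer_than_two_donors_rejected(self):
        with pytest.raises(ValueError):
            sq.rm_anova_two_condition([(0.5, 0.4)])

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 12))
    def test_f_equals_squared_paired_t_property(self, seed, n):
        g = np.random.default_rng(seed)
        x = g.normal(size=(n, 2)) + g.normal(size=(n, 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sq.rm_anova_two_condition([tuple(p) for p in x])
        t = stats.ttest_rel(x[:, 0], x[:, 1])
        assert abs(res.f_statistic - t.statistic**2) <= 1e-8


class TestProcessStudy:
    def _run(self, info, basis, lineage="adipogenic", **kwargs):
        layout = sq.discover_study(info["root"], lineage=lineage)
        pair = sq.repair_calibration(
            sq.CalibrationPair(
                dark=sq.read_rgb_image(info["root"] / "calibration" / "dark.png"),
                light=sq.read_rgb_image(info["root"] / "calibration" / "light.png"),
            )
        )
        return sq.process_study(layout, basis, pair, **kwargs)

    def test_effect_study_detected(self, tmp_path, basis):
        info = sq.generate_synthetic_study(
            tmp_path / "s",
            n_donors=4,
            effect_multipliers=[4.0, 4.0, 4.0, 4.0],
            seed=3,
            image_size=(64, 64),
        )
        result = self._run(info, basis)
        assert all(s.classification == "above-control" for s in result.summaries)
        assert result.anova is not None and result.anova.p_value < 0.05

    def test_dr_normalized_is_unity_for_identical_image_sets(self, tmp_path, basis, flat_scene):
        img, _ = sq.render_stained_image(flat_scene, basis)
        for cond in ("differentiated", "control"):
            for w in range(2):
                for i in range(2):
                    sq.write_rgb_image(
                        img, tmp_path / "d1" / cond / f"w{w}" / f"i{i}.png"
                    )
                    sq.write_rgb_image(
                        img, tmp_path / "d2" / cond / f"w{w}" / f"i{i}.png"
                    )
        layout = sq.discover_study(tmp_path)
        result = sq.process_study(layout, basis, None)
        for s in result.summaries:
            assert s.dr_normalized == 1.0
            assert s.classification == "neutral"

    def test_scale_equivariance_of_donor_means(self):
        wells = {"w1": [_rec(0.2), _rec(0.4)], "w2": [_rec(0.6)]}
        base = sq.aggregate_donor(wells)
        scaled = {
            k: [_rec(r.dr * 3.0) for r in v] for k, v in wells.items()
        }
        assert sq.aggregate_donor(scaled) == pytest.approx(3.0 * base)

    def test_pooled_fallback_when_donor_lacks_controls(self, tmp_path, basis):
        info = sq.generate_synthetic_study(
            tmp_path / "s", n_donors=3, effect_multipliers=[2.0, 2.0, 2.0],
            seed=5, image_size=(64, 64),
        )
        # remove donor_03's control branch entirely (as for the donor whose
        # non-induced cells formed no pellet)
        import shutil

        shutil.rmtree(info["root"] / "donor_03" / "control")
        with pytest.warns(UserWarning):
            result = self._run(info, basis)
        s3 = [s for s in result.summaries if s.donor == "donor_03"][0]
        assert s3.control_source == "pooled-fallback"
        others = [s.mean_dr_control for s in result.summaries if s.donor != "donor_03"]
        assert s3.mean_dr_control == pytest.approx(np.mean(others))
        assert not math.isnan(s3.dr_normalized)

    def test_rerun_writes_bit_identical_outputs(self, tmp_path, study_tree, basis):
        r1 = self._run(study_tree, basis)
        r2 = self._run(study_tree, basis)
        p1 = sq.write_study_result(r1, tmp_path / "o1")
        p2 = sq.write_study_result(r2, tmp_path / "o2")
        for key in ("records", "summary", "anova"):
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_chondrogenic_study_includes_pellet_statistics(self, tmp_path):
        basis = sq.lineage_basis("chondrogenic")
        info = sq.generate_synthetic_study(
            tmp_path / "s", n_donors=3, effect_multipliers=[3.0, 3.0, 3.0],
            lineage="chondrogenic", seed=8, image_size=(64, 64),
        )
        result = self._run(info, basis, lineage="chondrogenic")
        assert result.lineage == "chondrogenic"
        assert len(result.pellets) == 3 * 2 * 3  # donors x conditions x sections
        assert result.anova is not None
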