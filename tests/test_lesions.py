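import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from vsimri import (
    ParameterMap,
    classify_tissue,
    export_double_box,
    pool_macrovascular,
    proportion_above,
    roi_metric_summary,
    students_t,
)


class TestClassifyTissue:
    @pytest.mark.parametrize(
        "adc,expected", [(500.0, "edema"), (750.0, "normal"), (650.0, "normal")]
    )
    def test_threshold_rule(self, adc, expected):
        assert classify_tissue(adc) == expected

    @given(st.floats(min_value=0, max_value=2000), st.floats(min_value=0, max_value=2000))
    def test_monotone_in_adc(self, a, b):
        lo, hi = sorted((a, b))
        if classify_tissue(lo) == "normal":
            assert classify_tissue(hi) == "normal"

    def test_negative_adc_rejected(self):
        with pytest.raises(ValueError):
            classify_tissue(-1.0)


class TestRoiSummary:
    def _map(self, values, valid=None):
        values = np.asarray(values, dtype=float)
        valid = np.ones_like(values, bool) if valid is None else valid
        return ParameterMap(values, "um", valid)

    def test_uniform_roi(self):
        pmap = self._map(np.full((4, 4, 2), 7.0))
        mask = np.zeros((4, 4, 2), bool)
        mask[1:3, 1:3, :] = True
        s = roi_metric_summary(pmap, mask, "roi")
        assert s.mean == s.median == 7.0
        assert s.n_voxels == 8

    def test_partially_invalid_counts_valid_only(self):
        vals = np.full((3, 3, 1), 5.0)
        valid = np.ones((3, 3, 1), bool)
        valid[0] = False
        pmap = self._map(vals, valid)
        s = roi_metric_summary(pmap, np.ones((3, 3, 1), bool), "roi")
        assert s.n_voxels == 6

    def test_lesion_vsi_exceeds_normal(self, small_truth):
        vsi = self._map(small_truth.maps["vsi"])
        lesion = roi_metric_summary(vsi, small_truth.rois["lesion"], "lesion")
        contra = roi_metric_summary(vsi, small_truth.rois["contra_subcortex"], "contra")
        assert lesion.mean > contra.mean

    def test_no_valid_voxels_names_roi(self):
        pmap = self._map(np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool))
        with pytest.raises(ValueError, match="my_roi"):
            roi_metric_summary(pmap, np.ones((2, 2, 2), bool), "my_roi")


class TestProportionAbove:
    def test_examples(self):
        assert proportion_above([5, 12, 15], 10.0) == pytest.approx(2 / 3)
        assert proportion_above([1, 2], 10.0) == 0.0
        assert proportion_above([11, 12], 10.0) == 1.0

    def test_infinite_cutoffs(self):
        vals = [1.0, 5.0, 9.0]
        assert proportion_above(vals, -np.inf) == 1.0
        assert proportion_above(vals, np.inf) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            proportion_above([], 1.0)


class TestStudentsT:
    def test_identical_groups(self):
        r = students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0
        assert r.p_value == 1.0

    def test_hand_computed_example(self):
        r = students_t([1, 2, 3, 4], [2, 3, 4, 5])
        assert r.statistic == pytest.approx(-1.0954, abs=1e-4)

    def test_paired_constant_difference_degenerate(self):
        r = students_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], paired=True)
        assert r.degenerate
        assert r.p_value == 0.0

    def test_paired_requires_equal_sizes(self):
        with pytest.raises(ValueError):
            students_t([1.0, 2.0], [1.0, 2.0, 3.0], paired=True)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            na, nb = rng.integers(3, 20, size=2)
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), na)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), nb)
            ours = students_t(a, b)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert ours.statistic == pytest.approx(ref.statistic, abs=1e-6)
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-6)
            n = min(na, nb)
            ours_p = students_t(a[:n], b[:n], paired=True)
            ref_p = stats.ttest_rel(a[:n], b[:n])
            assert ours_p.statistic == pytest.approx(ref_p.statistic, abs=1e-6)
            assert ours_p.p_value == pytest.approx(ref_p.pvalue, abs=1e-6)


class TestExportDoubleBox:
    def test_row_shape(self):
        df = export_double_box(
            [500.0] * 3 + [750.0] * 3,
            [12.0] * 3 + [4.0] * 3,
            ["lesion"] * 3 + ["contra"] * 3,
        )
        assert len(df) == 6
        assert set(df.columns) >= {"roi", "side", "adc", "metric", "tissue_class"}
        assert df.attrs["adc_threshold"] == 650.0

    def test_lesion_rows_classified_edema(self):
        df = export_double_box(
            [500.0, 510.0, 760.0, 740.0],
            [12.0, 11.0, 4.0, 5.0],
            ["lesion", "lesion", "contra", "contra"],
        )
        assert (df.loc[df.roi == "lesion", "tissue_class"] == "edema").all()
        assert (df.loc[df.roi == "contra", "tissue_class"] == "normal").all()

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            export_double_box([], [], [])
        with pytest.raises(ValueError):
            export_double_box([1.0], [1.0, 2.0], ["a"])


class TestPoolMacrovascular:
    def test_max_venous_min_arterial(self):
        df = pd.DataFrame(
            [
                ("rat1", 1, "cRHV", 0.30),
                ("rat1", 4, "cRHV", 0.36),
                ("rat1", 7, "cRHV", 0.28),
                ("rat1", 1, "MCA", 0.20),
                ("rat1", 4, "MCA", 0.16),
                ("rat1", 7, "MCA", 0.21),
            ],
            columns=["animal", "day", "vessel", "diameter_mm"],
        )
        pooled = pool_macrovascular(df)
        early = pooled[pooled.phase == "early"].set_index("vessel")["diameter_mm"]
        late = pooled[pooled.phase == "late"].set_index("vessel")["diameter_mm"]
        assert early["cRHV"] == 0.36  # venous: max over early days
        assert early["MCA"] == 0.16  # arterial: min over early days
        assert late["cRHV"] == 0.28 and late["MCA"] == 0.21

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            pool_macrovascular(pd.DataFrame({"animal": [], "day": []}))
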