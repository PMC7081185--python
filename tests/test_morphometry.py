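import numpy as np
import pytest
from scipy import ndimage

from vsimri import (
    local_thickness,
    make_vascular_tree,
    summarize_vessel_diameter,
    threshold_vasculature,
)


def exhaustive_local_thickness(mask: np.ndarray) -> np.ndarray:
    """Brute-force maximal-sphere oracle (same digital-ball convention).

    For every mask voxel c the covering reach r(c) is the distance to the
    nearest background voxel centre (computed by direct distance
    minimization, no distance transform); thickness(p) is the largest
    2·(r(c) − 0.5) over all spheres whose reach covers p (|p − c| <= r(c)),
    the physical boundary sitting half a voxel inside the background centre.
    """
    coords = np.argwhere(mask)
    bg = np.argwhere(~mask)
    # distance of each mask voxel to the nearest background voxel
    r = np.empty(len(coords))
    for i, c in enumerate(coords):
        d2 = ((bg - c) ** 2).sum(axis=1)
        r[i] = np.sqrt(d2.min())
    thickness = np.zeros(mask.shape)
    for c, rc in zip(coords, r):
        d2 = ((coords - c) ** 2).sum(axis=1)
        covered = d2 <= rc * rc
        for p in coords[covered]:
            t = 2.0 * (rc - 0.5)
            if thickness[tuple(p)] < t:
                thickness[tuple(p)] = t
    return thickness


def digital_ball(n: int, radius: float) -> np.ndarray:
    c = (n - 1) / 2
    x, y, z = np.ogrid[0:n, 0:n, 0:n]
    return (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius**2


class TestThreshold:
    def test_all_below_threshold_empty(self):
        vol = np.full((8, 8, 8), 5.0)
        vol[0, 0, 0] = 60.0  # keep threshold inside the intensity range
        mask = threshold_vasculature(vol, 50.0)
        assert mask.mask.sum() == 1

    def test_tube_voxel_count_matches_generator(self):
        vol, exact_mask, truth = make_vascular_tree(
            (32, 32, 32), 1.0, [((4, 16, 16), (28, 16, 16), 3.0)]
        )
        mask = threshold_vasculature(vol, 50.0)
        assert np.array_equal(mask.mask, exact_mask)
        assert mask.mask.sum() == truth[0]["n_voxels"]

    def test_threshold_at_minimum_gives_full_volume(self):
        vol = np.arange(27, dtype=float).reshape(3, 3, 3)
        mask = threshold_vasculature(vol, 0.0)
        assert mask.mask.sum() == 26  # strictly greater than the minimum

    def test_threshold_outside_range_rejected(self):
        with pytest.raises(ValueError):
            threshold_vasculature(np.zeros((4, 4, 4)), 10.0)


class TestLocalThickness:
    def test_single_voxel(self):
        mask = np.zeros((7, 7, 7), dtype=bool)
        mask[3, 3, 3] = True
        t = local_thickness(mask)
        assert t[3, 3, 3] == pytest.approx(1.0)  # one voxel across

    def test_solid_ball_max_thickness(self):
        mask = digital_ball(21, 8.0)
        t = local_thickness(mask)
        assert abs(t.max() - 16.0) <= 1.0

    def test_cylinder_mean_thickness(self):
        _, mask, _ = make_vascular_tree(
            (48, 24, 24), 1.0, [((0, 12, 12), (47, 12, 12), 5.0)]
        )
        t = local_thickness(mask)
        assert abs(t[mask].mean() - 10.0) <= 1.0

    @pytest.mark.parametrize("case", ["ball", "tube", "blob", "two_balls"])
    def test_matches_exhaustive_oracle(self, case):
        if case == "ball":
            mask = digital_ball(17, 6.0)
        elif case == "tube":
            _, mask, _ = make_vascular_tree(
                (24, 14, 14), 1.0, [((2, 7, 7), (21, 7, 7), 3.0)]
            )
        elif case == "two_balls":
            mask = digital_ball(21, 4.0)
            mask |= np.roll(mask, 8, axis=0)
        else:
            rng = np.random.default_rng(3)
            seeds = np.zeros((16, 16, 16), dtype=bool)
            seeds[tuple(rng.integers(4, 12, size=(3, 5)))] = True
            mask = ndimage.binary_dilation(seeds, iterations=3)
        assert mask.shape <= (32, 32, 32)
        expected = exhaustive_local_thickness(mask)
        got = local_thickness(mask)
        assert np.allclose(got, expected, atol=1e-9)

    def test_edt_bounds_and_ridge_equality(self):
        # every voxel's own inscribed sphere is a lower bound; the maximum
        # thickness is attained on the distance ridge
        mask = digital_ball(19, 7.0)
        t = local_thickness(mask)
        edt = ndimage.distance_transform_edt(mask)
        assert np.all(t[mask] >= 2 * (edt[mask] - 0.5) - 1e-9)
        assert t.max() == pytest.approx(2 * (edt.max() - 0.5))

    def test_dilation_never_decreases_thickness(self):
        _, mask, _ = make_vascular_tree(
            (24, 16, 16), 1.0, [((2, 8, 8), (21, 8, 8), 3.0)]
        )
        t = local_thickness(mask)
        dilated = ndimage.binary_dilation(mask)
        t2 = local_thickness(dilated)
        assert np.all(t2[mask] >= t[mask] - 1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            local_thickness(np.zeros((4, 4, 4), dtype=bool))

    def test_voxel_size_scales_output(self):
        mask = digital_ball(13, 4.0)
        t1 = local_thickness(mask, voxel_size=1.0)
        t2 = local_thickness(mask, voxel_size=0.059)
        assert np.allclose(t2, 0.059 * t1)


class TestDiameterSummary:
    def test_uniform_branch(self):
        t = np.zeros((6, 6, 6))
        branch = np.zeros((6, 6, 6), dtype=bool)
        branch[2:4, 2:4, 2:4] = True
        t[branch] = 7.0
        res = summarize_vessel_diameter(t, branch, "main")
        assert res.mean_diameter == pytest.approx(7.0)
        assert res.sd_diameter == 0.0

    def test_two_segment_pooled_stats(self):
        t = np.zeros((8, 4, 4))
        branch = np.zeros((8, 4, 4), dtype=bool)
        branch[:4, 0, 0] = True
        branch[4:, 0, 0] = True
        t[:4, 0, 0] = 6.0
        t[4:, 0, 0] = 10.0
        res = summarize_vessel_diameter(t, branch)
        assert res.mean_diameter == pytest.approx(8.0)
        assert res.sd_diameter == pytest.approx(2.0)

    def test_tapering_tube_monotone_sections(self):
        segs = [((2, 16, 16), (14, 16, 16), 3.0), ((14, 16, 16), (29, 16, 16), 6.0)]
        _, mask, truth = make_vascular_tree((32, 32, 32), 1.0, segs)
        t = local_thickness(mask)
        m_thin = summarize_vessel_diameter(t, truth[0]["mask"]).mean_diameter
        m_thick = summarize_vessel_diameter(t, truth[1]["mask"]).mean_diameter
        assert m_thin < m_thick
        assert 6.0 <= (m_thin + m_thick) / 2 <= 12.0

    def test_empty_branch_rejected(self):
        with pytest.raises(ValueError):
            summarize_vessel_diameter(np.ones((4, 4, 4)), np.zeros((4, 4, 4), bool))
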