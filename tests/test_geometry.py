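"""Centers of gravity, border-orientation angles/percentages, sizes, ratios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecconnseg import (
    AxisFrame,
    LEC,
    MEC,
    SegmentationLabelMap,
    angle_to_percentage,
    axis_angle,
    border_orientation,
    center_of_gravity,
    make_cohort,
    segment_participant,
    size_report,
)
from ecconnseg.errors import DegenerateSegmentationError, ParameterError
from ecconnseg.geometry import two_value_mad
from ecconnseg.reference import (
    ANGLE_ROWS_CONSISTENT,
    REFERENCE_ANGLES,
    REFERENCE_SIZES,
)

from conftest import centered_grid


def labelmap(label_positions, shape=(12, 12, 12), affine_grid=None):
    """Label map with {label: [world-ish voxel indices]} on a centered grid."""
    grid = affine_grid if affine_grid is not None else centered_grid(shape)
    data = np.zeros(grid.shape, dtype=int)
    for label, positions in label_positions.items():
        for idx in positions:
            data[tuple(idx)] = label
    return SegmentationLabelMap(grid=grid.with_data(data), approach="t")


class TestCenterOfGravity:
    def test_single_voxel(self):
        grid = centered_grid((5, 5, 5))
        lm = labelmap({MEC: [(4, 4, 4)]}, affine_grid=grid)
        expected = grid.world_coordinates()[4, 4, 4]
        assert np.allclose(center_of_gravity(lm, MEC, "both"), expected)

    def test_two_voxel_midpoint(self):
        grid = centered_grid((7, 5, 5))
        lm = labelmap({MEC: [(1, 2, 2), (3, 2, 2)]}, affine_grid=grid)
        w = grid.world_coordinates()
        expected = (w[1, 2, 2] + w[3, 2, 2]) / 2
        assert np.allclose(center_of_gravity(lm, MEC, "both"), expected)

    def test_translation_equivariance(self):
        grid = centered_grid((7, 7, 7))
        lm = labelmap({MEC: [(1, 1, 1), (2, 3, 4), (5, 5, 5)]}, affine_grid=grid)
        shifted_affine = grid.affine.copy()
        shifted_affine[:3, 3] += (3.0, -2.0, 7.5)
        shifted = SegmentationLabelMap(
            grid=type(grid)(data=lm.grid.data, affine=shifted_affine),
            approach="t",
        )
        delta = center_of_gravity(shifted, MEC, "both") - center_of_gravity(
            lm, MEC, "both"
        )
        assert np.allclose(delta, (3.0, -2.0, 7.5))

    def test_empty_label_is_degenerate(self):
        lm = labelmap({MEC: [(1, 1, 1)]})
        with pytest.raises(DegenerateSegmentationError):
            center_of_gravity(lm, LEC, "both")


class TestAxisAngle:
    def test_parallel_is_zero(self):
        assert axis_angle((0, 2, 0), (0, 1, 0)) == pytest.approx(0.0)

    def test_orthogonal_is_ninety(self):
        assert axis_angle((1, 0, 0), (0, 1, 0)) == pytest.approx(90.0)

    def test_equal_components_is_forty_five_to_both(self):
        v = (1, 1, 0)
        assert axis_angle(v, (0, 1, 0)) == pytest.approx(45.0)
        assert axis_angle(v, (1, 0, 0)) == pytest.approx(45.0)

    def test_sign_free(self):
        assert axis_angle((0, -3, 0), (0, 1, 0)) == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateSegmentationError):
            axis_angle((0, 0, 0), (0, 1, 0))


class TestAngleToPercentage:
    def test_endpoints_exact(self):
        assert angle_to_percentage(0.0) == 100.0
        assert angle_to_percentage(90.0) == 0.0

    @pytest.mark.parametrize("angle, pct", [(45.1, 49.9), (84.5, 6.1),
                                            (29.8, 66.9), (6.8, 92.4)])
    def test_published_conversion_pairs(self, angle, pct):
        assert round(angle_to_percentage(angle), 1) == pct

    def test_strictly_decreasing(self):
        angles = np.linspace(0, 90, 91)
        pcts = [angle_to_percentage(a) for a in angles]
        assert all(p1 > p2 for p1, p2 in zip(pcts, pcts[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            angle_to_percentage(91.0)
        with pytest.raises(ParameterError):
            angle_to_percentage(-1.0)


class TestBorderOrientation:
    def _bilateral_labelmap(self, rot_deg=0.0):
        """Mirror-symmetric MEC posterior / LEC anterior blobs, both sides."""
        grid = centered_grid((16, 16, 10))
        data = np.zeros(grid.shape, dtype=int)
        x = grid.world_coordinates()[..., 0]
        y = grid.world_coordinates()[..., 1]
        side = {True: x > 0, False: x < 0}
        for is_right in (True, False):
            data[side[is_right] & (np.abs(x) > 2) & (y < -1)] = MEC
            data[side[is_right] & (np.abs(x) > 2) & (y > 1)] = LEC
        return SegmentationLabelMap(grid=grid.with_data(data), approach="t")

    def test_mirror_symmetry_gives_zero_mad(self):
        res = border_orientation(self._bilateral_labelmap())
        left, right = res.hemispheres["left"], res.hemispheres["right"]
        assert left.angle_pa == pytest.approx(right.angle_pa, abs=1e-9)
        assert res.summary["angle_pa"][1] == pytest.approx(0.0, abs=1e-9)
        assert res.summary["pct_pa"][0] == pytest.approx(100.0)

    def test_two_value_summary(self):
        assert two_value_mad(48.0, 52.0) == 2.0
        res_mean = (48.0 + 52.0) / 2
        assert res_mean == 50.0

    def test_percentage_angle_relation_exact(self):
        res = border_orientation(self._bilateral_labelmap())
        for h in res.hemispheres.values():
            assert h.pct_pa == pytest.approx((1 - h.angle_pa / 90) * 100)
            assert h.pct_ml == pytest.approx((1 - h.angle_ml / 90) * 100)
            assert 0 <= h.angle_pa <= 90 and 0 <= h.pct_pa <= 100

    def test_rotation_equivariance(self):
        """Rotating label map and frame together leaves the angles unchanged."""
        lm = self._bilateral_labelmap()
        theta = math.radians(25.0)
        rot = np.array([
            [math.cos(theta), -math.sin(theta), 0],
            [math.sin(theta), math.cos(theta), 0],
            [0, 0, 1],
        ])
        affine = lm.grid.affine.copy()
        affine[:3, :3] = rot @ affine[:3, :3]
        affine[:3, 3] = rot @ affine[:3, 3]
        rotated = SegmentationLabelMap(
            grid=type(lm.grid)(data=lm.grid.data, affine=affine), approach="t"
        )
        frame = AxisFrame()
        rot_frame = AxisFrame(
            pa_axis=rot @ frame.pa_axis,
            ml_axis_right=rot @ frame.ml_axis_right,
            midline_normal=rot @ frame.midline_normal,
        )
        base = border_orientation(lm, frame)
        moved = border_orientation(rotated, rot_frame)
        for hemi in ("left", "right"):
            assert moved.hemispheres[hemi].angle_pa == pytest.approx(
                base.hemispheres[hemi].angle_pa, abs=1e-6
            )
            assert moved.hemispheres[hemi].angle_ml == pytest.approx(
                base.hemispheres[hemi].angle_ml, abs=1e-6
            )

    def test_quarter_turn_swaps_pa_and_ml_percentages(self):
        """90 deg about SI with the frame fixed swaps %PA and %ML when the
        CoG vector has no SI component."""
        lm = self._bilateral_labelmap()
        base = border_orientation(lm, hemispheres=("right",))
        h = base.hemispheres["right"]
        assert abs(h.cog_vector[2]) < 1e-9
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        affine = lm.grid.affine.copy()
        affine[:3, :3] = rot @ affine[:3, :3]
        affine[:3, 3] = rot @ affine[:3, 3]
        rotated = SegmentationLabelMap(
            grid=type(lm.grid)(data=lm.grid.data, affine=affine), approach="t"
        )
        # the right-hemisphere blob now sits at +y; select it via a frame
        # whose midline separates along y
        sideways = AxisFrame(pa_axis=(0, 1, 0), ml_axis_right=(1, 0, 0),
                             midline_normal=(0, 1, 0))
        moved = border_orientation(rotated, hemispheres=("right",),
                                   frame=sideways)
        m = moved.hemispheres["right"]
        assert m.pct_pa == pytest.approx(h.pct_ml, abs=1e-6)
        assert m.pct_ml == pytest.approx(h.pct_pa, abs=1e-6)

    def test_single_hemisphere_mode_omits_summary(self):
        res = border_orientation(self._bilateral_labelmap(),
                                 hemispheres=("left",))
        assert res.summary is None
        assert set(res.hemispheres) == {"left"}


class TestParameterRecovery:
    @pytest.mark.parametrize("theta", [0.0, 30.0, 45.0, 60.0, 90.0])
    def test_noise_free_cohort_recovers_theta(self, tiny_spec, theta):
        import dataclasses

        spec = dataclasses.replace(tiny_spec, theta_true=theta,
                                   n_participants=1)
        subject = make_cohort(spec)[0]
        lm = segment_participant(subject, "presubiculum/dCA1pSub")
        res = border_orientation(lm)
        assert res.summary["angle_pa"][0] == pytest.approx(theta, abs=3.0)
        assert res.summary["pct_pa"][0] == pytest.approx(
            angle_to_percentage(theta), abs=4.0
        )
        assert res.summary["pct_ml"][0] == pytest.approx(
            angle_to_percentage(90.0 - theta), abs=4.0
        )


class TestSizeReport:
    def _flat_labelmap(self, mec_n, lec_n):
        total = mec_n + lec_n
        data = np.array([MEC] * mec_n + [LEC] * lec_n).reshape(total, 1, 1)
        grid = centered_grid((total, 1, 1), voxel_mm=0.5)
        return SegmentationLabelMap(grid=grid.with_data(data), approach="t")

    @pytest.mark.parametrize("mec_n, lec_n, ratio",
                             [(12_759, 7_763, 1.64), (3_776, 11_008, 0.34),
                              (100, 100, 1.00)])
    def test_counts_and_ratio(self, mec_n, lec_n, ratio):
        rep = size_report(self._flat_labelmap(mec_n, lec_n))
        assert (rep.mec_voxels, rep.lec_voxels) == (mec_n, lec_n)
        assert round(rep.ratio, 2) == ratio

    def test_empty_lec_gives_undefined_ratio(self):
        rep = size_report(self._flat_labelmap(10, 0))
        assert rep.ratio is None

    @settings(max_examples=25, deadline=None)
    @given(mec_n=st.integers(1, 400), lec_n=st.integers(1, 400))
    def test_ratio_antisymmetry(self, mec_n, lec_n):
        """Swapping the labels maps the ratio r to exactly 1/r."""
        fwd = size_report(self._flat_labelmap(mec_n, lec_n))
        rev = size_report(self._flat_labelmap(lec_n, mec_n))
        assert rev.ratio == pytest.approx(1.0 / fwd.ratio, rel=1e-12)


class TestReferenceTables:
    def test_all_consistent_percentages_reproduced(self):
        for approach, row in REFERENCE_ANGLES.items():
            for axis in ("pa", "ml"):
                if (approach, axis) not in ANGLE_ROWS_CONSISTENT:
                    continue
                angle, _ = row[f"angle_{axis}"]
                pct, _ = row[f"pct_{axis}"]
                assert round(angle_to_percentage(angle), 1) == pct, (
                    approach, axis)

    def test_all_size_ratios_reproduced(self):
        for approach, (mec_n, lec_n, printed) in REFERENCE_SIZES.items():
            rep = size_report(self._tiny(mec_n, lec_n))
            assert round(rep.ratio, 2) == printed, approach

    def _tiny(self, mec_n, lec_n):
        total = mec_n + lec_n
        data = np.array([MEC] * mec_n + [LEC] * lec_n).reshape(total, 1, 1)
        grid = centered_grid((total, 1, 1), voxel_mm=0.5)
        return SegmentationLabelMap(grid=grid.with_data(data), approach="t")
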