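"""Body axis, heading, paw splitting, digit ordering and spread measurement."""

import math

import numpy as np
import pytest

from ssipaw import (PipelineConfig, RoiPolygon, SceneSpec, SpreadPair,
                    assign_roles, body_axis, measure_paw, order_digits,
                    process_frames, record_from_spreads, render_frame,
                    resolve_heading, split_paws, toe_spreads)
from ssipaw.geometry import MISSING_DIGITS, OK, PAW_NOT_VISIBLE
from ssipaw.segmentation import DigitCandidate


def ellipse_mask(shape, center, a, b, angle_deg=0.0):
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    t = math.radians(angle_deg)
    dx, dy = xs - center[0], ys - center[1]
    along = dx * math.cos(t) + dy * math.sin(t)
    across = -dx * math.sin(t) + dy * math.cos(t)
    return (along / a) ** 2 + (across / b) ** 2 <= 1.0


def angle_of(direction) -> float:
    """Absolute angle (deg, mod 180) of an axis direction."""
    return math.degrees(math.atan2(direction[1], direction[0])) % 180.0


def candidates_at(points, areas=None):
    areas = areas if areas is not None else [100] * len(points)
    return [DigitCandidate(centroid=(float(x), float(y)), area=int(a), mean_intensity=200.0)
            for (x, y), a in zip(points, areas)]


class TestBodyAxis:
    def test_horizontal_ellipse(self):
        mask = ellipse_mask((300, 400), (200, 150), 100, 30)
        axis = body_axis(mask)
        assert angle_of(axis.direction) == pytest.approx(0.0, abs=2.0)
        assert axis.centroid == pytest.approx((200, 150), abs=0.5)
        assert not axis.degenerate
        # moment-equivalent full major-axis length of a solid ellipse is 2a
        assert axis.axis_length == pytest.approx(200.0, rel=0.05)

    def test_rotated_ellipse(self):
        mask = ellipse_mask((400, 400), (200, 200), 120, 40, angle_deg=30.0)
        axis = body_axis(mask)
        assert angle_of(axis.direction) == pytest.approx(30.0, abs=2.0)

    def test_circle_flagged_degenerate(self):
        mask = ellipse_mask((200, 200), (100, 100), 50, 50)
        assert body_axis(mask).degenerate

    def test_empty_mask_is_error(self):
        with pytest.raises(ValueError):
            body_axis(np.zeros((10, 10), bool))

    def test_direction_is_unit_and_deterministic(self):
        mask = ellipse_mask((300, 400), (200, 150), 100, 30, angle_deg=10.0)
        a, b = body_axis(mask), body_axis(mask)
        assert np.hypot(*a.direction) == pytest.approx(1.0)
        assert a.direction == b.direction


class TestResolveHeading:
    def setup_method(self):
        mask = ellipse_mask((400, 600), (300, 200), 150, 50)
        self.axis = body_axis(mask)  # horizontal, centroid (300, 200)

    def test_digits_on_left_point_heading_right(self):
        digits = np.array([[150.0, 150.0 + 10 * k] for k in range(5)])
        axis = resolve_heading(self.axis, digits)
        assert axis.heading @ np.array([1.0, 0.0]) > 0.9

    def test_mirrored_digits_flip_heading(self):
        digits = np.array([[450.0, 150.0 + 10 * k] for k in range(5)])
        axis = resolve_heading(self.axis, digits)
        assert axis.heading @ np.array([-1.0, 0.0]) > 0.9

    def test_straddling_digits_are_ambiguous(self):
        digits = np.array([[299.0, 100.0], [301.0, 100.0], [299.0, 300.0],
                           [301.0, 300.0], [300.0, 150.0]])
        axis = resolve_heading(self.axis, digits)
        assert axis.ambiguous and axis.heading_sign is None


class TestSplitPaws:
    def setup_method(self):
        mask = ellipse_mask((400, 600), (300, 200), 150, 50)
        axis = body_axis(mask)
        self.axis = resolve_heading(axis, np.array([[120.0, 200.0]]))  # heading +x

    def test_clean_five_five_split(self):
        # heading +x, y down: animal-left has positive cross => larger y
        left_pts = [(150, 300 + 8 * k) for k in range(5)]
        right_pts = [(150, 60 + 8 * k) for k in range(5)]
        split = split_paws(candidates_at(left_pts + right_pts), self.axis)
        assert split.left_status == OK and split.right_status == OK
        assert {tuple(c.centroid) for c in split.left} == {(float(x), float(y)) for x, y in left_pts}

    def test_flip_lr_swaps_sides(self):
        pts = [(150, 300 + 8 * k) for k in range(5)]
        normal = split_paws(candidates_at(pts), self.axis)
        flipped = split_paws(candidates_at(pts), self.axis, flip_lr=True)
        assert normal.left and not normal.right
        assert flipped.right and not flipped.left

    def test_noise_blob_dropped_by_area(self):
        pts = [(150, 300 + 8 * k) for k in range(5)] + [(160, 340)]
        areas = [100] * 5 + [40]  # sixth blob is small noise
        split = split_paws(candidates_at(pts, areas), self.axis)
        assert split.left_status == OK
        assert len(split.left) == 5
        assert (160.0, 340.0) not in {tuple(c.centroid) for c in split.left}

    def test_one_empty_side_marked_not_visible(self):
        pts = [(150, 300 + 8 * k) for k in range(5)]
        split = split_paws(candidates_at(pts), self.axis)
        assert split.left_status == OK
        assert split.right_status == PAW_NOT_VISIBLE

    def test_four_candidates_marked_missing_digits(self):
        pts = [(150, 300 + 8 * k) for k in range(4)]
        split = split_paws(candidates_at(pts), self.axis)
        assert split.left_status == MISSING_DIGITS


class TestOrderDigits:
    def setup_method(self):
        mask = ellipse_mask((400, 600), (300, 200), 150, 50)
        self.axis = resolve_heading(body_axis(mask), np.array([[120.0, 200.0]]))

    def test_collinear_digits_ordered_along_line(self):
        pts = np.array([[150.0, 260.0 + 15 * k] for k in range(5)])
        shuffled = pts[[3, 0, 4, 1, 2]]
        assert np.allclose(order_digits(shuffled, self.axis), pts)

    def test_reflected_paw_orders_consistently(self):
        """Mirroring about the body axis preserves anatomical digit indices."""
        pts = np.array([[150.0, 260.0 + 15 * k] for k in range(5)])
        mirrored = pts.copy()
        mirrored[:, 1] = 2 * 200.0 - mirrored[:, 1]  # reflect about y=200
        ordered = order_digits(pts, self.axis)
        ordered_m = order_digits(mirrored, self.axis)
        assert np.allclose(ordered_m[:, 1], 2 * 200.0 - ordered[:, 1])

    def test_arc_paw_matches_renderer_indices(self):
        spec = SceneSpec.default(frame_size=(960, 540), ts_o=35.0, its_o=20.0,
                                 noise_sd=0.0, jitter_sd=0.0)  # curved arc layout
        _, gt = render_frame(spec, 0)
        mask = gt.body_mask
        axis = resolve_heading(body_axis(mask),
                               np.array([d[2:] for d in gt.digits]))
        truth = gt.side_centroids("left")
        ordered = order_digits(truth[[4, 2, 0, 3, 1]], axis)
        assert np.allclose(ordered, truth)

    def test_requires_exactly_five(self):
        with pytest.raises(ValueError):
            order_digits(np.zeros((4, 2)), self.axis)


class TestToeSpreads:
    def test_coordinate_example(self):
        digits = np.array([(0, 0), (1, 2), (2, 3), (3, 2), (4, 0)], float)
        ts, its = toe_spreads(digits)
        assert ts == pytest.approx(4.0)
        assert its == pytest.approx(2.0)

    def test_coincident_digits_measure_zero(self):
        ts, its = toe_spreads(np.ones((5, 2)))
        assert ts == 0.0 and its == 0.0


class TestAssignRoles:
    def make_paws(self):
        mask = ellipse_mask((400, 600), (300, 200), 150, 50)
        axis = resolve_heading(body_axis(mask), np.array([[120.0, 200.0]]))
        left = measure_paw(candidates_at([(150, 280 + 12 * k) for k in range(5)]), axis, "left")
        right = measure_paw(candidates_at([(150, 72 + 9 * k) for k in range(5)]), axis, "right")
        return left, right

    def test_operated_left(self):
        left, right = self.make_paws()
        operated, control = assign_roles(left, right, "left")
        assert operated.side == "left" and operated.role == "operated"
        assert control.side == "right" and control.role == "control"
        assert operated.ts == pytest.approx(48.0)  # left spread becomes TSo
        assert control.ts == pytest.approx(36.0)

    def test_missing_paw_is_error(self):
        left, _ = self.make_paws()
        with pytest.raises(ValueError, match="PAW_NOT_VISIBLE"):
            assign_roles(left, None, "left")


class TestChainInvariances:
    """Geometric invariances of the full digit-to-SSI chain."""

    @staticmethod
    def chain_ssi(digit_points, body_pts_mask, operated_side="left"):
        axis = resolve_heading(body_axis(body_pts_mask),
                               np.array([c.centroid for c in digit_points]))
        split = split_paws(digit_points, axis)
        left = measure_paw(split.left, axis, "left")
        right = measure_paw(split.right, axis, "right")
        operated, control = assign_roles(left, right, operated_side)
        pair = SpreadPair(ts_o=operated.ts, ts_c=control.ts,
                          its_o=operated.its, its_c=control.its)
        return record_from_spreads(0, pair).ssi

    def scene_ssi(self, heading_deg, center, operated_side="left", flip=False):
        spec = SceneSpec.default(frame_size=(960, 540), heading_deg=heading_deg,
                                 body_center=center, noise_sd=0.0, jitter_sd=0.0,
                                 operated_side=operated_side)
        _, gt = render_frame(spec, 0)
        cands = candidates_at([(x, y) for _, _, x, y in gt.digits])
        return self.chain_ssi(cands, gt.body_mask, operated_side)

    def test_rigid_rotation_and_translation_leave_ssi_unchanged(self):
        base = self.scene_ssi(0.0, (480.0, 270.0))
        for angle, center in [(30.0, (500.0, 260.0)), (-45.0, (450.0, 280.0)),
                              (120.0, (480.0, 290.0))]:
            assert self.scene_ssi(angle, center) == pytest.approx(base, abs=1e-6)

    def test_mirroring_and_swapping_operated_side_leaves_ssi_unchanged(self):
        """The renderer's operated_side relabels which paw carries the operated
        spreads, i.e. a mirrored animal; swapping the declared side compensates."""
        assert self.scene_ssi(0.0, (480.0, 270.0), "left") == pytest.approx(
            self.scene_ssi(0.0, (480.0, 270.0), "right"), abs=1e-9)

    def test_spreads_recovered_exactly_from_ground_truth_centroids(self):
        spec = SceneSpec.default(frame_size=(960, 540), noise_sd=0.0, jitter_sd=0.0)
        _, gt = render_frame(spec, 0)
        cands = candidates_at([(x, y) for _, _, x, y in gt.digits])
        ssi = self.chain_ssi(cands, gt.body_mask)
        assert ssi == pytest.approx(gt.expected_ssi, abs=1e-9)


class TestEndToEndRecovery:
    def test_per_frame_spreads_within_2px_of_ground_truth(self):
        spec = SceneSpec.default(frame_size=(960, 540), jitter_sd=0.5, seed=11)
        truths = {}
        frames = []
        from ssipaw.scenes import iter_frames

        for i, img, gt in iter_frames(spec, 12):
            truths[i] = gt
            frames.append((i, img))
        res = process_frames(frames, RoiPolygon.full_frame(960, 540), PipelineConfig())
        assert res.summary.n_frames_labeled == 12
        # tolerance 2 px at 1080p-equivalent scales to 1 px at half resolution
        for r in res.records:
            gt = truths[r.frame_index]
            left = gt.side_centroids("left")
            ts_truth = np.linalg.norm(left[0] - left[4])
            assert abs(r.spreads.ts_o - ts_truth) <= 1.0
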