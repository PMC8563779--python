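"""Segment fitting, generation and rigid alignment."""

import numpy as np
import pytest

from shapechain import (
    align_segment_to_portion,
    extract_portion,
    fit_c_segment,
    fit_g_segment,
    fit_h_segment,
    fit_m_segment,
    generate_segment_points,
)
from shapechain.errors import DegeneracyError, DimensionError, HomologyError
from shapechain.segments import SegmentModel, _helix_points


def rot2(theta):
    return np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )


class TestExtractPortion:
    def test_inclusive_boundaries(self, line_target):
        pts = extract_portion(line_target, (1, 4))
        assert len(pts) == 4  # 3 pieces

    def test_full_profile(self, line_target):
        pts = extract_portion(line_target, (1, line_target.n_points))
        assert np.array_equal(pts, line_target.points)

    def test_adjacent_portions_share_a_point(self, line_target):
        a = extract_portion(line_target, (1, 5))
        b = extract_portion(line_target, (5, 9))
        assert np.array_equal(a[-1], b[0])

    def test_out_of_range(self, line_target):
        with pytest.raises(IndexError):
            extract_portion(line_target, (0, 5))


class TestMSegment:
    def test_identical_portions_under_rigid_motion(self):
        base = _helix_points(0.1, 0.0, 1.0, 8, 2)
        moved = base @ rot2(0.9).T + [4.0, -2.0]
        model = fit_m_segment([base, moved], 1.0)
        gen = generate_segment_points(model, 8)
        aligned = align_segment_to_portion(gen, base)
        assert aligned.error < 1e-6

    def test_single_portion_is_identity(self):
        base = _helix_points(0.05, 0.0, 1.0, 6, 2)
        model = fit_m_segment([base], 1.0)
        aligned = align_segment_to_portion(model.template, base)
        assert aligned.error < 1e-9

    def test_mirror_arcs_mean_between(self):
        # two mirror-symmetric arcs: the rigid mean is flatter than either,
        # its arc length between the chord length and the arc length
        arc = _helix_points(0.3, 0.0, 1.0, 10, 2)
        mirror = arc * [1.0, -1.0]
        model = fit_m_segment([arc, mirror], 1.0)
        from shapechain.profiles import arc_length

        chord = float(np.linalg.norm(arc[-1] - arc[0]))
        assert chord - 1e-9 <= arc_length(model.template) <= arc_length(arc) + 1e-9

    def test_unequal_counts_raise(self):
        a = _helix_points(0.1, 0.0, 1.0, 5, 2)
        b = _helix_points(0.1, 0.0, 1.0, 6, 2)
        with pytest.raises(HomologyError):
            fit_m_segment([a, b], 1.0)


class TestCSegment:
    def test_arcs_of_radius_five(self):
        portions = [
            _helix_points(0.2, 0.0, 1.0, m, 2) @ rot2(t).T
            for m, t in [(10, 0.0), (14, 0.5), (12, -1.2)]
        ]
        model = fit_c_segment(portions, 1.0)
        assert model.kappa == pytest.approx(0.2, abs=1e-9)

    def test_straight_lines_zero_curvature(self):
        line = np.column_stack([np.arange(8.0), np.zeros(8)])
        model = fit_c_segment([line], 1.0)
        assert model.kappa == 0.0
        gen = generate_segment_points(model, 5)
        assert np.allclose(gen[:, 1], 0.0)
        assert len(gen) == 6

    def test_torsion_in_2d_rejected(self):
        line3 = np.column_stack([np.arange(8.0), np.zeros(8), np.zeros(8)])
        with pytest.raises(DimensionError):
            fit_c_segment([line3], 1.0)

    def test_generated_arc_lies_on_circle(self):
        model = SegmentModel(type="C", piece_length=1.0, dimension=2, kappa=0.2)
        gen = generate_segment_points(model, 25)
        center = np.array([0.0, 5.0])
        radii = np.linalg.norm(gen - center, axis=1)
        assert np.abs(radii - 5.0).max() < 1e-6


class TestHSegment:
    @pytest.mark.parametrize(
        "r,c",
        [(1.0, 0.0), (1.0, 0.5), (2.0, 1.0)],
        ids=["circle", "helix", "wide-helix"],
    )
    def test_roundtrip_parameter_recovery(self, r, c):
        # true helix geometry: kappa = r/(r^2+c^2), tau = c/(r^2+c^2)
        kappa = r / (r * r + c * c)
        tau = c / (r * r + c * c)
        h = 0.05
        pts = _helix_points(kappa, tau, h, 200, 3)
        model = fit_h_segment([pts], h)
        # discretization error is O(h^2)
        assert model.kappa == pytest.approx(kappa, abs=10 * h * h)
        assert model.tau == pytest.approx(tau, abs=10 * h * h)

    def test_straight_3d(self):
        line = np.column_stack([np.arange(8.0), np.zeros(8), np.zeros(8)])
        model = fit_h_segment([line], 1.0)
        assert model.kappa == 0.0 and model.tau == 0.0

    def test_chord_lengths_uniform(self):
        model = SegmentModel(
            type="H", piece_length=0.5, dimension=3, kappa=0.8, tau=0.4
        )
        gen = generate_segment_points(model, 30)
        steps = np.linalg.norm(np.diff(gen, axis=0), axis=1)
        assert np.abs(steps - 0.5).max() < 1e-8

    def test_too_few_points(self):
        pts = np.zeros((3, 3))
        pts[:, 0] = [0, 1, 2]
        with pytest.raises(DegeneracyError):
            fit_h_segment([pts], 1.0)


class TestGSegment:
    def test_scale_pair_recovers_template(self):
        base = _helix_points(0.15, 0.0, 1.0, 12, 2)
        model = fit_g_segment([base, 2.0 * base], 1.0)
        gen = generate_segment_points(model, 12)
        aligned = align_segment_to_portion(gen, base)
        assert aligned.error < 1e-4

    def test_single_portion_normalized(self):
        base = _helix_points(0.1, 0.0, 1.0, 9, 2)
        model = fit_g_segment([base], 1.0)
        from shapechain.profiles import arc_length

        assert arc_length(model.template) == pytest.approx(1.0)

    def test_known_generator_random_poses(self):
        rng = np.random.default_rng(5)
        base = _helix_points(0.12, 0.0, 1.0, 15, 2)
        portions = [
            float(rng.uniform(0.5, 3.0)) * base @ rot2(rng.uniform(-np.pi, np.pi)).T
            + rng.normal(0, 10, 2)
            for _ in range(5)
        ]
        model = fit_g_segment(portions, 1.0)
        gen = generate_segment_points(model, 15)
        aligned = align_segment_to_portion(gen, base)
        assert aligned.error < 1e-4

    def test_generated_chords_equal(self):
        base = _helix_points(0.15, 0.0, 1.0, 12, 2)
        model = fit_g_segment([base], 2.0)
        gen = generate_segment_points(model, 7)
        steps = np.linalg.norm(np.diff(gen, axis=0), axis=1)
        assert np.abs(steps - 2.0).max() < 0.01 * 2.0


class TestAlignment:
    def test_rigid_motion_gives_zero_error(self):
        rng = np.random.default_rng(0)
        seg = rng.normal(size=(9, 3))
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=1).as_matrix()
        portion = seg @ R.T + [1.0, 2.0, 3.0]
        aligned = align_segment_to_portion(seg, portion)
        assert aligned.error < 1e-9

    def test_matches_rotation_grid_oracle(self):
        # independent brute-force: scan rotations at 1e-4 rad in 2D
        rng = np.random.default_rng(3)
        seg = rng.normal(size=(6, 2))
        portion = seg.copy()
        portion[2] += [0.3, -0.1]
        aligned = align_segment_to_portion(seg, portion)

        sc = seg - seg.mean(axis=0)
        pc = portion - portion.mean(axis=0)
        best = np.inf
        for theta in np.arange(-np.pi, np.pi, 1e-4):
            ssd = ((sc @ rot2(theta).T - pc) ** 2).sum()
            if ssd < best:
                best = ssd
        got = ((aligned.points - portion) ** 2).sum()
        assert got <= best + 1e-7

    def test_error_invariant_to_common_rigid_motion(self):
        rng = np.random.default_rng(4)
        seg = rng.normal(size=(7, 2))
        portion = seg + rng.normal(0, 0.1, seg.shape)
        e0 = align_segment_to_portion(seg, portion).error
        R = rot2(2.2)
        e1 = align_segment_to_portion(seg @ R.T + 5, portion @ R.T + 5).error
        assert e0 == pytest.approx(e1, abs=1e-9)

    def test_no_reflection(self):
        # mirror-image portion must NOT align perfectly (det +1 enforced)
        seg = np.array([[0, 0], [1, 0], [1, 1], [2, 1.0]])
        mirrored = seg * [1.0, -1.0]
        aligned = align_segment_to_portion(seg, mirrored)
        assert aligned.error > 0.1
        assert np.linalg.det(aligned.rotation) == pytest.approx(1.0)

    def test_optimality_under_small_rotations(self):
        rng = np.random.default_rng(6)
        seg = rng.normal(size=(8, 2))
        portion = seg + rng.normal(0, 0.2, seg.shape)
        aligned = align_segment_to_portion(seg, portion)
        base_ssd = ((aligned.points - portion) ** 2).sum()
        pc = portion.mean(axis=0)
        for dtheta in (-0.01, -0.003, 0.003, 0.01):
            tweaked = (aligned.points - pc) @ rot2(dtheta).T + pc
            assert ((tweaked - portion) ** 2).sum() >= base_ssd - 1e-12

    def test_count_mismatch(self):
        with pytest.raises(HomologyError):
            align_segment_to_portion(np.zeros((4, 2)), np.zeros((5, 2)))
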