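"""Relative angles, apex detection, GA placement and the segment matrix."""

import itertools

import numpy as np
import pytest

from shapechain import (
    SegmentationPoints,
    apex_count_sweep,
    detect_apices,
    place_supplementary_points,
    build_segment_matrix,
    relative_angle,
)
from shapechain.errors import ConfigurationError, HomologyError
from shapechain.profiles import TargetProfile
from shapechain.segmentation import (
    GASettings,
    evenness_fitness,
    evenness_lower_bound,
    relative_angles,
)
from shapechain.synthetic import LeafSpec, generate_leaflike

from conftest import regular_polygon_target


class TestRelativeAngle:
    def test_collinear_is_zero(self, line_target):
        assert relative_angle(line_target, 5, 1) == pytest.approx(0.0)

    def test_right_angle(self):
        prof = TargetProfile(
            "L", np.array([[0, 0], [1, 0], [1, 1], [1, 2.0]]), 1.0
        )
        assert relative_angle(prof, 2, 1) == pytest.approx(90.0)

    @pytest.mark.parametrize("n", [5, 8, 12, 36])
    def test_regular_polygon_exterior_angle(self, n):
        prof = regular_polygon_target(n)
        assert relative_angle(prof, 3, 1) == pytest.approx(360.0 / n, abs=1e-8)

    def test_out_of_range_open(self, line_target):
        with pytest.raises(IndexError):
            relative_angle(line_target, 1, 1)

    def test_closed_wraps_through_seam(self, square_target):
        # point 1 of the square sits on a corner: same angle as any corner
        assert relative_angle(square_target, 1, 1) == pytest.approx(90.0)

    def test_rigid_motion_and_scale_invariance(self):
        # unit steps with random turning: every chord has length exactly 1
        rng = np.random.default_rng(0)
        headings = np.cumsum(rng.normal(0.0, 0.3, size=20))
        steps = np.column_stack([np.cos(headings), np.sin(headings)])
        pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        prof = TargetProfile("x", pts, 1.0)
        theta = 1.1
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = TargetProfile("y", 3.7 * pts @ R.T + [5, -2], 3.7)
        for i in (4, 9, 15):
            assert relative_angle(prof, i, 2) == pytest.approx(
                relative_angle(moved, i, 2), abs=1e-8
            )


class TestDetectApices:
    def test_square_corners(self, square_target):
        assert detect_apices(square_target, 1, 45.0) == [1, 11, 21, 31]

    def test_circle_empty(self, circle_target):
        assert detect_apices(circle_target, 1, 90.0) == []

    def test_apices_are_above_threshold(self, square_target):
        idx, angles = relative_angles(square_target, 1)
        for a in detect_apices(square_target, 1, 45.0):
            assert angles[list(idx).index(a)] >= 45.0

    def test_burred_star_tips(self):
        leaves, truth = generate_leaflike(LeafSpec(seed=0, p=1, piece_length=2.0))
        prof = leaves[0]
        apices = detect_apices(prof, 20, 60.0)
        assert len(apices) == 5
        # each detected apex sits near a true lobe tip
        for a in apices:
            assert min(
                min(abs(a - t), prof.n_pieces - abs(a - t))
                for t in truth.tip_indices[0]
            ) <= 5

    def test_sweep_square_constant(self, square_target):
        counts = apex_count_sweep(square_target, [1, 2, 3, 4, 5], 45.0)
        assert (counts == 4).all()

    def test_sweep_circle_zero(self, circle_target):
        assert (apex_count_sweep(circle_target, [1, 2, 3], 90.0) == 0).all()

    def test_sweep_burred_star_stabilizes_at_lobe_count(self):
        leaves, _ = generate_leaflike(LeafSpec(seed=2, p=1, piece_length=2.0))
        counts = apex_count_sweep(leaves[0], [10, 15, 20, 25, 30], 60.0)
        assert (counts[-3:] == 5).all()


class TestSupplementaryPlacement:
    def test_exact_divisibility(self, line_target):
        sp = place_supplementary_points(line_target, [1, 13], 3, seed=0)
        assert sp.indices.tolist() == [1, 5, 9, 13]
        assert evenness_fitness(sp.indices, 13, 3) == 0.0

    def test_primaries_already_suffice(self, line_target):
        sp = place_supplementary_points(line_target, [1, 5, 9, 13], 3, seed=0)
        assert sp.indices.tolist() == [1, 5, 9, 13]
        assert sp.primary.all()

    def test_matches_exhaustive_optimum(self):
        pts = np.column_stack([np.arange(11.0), np.zeros(11)])
        prof = TargetProfile("t", pts, 1.0)
        sp = place_supplementary_points(prof, [1, 6, 11], 4, seed=3)
        got = evenness_fitness(sp.indices, 11, 4)
        free = [i for i in range(2, 11) if i != 6]
        best = min(
            evenness_fitness(np.array(sorted({1, 6, 11, *c})), 11, 4)
            for c in itertools.combinations(free, 2)
        )
        assert got == pytest.approx(best)

    @pytest.mark.parametrize("n_pieces,q", [(17, 5), (23, 4), (40, 7)])
    def test_attains_lower_bound_unconstrained(self, n_pieces, q):
        pts = np.column_stack([np.arange(n_pieces + 1.0), np.zeros(n_pieces + 1)])
        prof = TargetProfile("t", pts, 1.0)
        sp = place_supplementary_points(prof, [1, n_pieces + 1], q, seed=1)
        got = evenness_fitness(sp.indices, n_pieces + 1, q)
        assert got == pytest.approx(evenness_lower_bound(n_pieces, q))

    def test_never_worse_than_even_heuristic(self):
        rng = np.random.default_rng(7)
        pts = np.column_stack([np.arange(61.0), np.zeros(61)])
        prof = TargetProfile("t", pts, 1.0)
        from shapechain.segmentation import _even_heuristic

        for _ in range(5):
            prim = sorted(
                {1, 61, *rng.choice(np.arange(5, 58), size=2, replace=False)}
            )
            q = len(prim) - 1 + 3
            sp = place_supplementary_points(prof, prim, q, seed=int(rng.integers(1000)))
            heur = _even_heuristic(np.asarray(prim), 61, q)
            assert evenness_fitness(sp.indices, 61, q) <= evenness_fitness(
                heur, 61, q
            ) + 1e-12

    def test_deterministic_for_fixed_seed(self, line_target):
        a = place_supplementary_points(line_target, [1, 13], 5, seed=42)
        b = place_supplementary_points(line_target, [1, 13], 5, seed=42)
        assert a.indices.tolist() == b.indices.tolist()

    def test_infeasible_q(self, line_target):
        with pytest.raises(ConfigurationError):
            place_supplementary_points(line_target, [1, 13], 13, seed=0)


class TestSegmentMatrix:
    def test_row_from_cumulative_boundaries(self):
        # boundary indices are the cumulative piece sums plus one
        b = np.array([1, 208, 298, 805, 935, 1033, 1132])
        sp = SegmentationPoints("j1", b, np.ones(7, dtype=bool))
        assert sp.piece_counts().tolist() == [207, 90, 507, 130, 98, 99]

    def test_single_segment(self):
        sp = SegmentationPoints("x", np.array([1, 12]), np.array([True, True]))
        m = build_segment_matrix([sp], ["G"])
        assert m.entries.tolist() == [[11]]

    def test_row_sums_preserved(self):
        sps = [
            SegmentationPoints("a", np.array([1, 5, 9, 13]), np.array([1, 0, 0, 1], bool)),
            SegmentationPoints("b", np.array([1, 4, 9, 13]), np.array([1, 0, 0, 1], bool)),
        ]
        m = build_segment_matrix(sps, ["G", "G", "G"], [13, 13])
        assert (m.entries.sum(axis=1) == 12).all()

    def test_m_column_equalized_from_neighbors(self):
        # M column differs by one; the neighboring G column absorbs it
        sps = [
            SegmentationPoints("a", np.array([1, 6, 13]), np.array([1, 0, 1], bool)),
            SegmentationPoints("b", np.array([1, 7, 13]), np.array([1, 0, 1], bool)),
        ]
        m = build_segment_matrix(sps, ["M", "G"], [13, 13])
        assert len(set(m.entries[:, 0])) == 1
        assert (m.entries.sum(axis=1) == 12).all()

    def test_m_column_unfixable_raises(self):
        sps = [
            SegmentationPoints("a", np.array([1, 6, 11]), np.array([1, 0, 1], bool)),
            SegmentationPoints("b", np.array([1, 7, 13]), np.array([1, 0, 1], bool)),
        ]
        with pytest.raises(HomologyError, match="b|a"):
            build_segment_matrix(sps, ["M", "M"], [11, 13])

    def test_matrix_invariants(self):
        with pytest.raises(HomologyError):
            from shapechain.segmentation import SegmentMatrix

            SegmentMatrix(
                entries=np.array([[3, 0]]),
                type_vector=("G", "G"),
                profile_ids=("a",),
            )
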