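"""Feature extraction: orientation differences, length ratios, directions."""

import numpy as np
import pytest

from shapechain import (
    assemble_features,
    build_chain,
    count_analysis_variables,
    count_fitting_variables,
    length_ratio,
    orientation_difference_2d,
    segment_direction_3d,
)
from shapechain.errors import DimensionError
from shapechain.segmentation import SegmentMatrix
from shapechain.synthetic import (
    ChainSpec,
    SutureSpec,
    generate_chain_profiles,
    generate_suturelike,
)


def chain_2d(p=3, seed=0, **kw):
    spec = ChainSpec(seed=seed, p=p, noise_sd=0.0, **kw)
    profiles, truth = generate_chain_profiles(spec)
    sm = SegmentMatrix(
        np.array([np.diff(b) for b in truth.boundaries]),
        truth.type_vector,
        tuple(pr.id for pr in profiles),
    )
    return build_chain(profiles, segment_matrix=sm), truth


def chain_3d(seed=0):
    profiles, anchors = generate_suturelike(
        SutureSpec(seed=seed, p_per_group=3, noise_sd=0.0)
    )
    counts = np.array([[pr.n_pieces // 2, pr.n_pieces - pr.n_pieces // 2]
                       for pr in profiles])
    sm = SegmentMatrix(counts, ("G", "H"), tuple(pr.id for pr in profiles))
    return build_chain(profiles, segment_matrix=sm), anchors


class TestOrientationDifference:
    def test_straight_chain_zero(self):
        spec = ChainSpec(
            seed=0, p=2, type_vector=("G", "G"),
            group_angles={"A": (0.0,)}, group_lengths={"A": (30.0, 30.0)},
            angle_sd=0.0, length_sd=0.0, noise_sd=0.0,
        )
        profiles, truth = generate_chain_profiles(spec)
        sm = SegmentMatrix(truth.piece_counts, ("G", "G"),
                           tuple(pr.id for pr in profiles))
        chain = build_chain(profiles, segment_matrix=sm)
        assert orientation_difference_2d(chain, 0, 0) == pytest.approx(0.0, abs=0.5)

    def test_recovers_known_joint_angles(self):
        chain, truth = chain_2d(p=4, seed=1, angle_sd=0.0)
        for j in range(chain.p):
            for e in range(chain.q - 1):
                got = orientation_difference_2d(chain, j, e)
                assert got == pytest.approx(truth.joint_angles[j, e], abs=2.0)

    def test_right_angle_sign(self):
        chain, truth = chain_2d(
            p=2, seed=2,
            group_angles={"A": (90.0, -90.0)}, group_lengths={"A": (40.0,)},
            angle_sd=0.0,
        )
        assert orientation_difference_2d(chain, 0, 0) == pytest.approx(90.0, abs=2.0)
        assert orientation_difference_2d(chain, 0, 1) == pytest.approx(-90.0, abs=2.0)

    def test_chain_of_q_segments_yields_q_minus_1_values(self):
        chain, _ = chain_2d(p=2, seed=3)
        table = assemble_features(chain)
        sig_cols = [c for c in table.columns if c.startswith("sigma_")]
        assert len(sig_cols) == chain.q - 1

    def test_3d_chain_rejected(self):
        chain, _ = chain_3d()
        with pytest.raises(DimensionError):
            orientation_difference_2d(chain, 0, 0)


class TestLengthRatio:
    def test_printed_column_pair(self):
        sm = SegmentMatrix(
            np.array([[90, 10], [115, 10]]), ("C", "M"), ("a", "b")
        )
        g = length_ratio(sm, 0)
        assert g == pytest.approx([90 / 115, 1.0])

    def test_all_equal_column(self):
        sm = SegmentMatrix(np.array([[7], [7], [7]]), ("G",), ("a", "b", "c"))
        assert (length_ratio(sm, 0) == 1.0).all()

    def test_m_column_rejected(self):
        sm = SegmentMatrix(np.array([[5, 6], [5, 7]]), ("M", "G"), ("a", "b"))
        with pytest.raises(DimensionError):
            length_ratio(sm, 0)

    def test_range_and_max_attained(self):
        sm = SegmentMatrix(
            np.array([[3, 9], [5, 4], [2, 6]]), ("G", "G"), ("a", "b", "c")
        )
        for e in (0, 1):
            g = length_ratio(sm, e)
            assert ((g > 0) & (g <= 1)).all()
            assert g.max() == 1.0


class TestDirections3D:
    def test_unit_norm(self):
        chain, _ = chain_3d()
        for e in range(chain.q):
            u = segment_direction_3d(chain, 0, e)
            assert np.linalg.norm(u) == pytest.approx(1.0, abs=1e-9)

    def test_rotation_equivariance(self):
        chain, _ = chain_3d(seed=4)
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=0).as_matrix()
        prof = chain.profiles[0]
        from shapechain.profiles import TargetProfile

        rotated = TargetProfile(
            id=prof.id, points=prof.points @ R.T,
            piece_length=prof.piece_length, group=prof.group,
        )
        sm = SegmentMatrix(
            chain.matrix.entries[:1], chain.matrix.type_vector, (prof.id,)
        )
        chain_0 = build_chain([prof], segment_matrix=sm)
        chain_r = build_chain([rotated], segment_matrix=sm)
        u0 = segment_direction_3d(chain_0, 0, 0)
        u1 = segment_direction_3d(chain_r, 0, 0)
        assert np.allclose(u1, R @ u0, atol=1e-6)

    def test_2d_chain_rejected(self):
        chain, _ = chain_2d()
        with pytest.raises(DimensionError):
            segment_direction_3d(chain, 0, 0)


class TestVariableCounting:
    def test_mandible_scheme(self):
        # 6 sub-profiles: four [M G M] and two [M C G M] = 20 segments,
        # 12 rigid, 2 arc, 6 scalable: 20 orientations + 8 lengths
        v = list("MGM" * 1) * 0
        v = (["M", "G", "M"] * 3
             + ["M", "C", "G", "M"] * 2
             + ["M", "G", "M"])
        assert len(v) == 20
        assert v.count("M") == 12 and v.count("C") == 2 and v.count("G") == 6
        assert count_fitting_variables(v, 2) == 28
        assert count_analysis_variables(v, 2) == 19

    def test_leaf_scheme(self):
        v = ["G"] * 35
        assert count_analysis_variables(v, 2, n_extra_scalars=3) == 37

    def test_suture_schemes(self):
        sagittal = ["M", "G", "M", "H", "M", "G"]
        coronal = ["M", "G", "H", "H", "G", "M"]
        lambdoid = ["G", "H", "H", "G"]
        assert count_fitting_variables(sagittal, 3) == 21
        assert count_fitting_variables(coronal, 3) == 22
        assert count_fitting_variables(lambdoid, 3) == 16
        assert count_analysis_variables(sagittal, 3) == 18
        assert count_analysis_variables(coronal, 3) == 18
        assert count_analysis_variables(lambdoid, 3, n_anchor_points=1) == 15


class TestAssembleFeatures:
    def test_column_layout_2d(self):
        chain, _ = chain_2d(p=3, seed=5)
        table = assemble_features(
            chain, include_length_ratios=True, include_arc_length=True
        )
        assert table.columns[0] == "group"
        assert sum(c.startswith("sigma_") for c in table.columns) == chain.q - 1
        n_free = sum(1 for t in chain.matrix.type_vector if t != "M")
        assert sum(c.startswith("g_") for c in table.columns) == n_free
        assert "arclen" in table.columns
        assert len(table) == chain.p

    def test_column_layout_3d_with_anchor(self):
        chain, anchors = chain_3d(seed=6)
        table = assemble_features(
            chain,
            include_orientation_differences=False,
            include_directions=True,
            anchors={"P2": anchors["P2"][: chain.p]},
        )
        u_cols = [c for c in table.columns if c.startswith("u_")]
        assert len(u_cols) == 3 * chain.q
        assert sum(c.startswith("anchor_P2_") for c in table.columns) == 3

    def test_g_ratios_stable_under_submax_profiles(self):
        sm_small = SegmentMatrix(np.array([[4], [9]]), ("G",), ("a", "b"))
        sm_big = SegmentMatrix(np.array([[4], [9], [5]]), ("G",), ("a", "b", "c"))
        a = length_ratio(sm_small, 0)
        b = length_ratio(sm_big, 0)
        assert np.allclose(a, b[:2])
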