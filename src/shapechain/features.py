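"""Morphometric variables extracted from a fitted chain.

2D chains yield signed orientation differences between neighboring segments
(the rotation of one region relative to the next) and, for variable-length
segments, piece-count ratios that track growth.  3D chains yield per-segment
unit direction vectors (start to end of the aligned segment).  These become
the columns of a per-profile feature table for discriminant analysis.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegeneracyError, DimensionError, ShapeChainError
from .chain import FittedChain
from .profiles import arc_length
from .segmentation import SegmentMatrix, detect_apices

__all__ = [
    "orientation_difference_2d",
    "segment_orientation_2d",
    "length_ratio",
    "segment_direction_3d",
    "assemble_features",
    "count_fitting_variables",
    "count_analysis_variables",
]


def _wrap_degrees(a: float) -> float:
    """Wrap an angle to [-180, 180)."""
    return float((a + 180.0) % 360.0 - 180.0)


def segment_orientation_2d(chain: FittedChain, j: int, e: int) -> float:
    """Planar direction angle (degrees) of segment ``e``'s end-minus-start
    chord on profile ``j``."""
    pts = chain.aligned[j][e].points
    if pts.shape[1] != 2:
        raise DimensionError("segment orientation angles are 2D only")
    v = pts[-1] - pts[0]
    return float(np.degrees(np.arctan2(v[1], v[0])))


def orientation_difference_2d(chain: FittedChain, j: int, e: int) -> float:
    """Signed orientation change (degrees, in [-180, 180)) between segments
    ``e`` and ``e+1``: direction of the first piece of segment ``e+1`` minus
    direction of the last piece of segment ``e``, counter-clockwise positive."""
    if chain.dimension != 2:
        raise DimensionError("use segment_direction_3d for 3D chains")
    if not 0 <= e < chain.q - 1:
        raise IndexError(f"segment pair index {e} out of range (q={chain.q})")
    last = chain.aligned[j][e].points
    first = chain.aligned[j][e + 1].points
    v1 = last[-1] - last[-2]
    v2 = first[1] - first[0]
    a1 = np.degrees(np.arctan2(v1[1], v1[0]))
    a2 = np.degrees(np.arctan2(v2[1], v2[0]))
    return _wrap_degrees(a2 - a1)


def length_ratio(matrix: SegmentMatrix, e: int) -> np.ndarray:
    """Piece-count ratios for a variable-length column: each profile's piece
    count divided by the largest count in the column, so values lie in (0, 1]
    with at least one profile attaining 1."""
    if matrix.type_vector[e] == "M":
        raise DimensionError(
            f"column {e} is an M-segment: its length is fixed across profiles"
        )
    col = matrix.entries[:, e].astype(float)
    return col / col.max()


def segment_direction_3d(chain: FittedChain, j: int, e: int) -> np.ndarray:
    """Unit vector from the start to the end of aligned segment ``e`` on
    profile ``j`` (3D)."""
    if chain.dimension != 3:
        raise DimensionError("use orientation_difference_2d for 2D chains")
    pts = chain.aligned[j][e].points
    v = pts[-1] - pts[0]
    n = np.linalg.norm(v)
    if n == 0.0:
        raise DegeneracyError(
            f"segment {e} on profile {chain.profiles[j].id!r} has coincident "
            f"endpoints"
        )
    return v / n


# ---------------------------------------------------------------------------
# variable counting
# ---------------------------------------------------------------------------

def count_fitting_variables(type_vector: Sequence[str], dimension: int) -> int:
    """Number of variables the chain fit produces.

    2D: one orientation angle per segment plus one arc length per C/G (or H)
    segment.  3D: three orientation parameters per segment plus one length
    per variable-length (G/H/C) segment.
    """
    q = len(type_vector)
    n_var_len = sum(1 for t in type_vector if t != "M")
    if dimension == 2:
        return q + n_var_len
    if dimension == 3:
        return 3 * q + n_var_len
    raise DimensionError(f"dimension must be 2 or 3, got {dimension}")


def count_analysis_variables(
    type_vector: Sequence[str],
    dimension: int,
    n_anchor_points: int = 0,
    n_extra_scalars: int = 0,
) -> int:
    """Number of variables entering the discriminant analysis.

    2D: the q−1 orientation differences between neighboring segments plus any
    extra scalars (apex count, burr count, arc length...).  3D: three
    direction components per segment plus three coordinates per anchor point.
    """
    q = len(type_vector)
    if dimension == 2:
        return (q - 1) + n_extra_scalars
    if dimension == 3:
        return 3 * q + 3 * n_anchor_points + n_extra_scalars
    raise DimensionError(f"dimension must be 2 or 3, got {dimension}")


# ---------------------------------------------------------------------------
# feature table assembly
# ---------------------------------------------------------------------------

def assemble_features(
    chain: FittedChain,
    include_orientation_differences: bool = True,
    include_length_ratios: bool = False,
    include_directions: bool = False,
    include_arc_length: bool = False,
    apex_params: tuple[int, float] | None = None,
    burr_params: tuple[int, float] | None = None,
    anchors: dict[str, np.ndarray] | None = None,
    absolute_angles: bool = False,
) -> pd.DataFrame:
    """Build the per-profile feature table for statistics.

    Column naming: ``sigma_e`` (orientation differences, 2D), ``g_e`` (length
    ratios of variable-length columns), ``u_e_x|y|z`` (3D directions),
    ``arclen``, ``n_apex``, ``n_burr`` and ``anchor_<name>_<x|y|z>``.
    ``apex_params`` / ``burr_params`` are ``(k, T)`` pairs for the
    relative-angle detector.  ``anchors`` maps a name to a (p, dim) array of
    coordinates per profile.  The group label of each profile is kept in a
    ``group`` column; the profile id is the index.
    """
    dim = chain.dimension
    if include_orientation_differences and include_directions:
        raise DimensionError("orientation differences are 2D, directions 3D; "
                             "pick the block matching the chain's dimension")
    data: dict[str, np.ndarray] = {}
    p, q = chain.p, chain.q

    if include_orientation_differences and dim == 2:
        for e in range(q - 1):
            col = np.array(
                [orientation_difference_2d(chain, j, e) for j in range(p)]
            )
            if absolute_angles:
                col = np.abs(col)
            data[f"sigma_{e + 1}"] = col
    elif include_orientation_differences and dim == 3:
        raise DimensionError("orientation differences require a 2D chain")

    if include_directions:
        if dim != 3:
            raise DimensionError("direction vectors require a 3D chain")
        for e in range(q):
            u = np.array([segment_direction_3d(chain, j, e) for j in range(p)])
            for ax, name in enumerate("xyz"):
                data[f"u_{e + 1}_{name}"] = u[:, ax]

    if include_length_ratios:
        for e, t in enumerate(chain.matrix.type_vector):
            if t != "M":
                data[f"g_{e + 1}"] = length_ratio(chain.matrix, e)

    if include_arc_length:
        data["arclen"] = np.array([arc_length(pr.points) for pr in chain.profiles])

    if apex_params is not None:
        k, T = apex_params
        data["n_apex"] = np.array(
            [len(detect_apices(pr, int(k), float(T))) for pr in chain.profiles],
            dtype=float,
        )
    if burr_params is not None:
        k, T = burr_params
        data["n_burr"] = np.array(
            [len(detect_apices(pr, int(k), float(T))) for pr in chain.profiles],
            dtype=float,
        )

    if anchors:
        for name, coords in anchors.items():
            coords = np.asarray(coords, dtype=float)
            if coords.shape != (p, dim):
                raise ShapeChainError(
                    f"anchor {name!r} must be a ({p}, {dim}) array, "
                    f"got {coords.shape}"
                )
            for ax in range(dim):
                data[f"anchor_{name}_{'xyz'[ax]}"] = coords[:, ax]

    table = pd.DataFrame(data, index=[pr.id for pr in chain.profiles])
    table.index.name = "id"
    table.insert(0, "group", [pr.group for pr in chain.profiles])
    return table
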