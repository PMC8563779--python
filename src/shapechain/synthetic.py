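"""Synthetic profile families with known ground truth.

Three generators emulate the data structure of the method's typical use
cases so every pipeline stage can be tested without external data:

* ``generate_chain_profiles`` — open profiles concatenated from a known
  chain (known segment types, per-profile variable-segment lengths and
  inter-segment joint angles, additive Gaussian coordinate noise);
* ``generate_leaflike`` — closed serrated outlines: an elliptical base with
  low-frequency lobes (the global apices) plus a high-frequency burr
  sinusoid;
* ``generate_suturelike`` — smooth open 3D arcs with group-specific rigid
  offsets and length scalings, plus labeled anchor points at the ends.

Every generator is driven by a single seed and returns the ground truth
needed for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .profiles import DesignProfile, TargetProfile, arc_length, resample_to_target
from .segmentation import SegmentMatrix
from .segments import SegmentModel, _helix_points, generate_segment_points

__all__ = [
    "ChainSpec",
    "ChainTruth",
    "LeafSpec",
    "SutureSpec",
    "generate_chain_profiles",
    "generate_leaflike",
    "generate_suturelike",
]


def _rot2(deg: float) -> np.ndarray:
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


# ---------------------------------------------------------------------------
# chain-generated open profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainSpec:
    """Conditions for the known-truth chain generator (2D, open profiles).

    Per group: mean joint angles (degrees, one per inter-segment joint) and
    mean piece counts for each variable-length (non-M) segment.  Coordinate
    noise is isotropic Gaussian with standard deviation ``noise_sd`` in units
    of the piece length.
    """

    seed: int = 0
    p: int = 20
    piece_length: float = 1.0
    type_vector: tuple[str, ...] = ("M", "G", "M")
    m_pieces: int = 20  # pieces of every M segment
    group_angles: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {"A": (25.0, -35.0)}
    )
    group_lengths: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {"A": (40.0,)}
    )
    angle_sd: float = 2.0  # degrees
    length_sd: float = 4.0  # pieces
    noise_sd: float = 0.05  # × piece_length


@dataclass(frozen=True)
class ChainTruth:
    """Ground truth accompanying chain-generated profiles."""

    type_vector: tuple[str, ...]
    piece_counts: np.ndarray  # (p, q) true pieces per segment (pre-noise)
    joint_angles: np.ndarray  # (p, q-1) degrees
    boundaries: tuple[np.ndarray, ...]  # 1-based indices on the emitted profiles
    groups: tuple[str, ...]

    @property
    def segment_matrix(self) -> SegmentMatrix:
        ids = tuple(f"p{j:03d}" for j in range(len(self.piece_counts)))
        return SegmentMatrix(
            entries=self.piece_counts,
            type_vector=self.type_vector,
            profile_ids=ids,
        )


def _truth_templates(spec: ChainSpec) -> dict:
    """Fixed ground-truth segment shapes: a gently curved rigid template and
    a sinuous unit template for scalable segments."""
    h = spec.piece_length
    m_tpl = _helix_points(0.04 / h, 0.0, h, spec.m_pieces, 2)
    t = np.linspace(0.0, 1.0, 64)
    g_raw = np.column_stack([t, 0.12 * np.sin(2.0 * np.pi * t)])
    g_tpl = g_raw / arc_length(g_raw)
    return {"M": m_tpl, "G": g_tpl, "C_kappa": 0.03 / h}


def generate_chain_profiles(
    spec: ChainSpec,
) -> tuple[list[TargetProfile], ChainTruth]:
    """Generate open 2D profiles by concatenating ground-truth segments.

    Per profile, variable-segment piece counts and joint angles are drawn
    around the group means; segment polylines are generated, rotated at each
    joint by the drawn angle and chained end-to-start; isotropic Gaussian
    noise is added and the noisy polyline is resampled back to equal pieces.
    """
    rng = np.random.default_rng(spec.seed)
    h = spec.piece_length
    q = len(spec.type_vector)
    tpl = _truth_templates(spec)
    groups = sorted(spec.group_angles)
    if sorted(spec.group_lengths) != groups:
        raise ConfigurationError("group_angles and group_lengths keys must match")
    n_free = sum(1 for t in spec.type_vector if t != "M")
    for g in groups:
        if len(spec.group_angles[g]) != q - 1:
            raise ConfigurationError(f"group {g!r}: need {q - 1} joint angles")
        if len(spec.group_lengths[g]) != n_free:
            raise ConfigurationError(f"group {g!r}: need {n_free} segment lengths")

    g_model = SegmentModel(type="G", piece_length=h, dimension=2, template=tpl["G"])

    profiles: list[TargetProfile] = []
    counts = np.empty((spec.p, q), dtype=int)
    angles = np.empty((spec.p, q - 1))
    bounds_out: list[np.ndarray] = []
    group_of: list[str] = []
    for j in range(spec.p):
        grp = groups[j % len(groups)]
        group_of.append(grp)
        free_means = list(spec.group_lengths[grp])
        fi = 0
        for e, t in enumerate(spec.type_vector):
            if t == "M":
                counts[j, e] = spec.m_pieces
            else:
                m = int(round(rng.normal(free_means[fi], spec.length_sd)))
                counts[j, e] = max(4, m)
                fi += 1
        angles[j] = np.asarray(spec.group_angles[grp]) + rng.normal(
            0.0, spec.angle_sd, size=q - 1
        )

        pts = None
        for e, t in enumerate(spec.type_vector):
            m = int(counts[j, e])
            if t == "M":
                seg = tpl["M"].copy()
            elif t == "G":
                seg = generate_segment_points(g_model, m)
            elif t == "C":
                seg = _helix_points(tpl["C_kappa"], 0.0, h, m, 2)
            else:
                raise ConfigurationError("chain generator supports M, G, C in 2D")
            seg = seg - seg[0]
            d0 = seg[1] - seg[0]
            d0 = d0 / np.linalg.norm(d0)
            if pts is None:
                pts = seg
                continue
            prev_dir = pts[-1] - pts[-2]
            prev_dir = prev_dir / np.linalg.norm(prev_dir)
            want = _rot2(angles[j, e - 1]) @ prev_dir
            # rotation taking d0 onto want
            cross = d0[0] * want[1] - d0[1] * want[0]
            dot = float(np.clip(d0 @ want, -1.0, 1.0))
            R = _rot2(np.degrees(np.arctan2(cross, dot)))
            seg = seg @ R.T
            pts = np.vstack([pts, seg[1:] + pts[-1]])

        n_pieces = counts[j].sum()
        true_bounds = np.concatenate([[1], 1 + np.cumsum(counts[j])])
        if spec.noise_sd > 0.0:
            noisy = pts + rng.normal(0.0, spec.noise_sd * h, size=pts.shape)
            prof = resample_to_target(
                DesignProfile(id=f"p{j:03d}", points=noisy, group=grp), h
            )
            # map true joint arc positions onto the resampled index grid
            frac = (true_bounds - 1) / n_pieces
            idx = np.round(frac * prof.n_pieces).astype(int) + 1
            idx[0], idx[-1] = 1, prof.n_points
            bounds_out.append(idx)
        else:
            prof = TargetProfile(
                id=f"p{j:03d}", points=pts, piece_length=h, group=grp
            )
            bounds_out.append(true_bounds)
        profiles.append(prof)

    truth = ChainTruth(
        type_vector=tuple(spec.type_vector),
        piece_counts=counts,
        joint_angles=angles,
        boundaries=tuple(bounds_out),
        groups=tuple(group_of),
    )
    return profiles, truth


# ---------------------------------------------------------------------------
# leaf-like closed serrated outlines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeafSpec:
    """Conditions for the serrated closed-outline generator.

    The radius is ``r(θ) = base · (1 + lobe_amp · ((1+cos(lobes·θ))/2)^s
    + burr_amp · sin(burr_freq·θ))`` on an elliptical base — the raised-cosine
    power ``s`` makes lobe tips sharp and the sinuses between them flat, as on
    a lobed leaf; the burr sinusoid is the high-frequency serration.
    """

    seed: int = 0
    p: int = 10
    lobes: int = 5
    base_radius: float = 100.0
    aspect: float = 0.8  # y-radius / x-radius of the base ellipse
    lobe_amp: float = 0.4
    lobe_sharpness: float = 4.0
    burr_amp: float = 0.02
    burr_freq: int = 60
    piece_length: float = 1.0
    noise_sd: float = 0.0
    n_dense: int = 4000


@dataclass(frozen=True)
class LeafTruth:
    """True lobe-tip locations of leaf-like outlines."""

    tip_angles: np.ndarray  # (lobes,) polar angles of the true apices
    tip_indices: tuple[np.ndarray, ...]  # 1-based indices per profile


def generate_leaflike(spec: LeafSpec) -> tuple[list[TargetProfile], LeafTruth]:
    """Generate closed serrated outlines with known lobe-tip locations."""
    if spec.lobes < 3:
        raise ConfigurationError("need at least 3 lobes")
    rng = np.random.default_rng(spec.seed)
    theta = np.linspace(0.0, 2.0 * np.pi, spec.n_dense, endpoint=False)
    tips = 2.0 * np.pi * np.arange(spec.lobes) / spec.lobes
    profiles = []
    tip_idx = []
    for j in range(spec.p):
        wobble = rng.normal(1.0, 0.02)
        lobe = ((1.0 + np.cos(spec.lobes * theta)) / 2.0) ** spec.lobe_sharpness
        r = spec.base_radius * wobble * (
            1.0
            + spec.lobe_amp * lobe
            + spec.burr_amp * np.sin(spec.burr_freq * theta)
        )
        pts = np.column_stack(
            [r * np.cos(theta), spec.aspect * r * np.sin(theta)]
        )
        if spec.noise_sd > 0.0:
            pts = pts + rng.normal(0.0, spec.noise_sd * spec.piece_length, pts.shape)
        prof = resample_to_target(
            DesignProfile(id=f"leaf{j:03d}", points=np.vstack([pts, pts[0]]),
                          closed=True),
            spec.piece_length,
        )
        # nearest resampled point to each true tip
        ang = np.arctan2(
            prof.points[:-1, 1] / spec.aspect, prof.points[:-1, 0]
        ) % (2.0 * np.pi)
        idx = np.array(
            [
                1 + int(np.argmin(np.minimum(np.abs(ang - t),
                                             2 * np.pi - np.abs(ang - t))))
                for t in tips
            ]
        )
        tip_idx.append(idx)
        profiles.append(prof)
    return profiles, LeafTruth(tip_angles=tips, tip_indices=tuple(tip_idx))


# ---------------------------------------------------------------------------
# suture-like 3D open curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SutureSpec:
    """Conditions for the smooth 3D open-curve generator.

    Per group: a rigid tilt (degrees, about the x axis), an
    anterior–posterior shift and a length scaling applied to a common base
    arc; anchors analogous to suture intersection points sit at the ends.
    """

    seed: int = 0
    p_per_group: int = 8
    groups: tuple[str, ...] = ("A", "B", "C")
    base_radius: float = 60.0
    height: float = 30.0
    group_tilt: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.0, "B": 12.0, "C": -12.0}
    )
    group_shift: Mapping[str, float] = field(
        default_factory=lambda: {"A": 0.0, "B": 6.0, "C": -6.0}
    )
    group_scale: Mapping[str, float] = field(
        default_factory=lambda: {"A": 1.0, "B": 1.1, "C": 0.92}
    )
    piece_length: float = 1.0
    noise_sd: float = 0.05  # × piece_length
    n_dense: int = 200


def generate_suturelike(
    spec: SutureSpec,
) -> tuple[list[TargetProfile], dict[str, np.ndarray]]:
    """Generate smooth 3D open curves with group-specific pose and size.

    Returns the profiles (group labels attached) and an ``anchors`` mapping
    with the curve endpoints ``P1``/``P2`` per profile (p, 3) arrays.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.linspace(0.0, np.pi, spec.n_dense)
    base = np.column_stack(
        [
            spec.base_radius * np.cos(t),
            spec.base_radius * 0.7 * np.sin(t),
            spec.height * np.sin(t) ** 2,
        ]
    )
    profiles = []
    p1s, p2s = [], []
    for grp in spec.groups:
        tilt = np.radians(spec.group_tilt[grp])
        c, s = np.cos(tilt), np.sin(tilt)
        R = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
        for i in range(spec.p_per_group):
            scale = spec.group_scale[grp] * rng.normal(1.0, 0.02)
            pts = base * scale @ R.T
            pts = pts + np.array([0.0, spec.group_shift[grp], 0.0])
            pts = pts + rng.normal(0.0, spec.noise_sd * spec.piece_length, pts.shape)
            prof = resample_to_target(
                DesignProfile(id=f"{grp}{i:02d}", points=pts, group=grp),
                spec.piece_length,
            )
            profiles.append(prof)
            p1s.append(prof.points[0])
            p2s.append(prof.points[-1])
    anchors = {"P1": np.asarray(p1s), "P2": np.asarray(p2s)}
    return profiles, anchors
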