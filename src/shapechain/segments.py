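"""The four segment types and their fitting, generation and alignment.

* **M-segment** — rigid: the Procrustes mean (rotation + translation only, no
  scaling) of corresponding portions that all contain the same number of
  pieces.  Represents regions with little variation; adds no free variables.
* **C-segment** — planar circular arc of constant curvature and variable
  length (the 2D special case of H).
* **H-segment** — circular helix of constant curvature and torsion, variable
  length; models growth plus rotation of smoothly curved 3D regions.
* **G-segment** — fixed shape, variable size: a unit-arc-length template that
  is rescaled per profile, capturing growth of a region.

Generated segment polylines use the same piece length as the target profiles,
so a segment with ``m`` pieces corresponds point-for-point with an ``m``-piece
portion; the rigid alignment of segment to portion yields the matching error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DegeneracyError, DimensionError, HomologyError
from .profiles import (
    TargetProfile,
    arc_length,
    procrustes_superimpose,
    resample_polyline,
)

__all__ = [
    "SegmentModel",
    "AlignedSegment",
    "extract_portion",
    "fit_m_segment",
    "fit_c_segment",
    "fit_h_segment",
    "fit_g_segment",
    "fit_segment",
    "generate_segment_points",
    "align_segment_to_portion",
    "kabsch_align",
    "discrete_curvature",
    "discrete_torsion",
]


@dataclass(frozen=True)
class SegmentModel:
    """A fitted segment of one of the four types.

    ``template`` holds the M polyline (original scale) or the G template
    (unit arc length); ``kappa``/``tau`` hold C/H curvature and torsion in
    1/length units.
    """

    type: str  # M | C | H | G
    piece_length: float
    dimension: int
    kappa: float | None = None
    tau: float | None = None
    template: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.type not in ("M", "C", "H", "G"):
            raise ConfigurationError(f"unknown segment type {self.type!r}")
        if self.kappa is not None and self.kappa < 0:
            raise ConfigurationError("curvature must be >= 0")
        if self.template is not None:
            object.__setattr__(
                self, "template", np.asarray(self.template, dtype=float)
            )

    @property
    def n_template_pieces(self) -> int | None:
        return None if self.template is None else len(self.template) - 1


@dataclass(frozen=True)
class AlignedSegment:
    """A generated segment rigidly aligned onto one profile portion."""

    profile_id: str
    segment_index: int
    points: np.ndarray  # aligned polyline, (m+1, dim)
    rotation: np.ndarray
    translation: np.ndarray
    error: float  # max point-to-point distance after alignment

    @property
    def n_pieces(self) -> int:
        return len(self.points) - 1


# ---------------------------------------------------------------------------
# portions
# ---------------------------------------------------------------------------

def extract_portion(
    profile: TargetProfile, boundaries: tuple[int, int]
) -> np.ndarray:
    """Points of the portion between two 1-based boundary indices, inclusive."""
    k, k2 = boundaries
    if not (1 <= k < k2 <= profile.n_points):
        raise IndexError(
            f"boundaries {boundaries} out of range on profile of "
            f"{profile.n_points} points"
        )
    return profile.points[k - 1 : k2]


# ---------------------------------------------------------------------------
# discrete differential geometry on equal-piece polylines
# ---------------------------------------------------------------------------

def discrete_curvature(points: np.ndarray) -> float:
    """Mean curvature estimate from turning angles of an equal-chord polyline.

    For a chord-sampled circle of radius R with chord h the estimator
    ``2 sin(θ/2) / h`` (θ the turning angle at a vertex) is exact: θ equals
    the subtended angle 2 asin(h / 2R), so the estimate is 1/R.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise DegeneracyError("need >= 3 points to estimate curvature")
    d = np.diff(pts, axis=0)
    h = np.linalg.norm(d, axis=1)
    t = d / h[:, None]
    dots = np.clip(np.einsum("ij,ij->i", t[:-1], t[1:]), -1.0, 1.0)
    theta = np.arccos(dots)
    hbar = 0.5 * (h[:-1] + h[1:])
    return float(np.mean(2.0 * np.sin(theta / 2.0) / hbar))


def discrete_torsion(points: np.ndarray) -> float:
    """Mean torsion estimate from consecutive binormals of a 3D polyline.

    The angle between binormals of consecutive vertex triples, signed by the
    handedness about the shared tangent, divided by the chord step.  Zero for
    planar curves; O(h²)-accurate on a helix.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[1] != 3:
        raise DimensionError("torsion requires 3D points")
    if len(pts) < 4:
        raise DegeneracyError("need >= 4 points to estimate torsion")
    d = np.diff(pts, axis=0)
    h = np.linalg.norm(d, axis=1)
    t = d / h[:, None]
    b = np.cross(t[:-1], t[1:])
    nb = np.linalg.norm(b, axis=1)
    taus = []
    for i in range(len(b) - 1):
        if nb[i] < 1e-12 or nb[i + 1] < 1e-12:
            continue  # locally straight: no defined binormal
        b1, b2 = b[i] / nb[i], b[i + 1] / nb[i + 1]
        c = float(np.clip(np.dot(b1, b2), -1.0, 1.0))
        psi = np.arccos(c)
        sign = np.sign(np.dot(np.cross(b1, b2), t[i + 1]))
        taus.append(sign * 2.0 * np.sin(psi / 2.0) / h[i + 1])
    if not taus:
        return 0.0
    return float(np.mean(taus))


def _pratt_circle_curvature(points: np.ndarray) -> float:
    """Total-least-squares (Pratt) circle fit; returns curvature 1/R.

    Solves the algebraic fit A(x²+y²) + Bx + Cy + D = 0 with the Pratt
    constraint B² + C² − 4AD = 1; lines appear as A = 0, i.e. curvature 0.
    """
    pts = np.asarray(points, dtype=float)
    centroid = pts.mean(axis=0)
    xy = pts - centroid
    scale = np.sqrt((xy ** 2).sum(axis=1).mean())
    if scale == 0.0:
        raise DegeneracyError("coincident points in circle fit")
    xy = xy / scale
    z = (xy ** 2).sum(axis=1)
    M = np.column_stack([z, xy[:, 0], xy[:, 1], np.ones(len(xy))])
    S = M.T @ M / len(xy)
    # Pratt constraint matrix
    B = np.array(
        [
            [0.0, 0.0, 0.0, -2.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.0],
            [-2.0, 0.0, 0.0, 0.0],
        ]
    )
    from scipy.linalg import eig

    w, v = eig(S, B)
    w = np.real(w)
    v = np.real(v)
    # smallest non-negative generalized eigenvalue (roundoff can push the
    # exact-fit eigenvalue slightly below zero)
    tol = 1e-9 * max(1.0, float(np.max(np.abs(w[np.isfinite(w)]))))
    w = np.where(w < -tol, np.inf, np.abs(w))
    sol = v[:, int(np.argmin(w))]
    norm = sol[1] ** 2 + sol[2] ** 2 - 4.0 * sol[0] * sol[3]
    if norm <= 0:
        return 0.0
    sol = sol / np.sqrt(norm)
    kappa = 2.0 * abs(sol[0]) / scale  # undo the normalization
    return float(kappa)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _rigid_mean(portions: Sequence[np.ndarray]) -> np.ndarray:
    """Rotation+translation-only generalized Procrustes mean."""
    if len(portions) == 1:
        return np.asarray(portions[0], dtype=float).copy()
    aligned, mean = procrustes_superimpose(list(portions), scale=False)
    return mean


def fit_m_segment(
    portions: Sequence[np.ndarray], piece_length: float
) -> SegmentModel:
    """Fit a rigid M-segment: the rigid Procrustes mean of equal-length
    portions, resampled back to equal chords."""
    counts = {len(p) for p in portions}
    if len(counts) != 1:
        raise HomologyError(
            f"M-segment portions must have identical piece counts, got {sorted(counts)}"
        )
    m = counts.pop() - 1
    mean = _rigid_mean(portions)
    # the rigid mean of equal-chord portions is already near-equal-chord;
    # equal-arc resampling restores exact spacing cheaply
    pts = resample_polyline(mean, m)
    dim = pts.shape[1]
    return SegmentModel(type="M", piece_length=piece_length, dimension=dim, template=pts)


def fit_c_segment(
    portions: Sequence[np.ndarray], piece_length: float
) -> SegmentModel:
    """Fit a constant-curvature C-segment (2D): the unweighted mean of
    per-portion total-least-squares circle-fit curvatures."""
    kappas = []
    for p in portions:
        p = np.asarray(p, dtype=float)
        if p.shape[1] != 2:
            raise DimensionError("C-segments are planar; use H-segments in 3D")
        if len(p) < 3:
            raise DegeneracyError("C-segment portions need >= 3 points")
        kappas.append(_pratt_circle_curvature(p))
    kappa = float(np.mean(kappas))
    if kappa * piece_length < 1e-12:
        kappa = 0.0
    return SegmentModel(type="C", piece_length=piece_length, dimension=2, kappa=kappa)


def fit_h_segment(
    portions: Sequence[np.ndarray], piece_length: float
) -> SegmentModel:
    """Fit a helical H-segment (3D): unweighted means of per-portion discrete
    Frenet curvature and torsion estimates."""
    kappas, taus = [], []
    for p in portions:
        p = np.asarray(p, dtype=float)
        if p.shape[1] != 3:
            raise DimensionError("H-segments require 3D portions")
        if len(p) < 4:
            raise DegeneracyError("H-segment portions need >= 4 points")
        kappas.append(discrete_curvature(p))
        taus.append(discrete_torsion(p))
    kappa = float(np.mean(kappas))
    tau = float(np.mean(taus))
    if kappa * piece_length < 1e-12:
        kappa, tau = 0.0, 0.0
    return SegmentModel(
        type="H", piece_length=piece_length, dimension=3, kappa=kappa, tau=tau
    )


def fit_g_segment(
    portions: Sequence[np.ndarray], piece_length: float
) -> SegmentModel:
    """Fit a scalable G-segment: portions are rescaled to unit arc length,
    resampled to a common point count (the largest portion's), and averaged
    with a rigid Procrustes mean stored as a unit-arc-length template."""
    if not portions:
        raise ConfigurationError("need at least one portion")
    n_common = max(len(p) for p in portions)
    normed = []
    for p in portions:
        p = np.asarray(p, dtype=float)
        if len(p) < 2:
            raise DegeneracyError("G-segment portions need >= 2 points")
        L = arc_length(p)
        if L == 0.0:
            raise DegeneracyError("zero-length portion")
        normed.append(resample_polyline(p / L, n_common - 1))
    mean = _rigid_mean(normed)
    mean = mean / arc_length(mean)
    dim = mean.shape[1]
    return SegmentModel(
        type="G", piece_length=piece_length, dimension=dim, template=mean
    )


_FITTERS = {
    "M": fit_m_segment,
    "C": fit_c_segment,
    "H": fit_h_segment,
    "G": fit_g_segment,
}


def fit_segment(
    seg_type: str, portions: Sequence[np.ndarray], piece_length: float
) -> SegmentModel:
    """Dispatch to the typed fitter."""
    try:
        fitter = _FITTERS[seg_type]
    except KeyError:
        raise ConfigurationError(f"unknown segment type {seg_type!r}") from None
    return fitter(portions, piece_length)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _helix_points(kappa: float, tau: float, h: float, m: int, dim: int) -> np.ndarray:
    """Chord-sampled circular helix (or arc / line) with chord length ``h``."""
    if kappa == 0.0:
        pts = np.zeros((m + 1, dim))
        pts[:, 0] = h * np.arange(m + 1)
        return pts
    omega2 = kappa ** 2 + tau ** 2
    omega = np.sqrt(omega2)
    r = kappa / omega2
    c = tau / omega2
    if tau == 0.0:
        # planar arc: chord h subtends angle 2 asin(h / 2R)
        if h > 2.0 * r:
            raise ConfigurationError(
                f"piece length {h} exceeds the arc diameter 2/kappa = {2 * r}"
            )
        phi = 2.0 * np.arcsin(h / (2.0 * r))
        i = np.arange(m + 1)
        pts = np.zeros((m + 1, dim))
        pts[:, 0] = r * np.sin(i * phi)
        pts[:, 1] = r * (1.0 - np.cos(i * phi))
        return pts

    # solve for the arc-length step whose chord equals h (bisection, 1e-10)
    def chord(ds: float) -> float:
        return float(
            np.sqrt(4.0 * r ** 2 * np.sin(omega * ds / 2.0) ** 2 + c ** 2 * omega2 * ds ** 2)
        )

    lo, hi = h, 8.0 * h
    while chord(hi) < h:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if chord(mid) < h:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10 * h:
            break
    ds = 0.5 * (lo + hi)
    s = ds * np.arange(m + 1)
    pts = np.column_stack(
        [r * np.cos(omega * s), r * np.sin(omega * s), c * omega * s]
    )
    return pts - pts[0]


def generate_segment_points(model: SegmentModel, m: int) -> np.ndarray:
    """Generate the polyline of a segment with ``m`` pieces.

    M returns its stored polyline (``m`` must match); C/H sample the arc or
    helix at chords equal to the piece length; G scales its unit template to
    arc length ``m * piece_length`` and resamples to ``m`` equal chords.
    """
    if model.type == "M":
        if model.template is None or m != model.n_template_pieces:
            raise HomologyError(
                f"M-segment has {model.n_template_pieces} pieces, requested {m}"
            )
        return model.template.copy()
    if m < 1:
        raise ConfigurationError("need at least 1 piece")
    h = model.piece_length
    if model.type == "C":
        return _helix_points(model.kappa or 0.0, 0.0, h, m, model.dimension)
    if model.type == "H":
        return _helix_points(model.kappa or 0.0, model.tau or 0.0, h, m, 3)
    # G: scale the unit template to the requested arc length and resample;
    # smooth templates give equal chords to well within the 1% tolerance
    scaled = model.template * (m * h)
    pts = resample_polyline(scaled, m)
    chords = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    mean_chord = float(chords.mean())
    if mean_chord > 0:
        pts = pts * (h / mean_chord)
    return pts - pts[0]


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def kabsch_align(
    moving: np.ndarray, fixed: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid registration (rotation with det +1, translation).

    Returns ``(aligned_points, R, t)`` with ``aligned = moving @ R.T + t``.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise HomologyError(
            f"point-count mismatch: segment {moving.shape} vs portion {fixed.shape}"
        )
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    H = (moving - mc).T @ (fixed - fc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.eye(H.shape[0])
    D[-1, -1] = d
    R = Vt.T @ D @ U.T
    t = fc - R @ mc
    return moving @ R.T + t, R, t


def align_segment_to_portion(
    segment_points: np.ndarray,
    portion_points: np.ndarray,
    profile_id: str = "",
    segment_index: int = 0,
) -> AlignedSegment:
    """Rigidly align a generated segment onto its portion (no scaling, no
    reflection) and report the maximum point-to-point distance as the error."""
    aligned, R, t = kabsch_align(segment_points, portion_points)
    err = float(np.max(np.linalg.norm(aligned - portion_points, axis=1)))
    return AlignedSegment(
        profile_id=profile_id,
        segment_index=segment_index,
        points=aligned,
        rotation=R,
        translation=t,
        error=err,
    )
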