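"""Outline profiles: I/O, equal-piece resampling and Procrustes superimposition.

A *design profile* is the raw ordered outline of one specimen (2D or 3D, open
or closed).  A *target profile* is its piecewise-linear resampling into pieces
of (nearly) equal length — the object every later stage operates on.  Closed
profiles are stored with the start point duplicated at the end, so the number
of pieces is always ``len(points) - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DegeneracyError, ProfileParseError

__all__ = [
    "DesignProfile",
    "TargetProfile",
    "read_profile",
    "read_group_table",
    "resample_to_target",
    "procrustes_superimpose",
    "arc_length",
    "resample_polyline",
    "resample_equal_chords",
]

#: relative tolerance on equal piece lengths
PIECE_TOL = 0.01


@dataclass(frozen=True)
class DesignProfile:
    """Raw ordered outline curve of one specimen."""

    id: str
    points: np.ndarray  # (n, dim) float array
    closed: bool = False
    group: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] not in (2, 3):
            raise ProfileParseError(
                f"profile {self.id!r}: points must be an (n, 2) or (n, 3) array, "
                f"got shape {pts.shape}"
            )
        if len(pts) < 3:
            raise ProfileParseError(f"profile {self.id!r}: fewer than 3 points")
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps == 0.0):
            bad = int(np.argmin(steps)) + 1
            raise ProfileParseError(
                f"profile {self.id!r}: consecutive coincident points at row {bad + 1}"
            )
        object.__setattr__(self, "points", pts)

    @property
    def dimension(self) -> int:
        return self.points.shape[1]

    @property
    def arc_length(self) -> float:
        return arc_length(self.points)


@dataclass(frozen=True)
class TargetProfile:
    """Equal-piece polyline a chain is fitted to.

    ``points`` holds ``N`` coordinates; the profile has ``N - 1`` pieces of
    length ``piece_length`` (within 1% relative).  For closed profiles the
    first and last stored points coincide.
    """

    id: str
    points: np.ndarray
    piece_length: float
    closed: bool = False
    group: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if len(pts) < 3:
            raise ProfileParseError(f"target profile {self.id!r}: fewer than 3 points")
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(np.abs(steps - self.piece_length) > PIECE_TOL * self.piece_length):
            worst = float(np.max(np.abs(steps - self.piece_length)))
            raise ConfigurationError(
                f"target profile {self.id!r}: piece lengths deviate from "
                f"{self.piece_length} by up to {worst} (> 1% relative)"
            )
        if self.closed and not np.allclose(pts[0], pts[-1]):
            raise ConfigurationError(
                f"target profile {self.id!r}: closed profile must duplicate its start"
            )
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_pieces(self) -> int:
        return len(self.points) - 1

    @property
    def dimension(self) -> int:
        return self.points.shape[1]


# ---------------------------------------------------------------------------
# polyline geometry helpers
# ---------------------------------------------------------------------------

def arc_length(points: np.ndarray) -> float:
    """Total length of a polyline."""
    return float(np.linalg.norm(np.diff(np.asarray(points, float), axis=0), axis=1).sum())


def resample_polyline(points: np.ndarray, n_pieces: int) -> np.ndarray:
    """Resample a polyline to ``n_pieces + 1`` points at equal arc-length spacing.

    Endpoints are preserved exactly; interior points lie on the original
    polyline (linear interpolation along its arc-length parameterization).
    """
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0.0:
        raise DegeneracyError("cannot resample a zero-length polyline")
    targets = np.linspace(0.0, total, n_pieces + 1)
    out = np.column_stack(
        [np.interp(targets, s, pts[:, d]) for d in range(pts.shape[1])]
    )
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def _step_chords(pts: np.ndarray, chord: float, max_steps: int) -> tuple[np.ndarray, float]:
    """Walk along a polyline taking steps of constant chord length.

    From the current point, the next point is the first point further along
    the polyline at Euclidean distance ``chord``.  Returns the visited points
    (starting at ``pts[0]``) and the Euclidean distance from the last visited
    point to the polyline's endpoint.
    """
    out = [pts[0]]
    cur = pts[0]
    seg_idx = 0  # current point lies on segment seg_idx at parameter t
    t = 0.0
    n_seg = len(pts) - 1
    for _ in range(max_steps):
        found = False
        i, ti = seg_idx, t
        while i < n_seg:
            a = pts[i] + ti * (pts[i + 1] - pts[i])
            b = pts[i + 1]
            # solve |a + u (b - a) - cur| = chord for u in (0, 1]
            d = b - a
            f = a - cur
            aa = float(d @ d)
            bb = 2.0 * float(f @ d)
            cc = float(f @ f) - chord * chord
            if aa > 0.0:
                disc = bb * bb - 4.0 * aa * cc
                if disc >= 0.0:
                    sq = np.sqrt(disc)
                    for u in ((-bb - sq) / (2 * aa), (-bb + sq) / (2 * aa)):
                        if 0.0 < u <= 1.0 + 1e-12:
                            u = min(u, 1.0)
                            cur = a + u * d
                            seg_idx = i
                            t = ti + u * (1.0 - ti)
                            found = True
                            break
            if found:
                break
            i += 1
            ti = 0.0
        if not found:
            break
        out.append(cur)
    leftover = float(np.linalg.norm(pts[-1] - cur))
    return np.asarray(out), leftover


def resample_equal_chords(points: np.ndarray, n_pieces: int) -> tuple[np.ndarray, float]:
    """Resample a polyline into exactly ``n_pieces`` chords of equal length.

    The chord length is solved by bisection so that ``n_pieces`` constant-chord
    steps along the curve land exactly on the endpoint.  All resampled points
    lie on the input polyline; every consecutive-point distance equals the
    returned chord length.
    """
    pts = np.asarray(points, dtype=float)
    total = arc_length(pts)
    if total == 0.0:
        raise DegeneracyError("cannot resample a zero-length polyline")
    if n_pieces < 1:
        raise ConfigurationError("need at least 1 piece")
    if n_pieces == 1:
        return np.vstack([pts[0], pts[-1]]), float(np.linalg.norm(pts[-1] - pts[0]))

    # solve for the chord c such that, after n-1 on-curve steps of length c,
    # the straight chord remaining to the endpoint also has length c
    def residual(chord: float) -> float:
        walked, leftover = _step_chords(pts, chord, n_pieces - 1)
        return leftover - chord  # decreasing in chord

    lo, hi = 0.25 * total / n_pieces, total / max(n_pieces - 1, 1)
    while residual(hi) > 0.0:
        hi *= 1.5
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        r = residual(mid)
        if r > 1e-14 * total:
            lo = mid
        elif r < -1e-14 * total:
            hi = mid
        else:
            lo = hi = mid
            break
    chord = 0.5 * (lo + hi)
    walked, _ = _step_chords(pts, chord, n_pieces - 1)
    out = np.vstack([np.asarray(walked), pts[-1]])
    return out, chord


# ---------------------------------------------------------------------------
# reading profiles
# ---------------------------------------------------------------------------

def _parse_csv(path: Path) -> np.ndarray:
    rows: list[list[float]] = []
    dim: int | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            cells = [c.strip() for c in line.split(",")]
            if lineno == 1 and any(c.lower() in ("x", "y", "z") for c in cells):
                continue  # header
            try:
                vals = [float(c) for c in cells]
            except ValueError:
                raise ProfileParseError(
                    f"{path}: malformed row at line {lineno}: {line!r}"
                ) from None
            if len(vals) not in (2, 3):
                raise ProfileParseError(
                    f"{path}: line {lineno} has {len(vals)} columns (expected 2 or 3)"
                )
            if dim is None:
                dim = len(vals)
            elif len(vals) != dim:
                raise ProfileParseError(
                    f"{path}: mixed dimensionality at line {lineno} "
                    f"({len(vals)} columns after {dim})"
                )
            rows.append(vals)
    if len(rows) < 3:
        raise ProfileParseError(f"{path}: fewer than 3 coordinate rows")
    return np.asarray(rows, dtype=float)


def _parse_tps(path: Path) -> tuple[np.ndarray, str | None]:
    """Parse the first landmark block of a TPS file (LM= / LM3= ... ID=)."""
    pts: list[list[float]] = []
    prof_id: str | None = None
    n_expected: int | None = None
    dim = 2
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3="):
                n_expected = int(line.split("=", 1)[1])
                dim = 3
            elif upper.startswith("LM="):
                n_expected = int(line.split("=", 1)[1])
                dim = 2
            elif upper.startswith("ID="):
                prof_id = line.split("=", 1)[1].strip()
            elif "=" in line and not line[0].isdigit() and not line[0] in "+-.":
                continue  # IMAGE=, SCALE=, ...
            else:
                if n_expected is not None and len(pts) == n_expected:
                    continue  # past the first landmark block
                try:
                    vals = [float(c) for c in line.replace(",", " ").split()]
                except ValueError:
                    raise ProfileParseError(
                        f"{path}: malformed TPS row at line {lineno}: {line!r}"
                    ) from None
                if len(vals) != dim:
                    raise ProfileParseError(
                        f"{path}: line {lineno} has {len(vals)} coordinates "
                        f"(expected {dim})"
                    )
                pts.append(vals)
    if n_expected is not None and len(pts) != n_expected:
        raise ProfileParseError(
            f"{path}: TPS block declares {n_expected} landmarks, found {len(pts)}"
        )
    if len(pts) < 3:
        raise ProfileParseError(f"{path}: fewer than 3 landmarks")
    return np.asarray(pts, dtype=float), prof_id


def read_profile(
    path: str | Path,
    fmt: str = "csv",
    closed: bool = False,
    id: str | None = None,
    group: str = "",
) -> DesignProfile:
    """Read one outline profile from a CSV (``x,y[,z]`` per row) or TPS file.

    For ``closed=True`` the terminal point is duplicated from the start if the
    file does not already close the loop.
    """
    path = Path(path)
    if not path.exists():
        raise ProfileParseError(f"no such file: {path}")
    if fmt == "csv":
        pts = _parse_csv(path)
        file_id = None
    elif fmt == "tps":
        pts, file_id = _parse_tps(path)
    else:
        raise ConfigurationError(f"unknown profile format {fmt!r} (use 'csv' or 'tps')")
    if closed and not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    prof_id = id or file_id or path.stem
    return DesignProfile(id=prof_id, points=pts, closed=closed, group=group)


def read_group_table(path: str | Path) -> dict[str, str]:
    """Read an ``id,group`` CSV into a mapping."""
    out: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            cells = [c.strip() for c in line.split(",")]
            if lineno == 1 and cells[0].lower() == "id":
                continue
            if len(cells) < 2:
                raise ProfileParseError(f"{path}: line {lineno}: expected 'id,group'")
            out[cells[0]] = cells[1]
    return out


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_to_target(profile: DesignProfile, piece_length: float) -> TargetProfile:
    """Convert a design profile into an equal-piece target profile.

    The piece count is ``round(arc_length / piece_length)``; points are placed
    at equal arc-length spacing along the input polyline, so the effective
    piece length stored on the result is ``arc_length / n_pieces``.
    """
    if piece_length <= 0:
        raise ConfigurationError("piece_length must be positive")
    total = profile.arc_length
    if piece_length >= total / 2:
        raise ConfigurationError(
            f"piece_length {piece_length} too large for profile {profile.id!r} "
            f"(arc length {total})"
        )
    n_pieces = int(round(total / piece_length))
    if n_pieces < 3:
        raise ConfigurationError(
            f"piece_length {piece_length} yields only {n_pieces} pieces on "
            f"profile {profile.id!r}; need at least 3"
        )
    best: tuple[float, np.ndarray, float] | None = None
    for n_try in (n_pieces, n_pieces + 1, n_pieces - 1):
        if n_try < 3:
            continue
        pts, chord = resample_equal_chords(profile.points, n_try)
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        dev = float(np.max(np.abs(steps - chord)) / chord)
        if best is None or dev < best[0]:
            best = (dev, pts, chord)
        if dev <= PIECE_TOL:
            break
    dev, pts, chord = best
    if dev > PIECE_TOL:
        raise ConfigurationError(
            f"profile {profile.id!r}: cannot place equal pieces of length "
            f"~{piece_length} (worst relative deviation {dev:.3f}); the curve "
            f"folds back at this scale — use a smaller piece_length"
        )
    if profile.closed:
        pts[-1] = pts[0]
    return TargetProfile(
        id=profile.id,
        points=pts,
        piece_length=chord,
        closed=profile.closed,
        group=profile.group,
    )


# ---------------------------------------------------------------------------
# generalized Procrustes superimposition
# ---------------------------------------------------------------------------

def _kabsch(moving: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (det = +1) taking centered ``moving`` onto
    centered ``fixed`` in the least-squares sense."""
    H = moving.T @ fixed
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.eye(H.shape[0])
    D[-1, -1] = d
    return Vt.T @ D @ U.T


def procrustes_superimpose(
    configurations: Sequence[np.ndarray],
    scale: bool = True,
    max_iter: int = 200,
    tol: float = 1e-9,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Generalized Procrustes superimposition of point configurations.

    Each configuration is translated to a zero centroid, optionally scaled to
    unit centroid size, and rotated (proper rotations only) to a consensus;
    the consensus is iterated until the mean shape moves by less than ``tol``.

    Returns ``(aligned_configurations, mean_shape)``.
    """
    configs = [np.asarray(c, dtype=float) for c in configurations]
    if len(configs) < 2:
        raise ConfigurationError("need at least 2 configurations to superimpose")
    shape0 = configs[0].shape
    for c in configs:
        if c.shape != shape0:
            raise ConfigurationError(
                f"configurations differ in shape: {c.shape} vs {shape0}"
            )
    centered = []
    for c in configs:
        cc = c - c.mean(axis=0)
        size = np.linalg.norm(cc)
        if size == 0.0:
            raise DegeneracyError("degenerate configuration: all points coincident")
        centered.append(cc / size if scale else cc)

    mean = centered[0].copy()
    mean_norm = np.linalg.norm(mean)
    for _ in range(max_iter):
        aligned = [c @ _kabsch(c, mean).T for c in centered]
        new_mean = np.mean(aligned, axis=0)
        if scale:
            nm = np.linalg.norm(new_mean)
            if nm > 0:
                new_mean = new_mean / nm
        shift = np.linalg.norm(new_mean - mean) / max(mean_norm, 1e-300)
        mean = new_mean
        mean_norm = np.linalg.norm(mean)
        centered = aligned
        if shift < tol:
            break
    return centered, mean
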