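"""Chain assembly over all profiles, error metrics and the two optimizers.

Given the target profiles, a segment type vector and a segment matrix, each
column's typed segment model is fitted on the corresponding portions of every
profile; the generated segment polylines are rigidly aligned to their portions
and the p×q error matrix of maximum point-to-point distances is filled in.

Two optimizers refine the segment matrix without moving primary boundaries:

* a piecewise transfer that, per profile, moves single pieces from the worst
  to the best non-rigid segment inside the same sub-profile, accepting a move
  only if that profile's mean matching error decreases; and
* a worst-profile re-segmentation that redraws random non-rigid segment
  lengths for the worst-matched share of profiles, accepting per profile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, HomologyError
from .profiles import TargetProfile
from .segmentation import SegmentMatrix
from .segments import (
    AlignedSegment,
    SegmentModel,
    align_segment_to_portion,
    extract_portion,
    fit_segment,
    generate_segment_points,
)

__all__ = [
    "FittedChain",
    "build_chain",
    "error_metrics",
    "optimize_piecewise",
    "optimize_worst_profiles",
    "save_chain",
]


@dataclass(frozen=True)
class FittedChain:
    """A shape-changing chain fitted to a family of profiles."""

    profiles: tuple[TargetProfile, ...]
    matrix: SegmentMatrix
    models: tuple[SegmentModel, ...]
    aligned: tuple[tuple[AlignedSegment, ...], ...]  # [j][e]
    error_matrix: np.ndarray  # (p, q) of E_j^e

    @property
    def p(self) -> int:
        return self.matrix.p

    @property
    def q(self) -> int:
        return self.matrix.q

    @property
    def dimension(self) -> int:
        return self.profiles[0].dimension

    @property
    def e_max(self) -> float:
        """Largest entry of the error matrix."""
        return float(self.error_matrix.max())

    @property
    def e_mean(self) -> float:
        """Mean entry of the error matrix."""
        return float(self.error_matrix.mean())

    def profile_mean_max_error(self) -> np.ndarray:
        """Per-profile mean of segment maximum errors (row means of EM)."""
        return self.error_matrix.mean(axis=1)

    def profile_mean_point_error(self) -> np.ndarray:
        """Per-profile mean point-to-point distance over all segment points,
        normalized by the profile's point count."""
        out = np.empty(self.p)
        for j in range(self.p):
            total = 0.0
            prof = self.profiles[j]
            bounds = self.matrix.boundaries(j)
            for e, seg in enumerate(self.aligned[j]):
                portion = extract_portion(prof, (int(bounds[e]), int(bounds[e + 1])))
                total += float(
                    np.linalg.norm(seg.points - portion, axis=1).sum()
                )
            out[j] = total / prof.n_points
        return out


def error_metrics(chain: FittedChain) -> dict:
    """The four matching-error metrics of a fitted chain.

    ``E_max`` — maximum entry of the error matrix; ``E_mean`` — its mean;
    ``E_profile_mean[j]`` — row means; ``E_profile_point[j]`` — per-profile
    mean point-to-point distance over all segment points.
    """
    return {
        "E_max": chain.e_max,
        "E_mean": chain.e_mean,
        "E_profile_mean": chain.profile_mean_max_error(),
        "E_profile_point": chain.profile_mean_point_error(),
    }


# ---------------------------------------------------------------------------
# building
# ---------------------------------------------------------------------------

def build_chain(
    profiles: Sequence[TargetProfile],
    type_vector: Sequence[str] | None = None,
    segment_matrix: SegmentMatrix | None = None,
) -> FittedChain:
    """Fit one chain to all profiles given a segment matrix.

    For each column the typed segment model is fitted on that column's
    portions across profiles; for each (profile, column) cell the generated
    segment is aligned to the portion and the maximum point-to-point distance
    recorded in the error matrix.
    """
    if segment_matrix is None:
        raise ConfigurationError("a segment matrix is required")
    matrix = segment_matrix
    if type_vector is not None and tuple(type_vector) != matrix.type_vector:
        raise ConfigurationError("type vector disagrees with the segment matrix")
    profiles = tuple(profiles)
    if len(profiles) != matrix.p:
        raise HomologyError(
            f"{len(profiles)} profiles but segment matrix has {matrix.p} rows"
        )
    for j, prof in enumerate(profiles):
        if matrix.entries[j].sum() != prof.n_pieces:
            raise HomologyError(
                f"profile {prof.id!r}: row sum {matrix.entries[j].sum()} != "
                f"{prof.n_pieces} pieces"
            )
    piece_length = float(np.mean([p.piece_length for p in profiles]))

    portions: list[list[np.ndarray]] = []
    for j, prof in enumerate(profiles):
        bounds = matrix.boundaries(j)
        portions.append(
            [
                extract_portion(prof, (int(bounds[e]), int(bounds[e + 1])))
                for e in range(matrix.q)
            ]
        )

    models = tuple(
        fit_segment(matrix.type_vector[e], [portions[j][e] for j in range(matrix.p)],
                    piece_length)
        for e in range(matrix.q)
    )

    aligned_rows = []
    em = np.empty((matrix.p, matrix.q))
    for j, prof in enumerate(profiles):
        row = []
        for e in range(matrix.q):
            pts = generate_segment_points(models[e], int(matrix.entries[j, e]))
            seg = align_segment_to_portion(
                pts, portions[j][e], profile_id=prof.id, segment_index=e
            )
            row.append(seg)
            em[j, e] = seg.error
        aligned_rows.append(tuple(row))
    return FittedChain(
        profiles=profiles,
        matrix=matrix,
        models=models,
        aligned=tuple(aligned_rows),
        error_matrix=em,
    )


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

def _with_row(matrix: SegmentMatrix, j: int, new_row: np.ndarray) -> SegmentMatrix:
    m = matrix.entries.copy()
    m[j] = new_row
    return SegmentMatrix(
        entries=m,
        type_vector=matrix.type_vector,
        profile_ids=matrix.profile_ids,
        sub_profile_of=matrix.sub_profile_of,
    )


def optimize_piecewise(
    chain: FittedChain,
    max_iter: int = 200,
    tol: float = 0.0,
) -> FittedChain:
    """Piece-transfer optimization: per profile, move one piece from the
    highest-error non-rigid segment to the lowest-error non-rigid segment of
    the same sub-profile; keep the move only if the profile's mean
    point-to-point error decreases.  Stops after a full pass with no accepted
    move, or ``max_iter`` passes.  Row sums and M columns are preserved."""
    matrix = chain.matrix
    types = matrix.type_vector
    sub_of = np.asarray(matrix.sub_profile_of)
    movable = np.array([t != "M" for t in types])
    current = chain
    for _ in range(max_iter):
        accepted = False
        scores = current.profile_mean_point_error()
        for j in range(matrix.p):
            em_row = current.error_matrix[j]
            # candidate (source, sink) pairs inside one sub-profile
            best_move = None
            for sub in np.unique(sub_of):
                cols = list(np.where((sub_of == sub) & movable)[0])
                donors = [e for e in cols if current.matrix.entries[j, e] > 1]
                if not donors or len(cols) < 2:
                    continue
                src = max(donors, key=lambda e: em_row[e])
                sink = min((e for e in cols if e != src), key=lambda e: em_row[e])
                if best_move is None or em_row[src] > em_row[best_move[0]]:
                    best_move = (src, sink)
            if best_move is None:
                continue
            src, sink = best_move
            new_row = current.matrix.entries[j].copy()
            new_row[src] -= 1
            new_row[sink] += 1
            trial = build_chain(
                current.profiles, segment_matrix=_with_row(current.matrix, j, new_row)
            )
            if trial.profile_mean_point_error()[j] < scores[j] - tol:
                current = trial
                scores = current.profile_mean_point_error()
                accepted = True
        if not accepted:
            break
    return current


def _random_row(
    matrix: SegmentMatrix,
    j: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Redraw non-rigid segment lengths within each sub-profile of row ``j``,
    preserving the sub-profile totals and all M entries."""
    types = matrix.type_vector
    sub_of = np.asarray(matrix.sub_profile_of)
    row = matrix.entries[j].copy()
    for sub in np.unique(sub_of):
        cols = np.where(sub_of == sub)[0]
        free = [e for e in cols if types[e] != "M"]
        if len(free) < 2:
            continue
        total = int(row[free].sum())
        # random composition of `total` into len(free) parts, each >= 1
        cuts = np.sort(
            rng.choice(np.arange(1, total), size=len(free) - 1, replace=False)
        )
        parts = np.diff(np.concatenate([[0], cuts, [total]]))
        row[free] = parts
    return row


def optimize_worst_profiles(
    chain: FittedChain,
    fraction: float = 0.1,
    restarts: int = 20,
    max_rounds: int = 200,
    seed: int | np.random.Generator = 0,
) -> FittedChain:
    """Re-segmentation of the worst-matched profiles.

    Profiles are ranked by their mean point-to-point error; for the worst
    ``ceil(fraction * p)`` profiles, non-rigid segment lengths are redrawn at
    random within their sub-profiles (``restarts`` draws per profile per
    round) and a draw is kept only if that profile's error decreases.  Stops
    when a full round accepts nothing."""
    if not 0.0 < fraction <= 1.0:
        raise ConfigurationError("fraction must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    current = chain
    n_worst = int(np.ceil(fraction * chain.p))
    for _ in range(max_rounds):
        scores = current.profile_mean_point_error()
        worst = np.argsort(scores, kind="stable")[::-1][:n_worst]
        accepted = False
        for j in worst:
            j = int(j)
            for _ in range(restarts):
                new_row = _random_row(current.matrix, j, rng)
                if np.array_equal(new_row, current.matrix.entries[j]):
                    continue
                trial = build_chain(
                    current.profiles,
                    segment_matrix=_with_row(current.matrix, j, new_row),
                )
                if trial.profile_mean_point_error()[j] < scores[j]:
                    current = trial
                    scores = current.profile_mean_point_error()
                    accepted = True
        if not accepted:
            break
    return current


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_chain(chain: FittedChain, path: str | Path) -> None:
    """Serialize the fitted chain (matrix, models, errors, metrics) to JSON."""
    models = []
    for m in chain.models:
        models.append(
            {
                "type": m.type,
                "piece_length": m.piece_length,
                "dimension": m.dimension,
                "kappa": m.kappa,
                "tau": m.tau,
                "template": None if m.template is None else m.template.tolist(),
            }
        )
    payload = {
        "type_vector": list(chain.matrix.type_vector),
        "profile_ids": list(chain.matrix.profile_ids),
        "segment_matrix": chain.matrix.entries.tolist(),
        "sub_profile_of": list(chain.matrix.sub_profile_of),
        "models": models,
        "error_matrix": chain.error_matrix.tolist(),
        "metrics": {
            "E_max": chain.e_max,
            "E_mean": chain.e_mean,
            "E_profile_mean": chain.profile_mean_max_error().tolist(),
            "E_profile_point": chain.profile_mean_point_error().tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))
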