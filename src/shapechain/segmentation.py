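"""Segmentation points: relative-angle apex detection, GA placement, segment matrix.

A profile is divided at *segmentation points* into portions, each approximated
by one chain segment.  Primary points are anatomical landmarks or detected
apices (globally sharp corners); supplementary points are added so every
profile has the same number of portions, placed as evenly as possible by a
seeded genetic algorithm.

All point indices in this module are 1-based, matching the convention that a
profile's first and last points (indices 1 and N) are always segmentation
points.  Closed profiles (stored with a duplicated start point) wrap index
arithmetic through the seam.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, HomologyError
from .profiles import TargetProfile

__all__ = [
    "SegmentationPoints",
    "SegmentMatrix",
    "GASettings",
    "relative_angle",
    "relative_angles",
    "detect_apices",
    "apex_count_sweep",
    "place_supplementary_points",
    "build_segment_matrix",
    "rotate_closed_start",
]


@dataclass(frozen=True)
class SegmentationPoints:
    """Boundary indices dividing one profile into portions.

    ``indices`` are strictly increasing 1-based point indices with
    ``indices[0] == 1`` and ``indices[-1] == N``; ``primary[i]`` marks
    apex/anatomical boundaries as opposed to supplementary ones.
    """

    profile_id: str
    indices: np.ndarray
    primary: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        prim = np.asarray(self.primary, dtype=bool)
        if idx.shape != prim.shape:
            raise ConfigurationError("indices and primary flags differ in length")
        if np.any(np.diff(idx) < 1):
            raise ConfigurationError(
                f"profile {self.profile_id!r}: boundary indices must be strictly "
                f"increasing with every portion >= 1 piece, got {idx.tolist()}"
            )
        if idx[0] != 1:
            raise ConfigurationError("first segmentation point must be index 1")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "primary", prim)

    @property
    def n_portions(self) -> int:
        return len(self.indices) - 1

    def piece_counts(self) -> np.ndarray:
        return np.diff(self.indices)


@dataclass(frozen=True)
class SegmentMatrix:
    """p×q table of pieces per segment per profile, plus the segment types."""

    entries: np.ndarray  # (p, q) int
    type_vector: tuple[str, ...]
    profile_ids: tuple[str, ...]
    sub_profile_of: tuple[int, ...] = ()  # sub-profile index per column

    def __post_init__(self) -> None:
        m = np.asarray(self.entries, dtype=int)
        if m.ndim != 2:
            raise ConfigurationError("segment matrix must be 2-dimensional")
        p, q = m.shape
        if len(self.type_vector) != q:
            raise ConfigurationError(
                f"type vector length {len(self.type_vector)} != {q} columns"
            )
        bad = set(self.type_vector) - {"M", "C", "H", "G"}
        if bad:
            raise ConfigurationError(f"unknown segment types: {sorted(bad)}")
        if np.any(m < 1):
            raise HomologyError("segment matrix entries must be >= 1")
        for e, t in enumerate(self.type_vector):
            if t == "M" and len(np.unique(m[:, e])) > 1:
                raise HomologyError(
                    f"M column {e} has unequal piece counts: {m[:, e].tolist()}"
                )
        object.__setattr__(self, "entries", m)
        object.__setattr__(self, "type_vector", tuple(self.type_vector))
        object.__setattr__(self, "profile_ids", tuple(self.profile_ids))
        sub = self.sub_profile_of or tuple([0] * q)
        object.__setattr__(self, "sub_profile_of", tuple(sub))

    @property
    def p(self) -> int:
        return self.entries.shape[0]

    @property
    def q(self) -> int:
        return self.entries.shape[1]

    def boundaries(self, j: int) -> np.ndarray:
        """1-based segmentation point indices for row ``j`` (cumulative sums)."""
        return np.concatenate([[1], 1 + np.cumsum(self.entries[j])])


@dataclass(frozen=True)
class GASettings:
    """Genetic-algorithm settings for supplementary-point placement."""

    population: int = 50
    generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob: float = 0.05
    elitism: int = 1


# ---------------------------------------------------------------------------
# relative angles
# ---------------------------------------------------------------------------

def _cyclic_point(profile: TargetProfile, i: int) -> np.ndarray:
    """Point at 1-based index ``i`` with wrap-around on closed profiles."""
    n_unique = profile.n_points - 1  # closed: last point duplicates the first
    return profile.points[(i - 1) % n_unique]


def relative_angle(profile: TargetProfile, i: int, k: int = 1) -> float:
    """Relative angle (degrees, in [0, 180]) at point ``i`` over interval ``k``.

    The angle between the forward chord (from point ``i`` to point ``i+k``)
    and the backward chord (from point ``i-k`` to point ``i``): 0° on a
    straight stretch, approaching 180° at a cusp.  Closed profiles wrap.
    """
    if k < 1:
        raise ConfigurationError("interval k must be >= 1")
    n = profile.n_points
    if profile.closed:
        back = _cyclic_point(profile, i - k)
        here = _cyclic_point(profile, i)
        fwd = _cyclic_point(profile, i + k)
    else:
        if i - k < 1 or i + k > n:
            raise IndexError(
                f"point {i} with interval {k} out of range on open profile "
                f"of {n} points"
            )
        back, here, fwd = profile.points[[i - k - 1, i - 1, i + k - 1]]
    v_fwd = fwd - here
    v_back = here - back
    denom = np.linalg.norm(v_fwd) * np.linalg.norm(v_back)
    if denom == 0.0:
        return 0.0
    c = float(np.dot(v_fwd, v_back) / denom)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _admissible_indices(profile: TargetProfile, k: int) -> np.ndarray:
    """1-based indices where the relative angle is defined."""
    n = profile.n_points
    if profile.closed:
        n_unique = n - 1
        if 2 * k >= n_unique:
            raise ConfigurationError(f"interval {k} too large for {n_unique} pieces")
        return np.arange(1, n_unique + 1)
    return np.arange(1 + k, n - k + 1)


def relative_angles(profile: TargetProfile, k: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Relative angle at every admissible point; returns (indices, angles)."""
    idx = _admissible_indices(profile, k)
    if profile.closed:
        z = profile.points[:-1]
        fwd = np.roll(z, -k, axis=0) - z
        back = z - np.roll(z, k, axis=0)
    else:
        z = profile.points
        fwd = z[2 * k :] - z[k:-k]
        back = z[k:-k] - z[: -2 * k]
    denom = np.linalg.norm(fwd, axis=1) * np.linalg.norm(back, axis=1)
    denom[denom == 0.0] = np.inf
    c = np.clip(np.einsum("ij,ij->i", fwd, back) / denom, -1.0, 1.0)
    return idx, np.degrees(np.arccos(c))


# ---------------------------------------------------------------------------
# apex detection
# ---------------------------------------------------------------------------

def detect_apices(profile: TargetProfile, k: int, T: float) -> list[int]:
    """Detect globally sharp corners: one apex per contiguous run of points
    whose relative angle meets the threshold.

    Points with angle >= ``T`` are grouped into maximal contiguous runs (runs
    meeting across the seam of a closed profile are merged); within each run
    the point of largest angle is returned (lowest index on ties).
    """
    if not 0.0 < T < 180.0:
        raise ConfigurationError("threshold T must be in (0, 180) degrees")
    idx, angles = relative_angles(profile, k)
    hot = angles >= T
    if not hot.any():
        return []
    # split into contiguous runs over the admissible index sequence
    runs: list[list[int]] = []
    current: list[int] = []
    for pos in range(len(idx)):
        if hot[pos]:
            current.append(pos)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)
    if profile.closed and len(runs) > 1 and hot[0] and hot[-1]:
        # wrap-around: last run continues into the first
        runs[0] = runs.pop() + runs[0]
    apices = []
    for run in runs:
        best = max(run, key=lambda pos: (angles[pos], -idx[pos]))
        apices.append(int(idx[best]))
    return sorted(apices)


def apex_count_sweep(
    profile: TargetProfile, k_range: Sequence[int], T: float
) -> np.ndarray:
    """Number of detected apices for each interval in ``k_range``.

    Used to pick the interval where the count plateaus: local burrs vanish as
    the interval grows past their wavelength while global apices persist.
    """
    return np.array([len(detect_apices(profile, int(k), T)) for k in k_range])


def rotate_closed_start(
    profile: TargetProfile, new_start: int
) -> tuple[TargetProfile, int]:
    """Relocate the cyclic start of a closed profile to 1-based ``new_start``.

    Returns the rotated profile and the offset (so indices can be mapped
    back).  Homologous portions then start at homologous apices.
    """
    if not profile.closed:
        raise ConfigurationError("can only rotate the start of a closed profile")
    n_unique = profile.n_points - 1
    off = (new_start - 1) % n_unique
    pts = np.vstack([np.roll(profile.points[:-1], -off, axis=0),
                     profile.points[(off) % n_unique][None, :]])
    rotated = TargetProfile(
        id=profile.id,
        points=pts,
        piece_length=profile.piece_length,
        closed=True,
        group=profile.group,
    )
    return rotated, off


# ---------------------------------------------------------------------------
# supplementary-point placement (GA)
# ---------------------------------------------------------------------------

def evenness_fitness(boundaries: np.ndarray, n_points: int, q: int) -> float:
    """Sum over portions of (pieces − (N−1)/q)²: zero iff perfectly even."""
    m = np.diff(np.asarray(boundaries, dtype=float))
    return float(np.sum((m - (n_points - 1) / q) ** 2))


def evenness_lower_bound(n_pieces: int, q: int) -> float:
    """Minimum of the evenness fitness over integer partitions of ``n_pieces``
    into ``q`` portions: attained by mixing floor and ceil portion sizes."""
    s = n_pieces % q
    frac = n_pieces / q - n_pieces // q
    return s * (1.0 - frac) ** 2 + (q - s) * frac ** 2


def _even_heuristic(primaries: np.ndarray, n_points: int, q: int) -> np.ndarray:
    """Deterministic fallback: allocate portions to sub-profiles proportionally
    to their piece counts (largest remainder), then space boundaries evenly
    within each sub-profile."""
    sub_pieces = np.diff(primaries)
    n_sub = len(sub_pieces)
    quota = q * sub_pieces / sub_pieces.sum()
    alloc = np.maximum(np.floor(quota).astype(int), 1)
    # largest-remainder repair to hit sum q within [1, pieces] bounds
    while alloc.sum() < q:
        room = alloc < sub_pieces
        rem = np.where(room, quota - alloc, -np.inf)
        alloc[int(np.argmax(rem))] += 1
    while alloc.sum() > q:
        over = alloc > 1
        rem = np.where(over, quota - alloc, np.inf)
        alloc[int(np.argmin(rem))] -= 1
    boundaries = [int(primaries[0])]
    for i in range(n_sub):
        a, b = primaries[i], primaries[i + 1]
        inner = np.round(np.linspace(a, b, alloc[i] + 1)).astype(int)
        # enforce strict monotonicity inside the sub-profile
        for v in inner[1:]:
            v = max(v, boundaries[-1] + 1)
            boundaries.append(min(int(v), int(b)))
        boundaries[-1] = int(b)
    return np.asarray(boundaries, dtype=int)


def place_supplementary_points(
    profile: TargetProfile,
    primary: SegmentationPoints | Sequence[int],
    q: int,
    ga: GASettings | None = None,
    seed: int | np.random.Generator = 0,
) -> SegmentationPoints:
    """Place supplementary segmentation points so the profile has ``q`` portions.

    Minimizes the evenness fitness (sum of squared deviations of portion piece
    counts from the ideal (N−1)/q) over placements of the supplementary points,
    keeping every primary point fixed.  A seeded genetic algorithm (integer
    genes = supplementary indices, one-point crossover, per-gene mutation,
    elitism) is polished by a ±1 hill climb; the deterministic even-spacing
    heuristic seeds the population, so the result never does worse than it.
    """
    ga = ga or GASettings()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = profile.n_points
    if isinstance(primary, SegmentationPoints):
        prim_idx = primary.indices
    else:
        prim_idx = np.asarray(sorted(set(primary) | {1, n}), dtype=int)
    if prim_idx[0] != 1 or prim_idx[-1] != n:
        raise ConfigurationError("primary indices must include 1 and N")
    n_primary_portions = len(prim_idx) - 1
    n_supp = q + 1 - len(prim_idx)
    if n_supp < 0:
        raise ConfigurationError(
            f"q={q} portions but {len(prim_idx)} primary boundaries already "
            f"define {n_primary_portions} portions"
        )
    if q > n - 1:
        raise ConfigurationError(f"q={q} portions exceed {n - 1} pieces")

    prim_set = set(prim_idx.tolist())
    allowed = np.array([i for i in range(2, n) if i not in prim_set], dtype=int)

    def full_boundaries(supp: np.ndarray) -> np.ndarray:
        return np.sort(np.concatenate([prim_idx, supp]))

    def fitness(supp: np.ndarray) -> float:
        return evenness_fitness(full_boundaries(supp), n, q)

    if n_supp == 0:
        best = np.array([], dtype=int)
    else:
        heur = _even_heuristic(prim_idx, n, q)
        heur_supp = np.array(sorted(set(heur.tolist()) - prim_set), dtype=int)
        if len(heur_supp) != n_supp:
            # heuristic collided with primaries; fill from unused indices
            extra = [a for a in allowed if a not in set(heur_supp.tolist())]
            heur_supp = np.sort(
                np.concatenate([heur_supp, extra[: n_supp - len(heur_supp)]])
            )
        best = _ga_minimize(fitness, allowed, n_supp, heur_supp, ga, rng)
        best = _hill_climb(fitness, best, allowed)

    boundaries = full_boundaries(best)
    flags = np.array([int(b) in prim_set for b in boundaries])
    return SegmentationPoints(profile_id=profile.id, indices=boundaries, primary=flags)


def _ga_minimize(
    fitness,
    allowed: np.ndarray,
    n_genes: int,
    heuristic: np.ndarray,
    ga: GASettings,
    rng: np.random.Generator,
) -> np.ndarray:
    def random_individual() -> np.ndarray:
        return np.sort(rng.choice(allowed, size=n_genes, replace=False))

    def repair(genes: np.ndarray) -> np.ndarray:
        genes = np.clip(genes, allowed[0], allowed[-1])
        ok = np.isin(genes, allowed)
        distinct = list(dict.fromkeys(int(g) for g, o in zip(genes, ok) if o))
        if len(distinct) < n_genes:
            pool = [a for a in allowed if a not in set(distinct)]
            picks = rng.choice(len(pool), size=n_genes - len(distinct), replace=False)
            distinct += [pool[i] for i in picks]
        return np.sort(np.asarray(distinct[:n_genes], dtype=int))

    pop = [heuristic.copy()] + [random_individual() for _ in range(ga.population - 1)]
    scores = np.array([fitness(ind) for ind in pop])
    for _ in range(ga.generations):
        order = np.argsort(scores, kind="stable")
        elite = [pop[i].copy() for i in order[: ga.elitism]]
        # binary tournament selection
        children: list[np.ndarray] = []
        while len(children) < ga.population - ga.elitism:
            a, b = rng.integers(0, ga.population, size=2)
            p1 = pop[a] if scores[a] <= scores[b] else pop[b]
            a, b = rng.integers(0, ga.population, size=2)
            p2 = pop[a] if scores[a] <= scores[b] else pop[b]
            c1, c2 = p1.copy(), p2.copy()
            if n_genes > 1 and rng.random() < ga.crossover_prob:
                cut = int(rng.integers(1, n_genes))
                c1 = np.concatenate([p1[:cut], p2[cut:]])
                c2 = np.concatenate([p2[:cut], p1[cut:]])
            for c in (c1, c2):
                mut = rng.random(n_genes) < ga.mutation_prob
                if mut.any():
                    step = rng.integers(-3, 4, size=int(mut.sum()))
                    c[mut] = c[mut] + step
                children.append(repair(c))
        pop = elite + children[: ga.population - ga.elitism]
        scores = np.array([fitness(ind) for ind in pop])
    return pop[int(np.argmin(scores))]


def _hill_climb(fitness, genes: np.ndarray, allowed: np.ndarray) -> np.ndarray:
    """Deterministic ±1 local search on each supplementary index."""
    allowed_set = set(allowed.tolist())
    best = genes.copy()
    best_f = fitness(best)
    improved = True
    while improved:
        improved = False
        for gi in range(len(best)):
            for step in (-1, 1):
                cand = best.copy()
                cand[gi] = cand[gi] + step
                if int(cand[gi]) not in allowed_set:
                    continue
                cand = np.sort(cand)
                if len(np.unique(cand)) < len(cand):
                    continue
                f = fitness(cand)
                if f < best_f - 1e-12:
                    best, best_f = cand, f
                    improved = True
    return best


# ---------------------------------------------------------------------------
# segment matrix
# ---------------------------------------------------------------------------

def build_segment_matrix(
    all_points: Sequence[SegmentationPoints],
    type_vector: Sequence[str],
    profile_lengths: Sequence[int] | None = None,
) -> SegmentMatrix:
    """Assemble the p×q segment matrix from per-profile boundaries.

    ``m_j^e`` is the piece count of portion ``e`` on profile ``j``.  Columns
    typed M must end up equal across profiles: rows deviating from the column
    consensus (the most common value) donate/borrow pieces from the nearest
    non-M column within the same sub-profile, preserving row sums.
    """
    type_vector = tuple(type_vector)
    q = len(type_vector)
    rows = []
    for sp in all_points:
        if sp.n_portions != q:
            raise HomologyError(
                f"profile {sp.profile_id!r} has {sp.n_portions} portions, "
                f"expected {q}"
            )
        rows.append(sp.piece_counts())
    m = np.array(rows, dtype=int)
    if profile_lengths is not None:
        for j, (sp, n) in enumerate(zip(all_points, profile_lengths)):
            if m[j].sum() != n - 1:
                raise HomologyError(
                    f"profile {sp.profile_id!r}: row sum {m[j].sum()} != "
                    f"N-1 = {n - 1}"
                )

    # sub-profile id per column, from the primary flags of the first profile
    prim = np.asarray(all_points[0].primary, dtype=bool)
    sub_of = np.concatenate([[0], np.cumsum(prim[1:-1])]).astype(int)

    # equalize M columns
    offenders: list[str] = []
    for e, t in enumerate(type_vector):
        if t != "M":
            continue
        col = m[:, e]
        vals, counts = np.unique(col, return_counts=True)
        target = int(vals[np.argmax(counts)])
        for j in range(m.shape[0]):
            delta = int(m[j, e]) - target
            if delta == 0:
                continue
            # candidate recipients: non-M columns in the same sub-profile,
            # nearest first
            cands = [
                f for f in range(q)
                if f != e and type_vector[f] != "M" and sub_of[f] == sub_of[e]
            ]
            cands.sort(key=lambda f: abs(f - e))
            moved = False
            for f in cands:
                if m[j, f] + delta >= 1:
                    m[j, f] += delta
                    m[j, e] = target
                    moved = True
                    break
            if not moved:
                offenders.append(all_points[j].profile_id)
    if offenders:
        raise HomologyError(
            "cannot equalize M-segment piece counts for profiles: "
            + ", ".join(sorted(set(offenders)))
        )
    return SegmentMatrix(
        entries=m,
        type_vector=type_vector,
        profile_ids=tuple(sp.profile_id for sp in all_points),
        sub_profile_of=tuple(int(s) for s in sub_of),
    )
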