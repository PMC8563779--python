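# Methods

## Model and procedure

A family of p outline curves is jointly approximated by one *shape-changing
chain* of q typed segments. The pipeline is:

1. **Resampling.** Each design profile is converted to a target profile of
   equal-length pieces. The piece count is `round(arc_length /
   piece_length)`; the piece (chord) length is then re-solved by bisection so
   that walking constant-length chords along the curve lands exactly on the
   endpoint. All resampled points lie on the input polyline and every chord
   is equal to machine precision, including across polygonal corners. Closed
   profiles are stored with the start point duplicated at the end, so a
   profile always has `N − 1` pieces and the open-curve bookkeeping applies
   unchanged. A common piece length across a study (user-set, or longest arc
   length divided by a piece budget) keeps piece counts comparable between
   profiles, which the length-ratio variables require.
2. **Segmentation.** Primary segmentation points are anatomical anchors or
   apices from the relative-angle detector; supplementary points are placed
   by a genetic algorithm; the piece counts between consecutive boundaries
   form the segment matrix.
3. **Fitting.** Per column, the typed segment model is fitted on the
   corresponding portions of all profiles; generated segment polylines are
   rigidly aligned to each portion; the error matrix holds the maximum
   point-to-point distances.
4. **Optimization.** Two loops refine segment lengths without moving primary
   boundaries (details below).
5. **Statistics.** Chain parameters become a per-profile feature table for
   stepwise discriminant analysis with leave-one-out cross-validation.

## Segment types and estimators

* **M** — rigid-only (no scaling) generalized Procrustes mean of portions
  with equal piece counts, resampled back to equal spacing. Generalized
  Procrustes iterations stop when the mean shape moves by less than 1e−9
  (relative); proper rotations only.
* **C** — per-portion total-least-squares circle fit (Pratt's algebraic
  formulation, which contains straight lines as the zero-curvature case),
  then the unweighted mean curvature across portions. Curvatures below
  1e−12 per piece length are snapped to exactly zero so straight regions
  generate straight polylines.
* **H** — discrete Frenet estimates: the turning angle θ at each vertex
  gives curvature `2 sin(θ/2)/h`, which is *exact* for chord-sampled
  circles; torsion comes from the signed angle between consecutive
  binormals. Both are averaged along the portion and then across portions
  (unweighted). Accuracy is O(h²) in the piece length h.
* **G** — portions are rescaled to unit arc length, resampled to a common
  point count (the largest portion's, preserving the detail of the longest
  exemplar), and averaged with a rigid Procrustes mean stored as a unit
  template.

Curvature/torsion averaging is per-portion-then-unweighted-mean by design;
arc-length weighting was considered and rejected for simplicity.

Segment generation samples arcs and helices at chords equal to the piece
length (the helix arc-length step is solved by bisection to 1e−10); G
templates are scaled to `m · piece_length` and resampled. Alignment is
orthogonal Procrustes restricted to det(R) = +1 — reflections are forbidden
because biological outlines have handedness. The alignment objective is
least squares over all corresponding points even though the reported error
is the maximum distance; least squares is stable, standard, and
differentiable, and the max is reported afterwards.

## Corner detection and supplementary placement

The relative angle at point i with interval k is the angle between the
forward chord (i → i+k) and backward chord (i−k → i), clamped into
arccos's domain; it is invariant to rigid motion and uniform scale. Points
at or above the threshold T are grouped into maximal contiguous runs; each
run contributes its argmax (lowest index on ties), and runs meeting across a
closed profile's seam are merged. Sweeping k and watching the apex count
plateau separates high-frequency burrs (which fade as k grows past their
wavelength) from global apices (which persist); the choice of (k, T) per
data set remains with the user.

For closed profiles the cyclic start is relocated to the first detected
apex before boundaries are built, so homologous portions start at
homologous apices.

Supplementary points minimize the evenness fitness (sum of squared
deviations of portion piece counts from (N−1)/q) with all primaries held
fixed. The GA uses integer genes (the supplementary indices), population
50, 100 generations, one-point crossover p = 0.8, per-gene mutation
p = 0.05 (a ±3 jitter), binary tournament selection and elitism 1, all
driven by one seeded generator. The initial population contains the
deterministic even-spacing heuristic (portions allocated to sub-profiles by
largest remainder, then even spacing), so the GA never returns anything
worse; a final deterministic ±1 hill climb polishes the best individual,
which also makes the exact optimum reliable on small instances. The
attainable minimum for an unconstrained profile is
`s(1−f)² + (q−s)f²` with `s = (N−1) mod q` and `f` the fractional part of
`(N−1)/q`; the tests assert the GA reaches it.

## Optimizers

* **Piece transfer.** Per profile: move one piece from the
  highest-error non-M segment to the lowest-error non-M segment within the
  same sub-profile, rebuild, and keep the move only if that profile's mean
  point error Ẽ_j decreases; stop after a full pass with no accepted move
  (or 200 passes). Greedy acceptance makes the error sequence monotone; a
  one-piece step is the smallest move that preserves integrality.
* **Worst-profile re-segmentation.** Rank profiles by Ẽ_j; for the worst
  ceil(fraction · p) (default 10%), redraw the non-M lengths within each
  sub-profile uniformly at random (a random composition preserving the
  sub-profile total and all M entries), accepting per profile only on
  improvement; stop when a round accepts nothing.

Both preserve row sums and M-column equality by construction, and both are
deterministic under a fixed seed. Transfers never cross primary boundaries,
so homology established by segmentation is never undone.

When building a segment matrix from detected boundaries, M columns that
disagree across profiles are equalized to the column's most common value,
donating or borrowing pieces from the nearest non-M column in the same
sub-profile; if no such column exists the conflict is an error naming the
offending profiles.

## Feature variables

2D: the signed orientation difference σ between the last piece of segment e
and the first piece of segment e+1, wrapped to [−180°, 180°) with
counter-clockwise positive (q−1 values per profile); the subtraction of
planar direction angles is inherently signed, and an absolute-value option
exists. Length ratios g = m_j^e / max_r m_r^e lie in (0, 1] with the max
attained. Optional extras: profile arc length, apex count and burr count
(the raw apex count at a user-stated small interval and threshold). 3D:
unit start-to-end direction vectors per segment (3 components each) and
anchor-point coordinates. The fitting-variable counts are q + #non-M in 2D
and 3q + #non-M in 3D; analysis counts are (q−1) + extras in 2D and
3q + 3·#anchors in 3D.

## Discriminant analysis

Forward stepwise selection with backward removal on the partial F statistic
derived from Wilks' lambda (Λ = det(W)/det(T)); defaults f_enter = 3.84 and
f_remove = 2.71, the classic SPSS thresholds. Ties break to the smaller
variable index; selection stops when no candidate reaches f_enter or when
the sample-size guard (more samples than variables plus groups) trips. If
nothing enters, an explicit empty-model result is returned. The classifier
is a linear discriminant with pooled covariance and equal priors (group
sizes are typically unbalanced; equal priors mirror the common software
default). Canonical components solve the symmetric generalized eigenproblem
of between- vs within-group scatter, returning g−1 axes with a
largest-loading-positive sign convention. LOOCV refits the classifier on
each n−1 subset with the variable set fixed from the full-data selection
(selection is not re-run per fold); folds that would leave a group with
fewer than two training samples are skipped with a warning.

## Synthetic data

Three generators provide known ground truth:

* **Chain profiles** (2D, open): segment polylines from fixed ground-truth
  templates (a gently curved rigid template; a sinuous unit template for
  scalable segments) are concatenated with per-profile joint rotations and
  variable-segment lengths drawn around group means (defaults: joint angles
  25°/−35° with SD 2°, scalable length 40 pieces with SD 4, p = 20), then
  isotropic Gaussian coordinate noise (default SD 0.05 piece lengths) is
  added and the polyline re-resampled to equal pieces. True joint arc
  positions are mapped onto the resampled index grid and returned.
* **Leaf-like outlines** (2D, closed): an elliptical base with a
  raised-cosine lobe term (sharp tips, flat sinuses — default 5 lobes,
  amplitude 0.4, sharpness 4) plus a high-frequency burr sinusoid
  (amplitude 0.02, frequency 60). True tip locations are returned.
* **Suture-like curves** (3D, open): a smooth base arc with group-specific
  tilt, shift and scale, mild per-profile size wobble and coordinate noise;
  endpoint anchors are returned.

What the generators do *not* emulate: digitization artifacts of real
contour tracing, within-group allometry, correlated (non-isotropic) noise,
and outlines whose curvature varies at the piece scale (hairpins sharper
than the piece length are rejected by the resampler rather than silently
smoothed). Passing tests therefore demonstrate correct recovery under
idealized noise, not robustness to every property of real traced outlines.

Joint angles beyond roughly ±60° produce near-hairpin corners that
equal-chord resampling cannot honor at the default piece length; the
generators' defaults stay well inside that regime, matching the smooth
biological outlines the method targets.

## Numerical choices

* Piece-length tolerance 1% relative everywhere; chord-solving bisections
  run to ~1e−14 relative.
* Procrustes convergence 1e−9; Kabsch SVD with determinant correction.
* Pratt circle fit selects the smallest non-negative generalized
  eigenvalue with a roundoff guard (the exact-fit eigenvalue can land at
  −1e−16).
* Angles are handled in degrees throughout.
* All stochastic components (GA, worst-profile redraws, generators) take
  either a seed or a Generator; a single seed drives a full pipeline run.

## Problem sizes

The test suite and the reproduction script use p = 20–30 profiles of
roughly 80 pieces with q = 2–3 segments for the recovery studies, and
350–450-piece outlines for apex detection — sizes at which every stage of
the method is exercised and the chain fit is fully determined, chosen to
keep the whole suite fast to iterate on.

## Known limitations

* C/H fitting assumes portions are well approximated by a single arc/helix;
  strongly varying curvature inside one portion biases κ toward an average.
* The piece-transfer optimizer is greedy and can stall at local optima far
  from the global split; the worst-profile re-segmentation escapes some of
  these but is itself randomized.
* M-column equalization changes neighboring segment lengths by the
  disagreement amount; large disagreements indicate a poor segmentation
  rather than something the builder should silently fix.
* Stepwise selection inherits the known instabilities of stepwise methods;
  thresholds are configurable and the selection path is reported so users
  can audit it.
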