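"""Similarity-invariant scoring of recalled object layouts.

The central measure, *pattern accuracy*, asks how well a participant
reproduced the positional pattern of the objects in a room irrespective of
where the pattern sat, how it was oriented, how large it was drawn, and
which object went where.  The recalled layout is translated (centroids
matched), rotated (closed-form proper rotation minimizing paired RMSD),
and scaled (closed-form least-squares factor, bounded) into alignment with
the true layout; the residual error is the sum over recalled positions of
the squared distance to the *closest* true position, and accuracy is
``1 / (1 + SSE)``.

Because the alignment must ignore object identity, the rotation/scale
solves (which need paired points) are wrapped in an alternating
assignment/transform optimization with multiple starts; at small n the
result is verifiably the global optimum over all correspondences.

Two companion measures decompose recall quality further:

* *environmental geometry* — how little transformation the recalled
  pattern needed, i.e. how well it was anchored to the room's perimeter:
  the (non-positive) difference between untransformed accuracy and pattern
  accuracy;
* *object identity* — how many objects were recalled at their correct
  positions within the aligned pattern.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .errors import DegenerateGeometryError, InvalidInputError
from .patterns import PositionalPattern, rotation_matrix, wrap_angle

_COINCIDENT_TOL = 1e-12


@dataclass(frozen=True)
class SimilarityTransform:
    """Rotation ``theta`` (radians), positive ``scale``, and 2-vector translation.

    Applied to a point ``p`` as ``scale * R(theta) @ p + translation``.
    Reflections are deliberately excluded: responses are produced by
    drag-and-drop in the same 2D plane as the overview, so only proper
    rotations are physically meaningful.
    """

    theta: float
    scale: float
    translation: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.translation, dtype=float).reshape(2)
        t.setflags(write=False)
        object.__setattr__(self, "theta", wrap_angle(float(self.theta)))
        object.__setattr__(self, "scale", float(self.scale))
        object.__setattr__(self, "translation", t)
        if not self.scale > 0:
            raise InvalidInputError(f"scale must be positive, got {self.scale}")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(0.0, 1.0, np.zeros(2))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return self.scale * pts @ rotation_matrix(self.theta).T + self.translation

    def apply_pattern(self, pattern: PositionalPattern) -> PositionalPattern:
        return pattern.with_points(self.apply(pattern.points))


@dataclass(frozen=True)
class Correspondence:
    """A bijection from recalled-point indices to true-point indices."""

    assignment: tuple[int, ...]

    def __post_init__(self):
        a = tuple(int(i) for i in self.assignment)
        if sorted(a) != list(range(len(a))):
            raise InvalidInputError(f"assignment is not a permutation: {a}")
        object.__setattr__(self, "assignment", a)

    def __len__(self) -> int:
        return len(self.assignment)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.assignment, dtype=int)


@dataclass(frozen=True)
class AlignConfig:
    """Tunables of the correspondence-free alignment.

    scale_min, scale_max
        Bounds on the fitted scale factor (default [1/3, 3]).  Unbounded
        scaling can collapse a response onto a single true position under
        nearest-position scoring; the bounds keep the optimum meaningful.
    n_grid_rotations
        Number of evenly spaced rotation angles used to seed candidate
        correspondences (multi-start).
    max_iter
        Cap on assignment/transform alternation rounds per start.
    correspondence
        "free" (default): the correspondence is optimized, honoring the
        identity-agnostic definition of pattern accuracy.  "label": points
        are paired by object label inside the closed-form solves.
    """

    scale_min: float = 1.0 / 3.0
    scale_max: float = 3.0
    n_grid_rotations: int = 24
    max_iter: int = 50
    correspondence: str = "free"

    def __post_init__(self):
        if not (0 < self.scale_min <= 1.0 <= self.scale_max):
            raise InvalidInputError(
                f"scale bounds must straddle 1: [{self.scale_min}, {self.scale_max}]"
            )
        if self.correspondence not in ("free", "label"):
            raise InvalidInputError(f"unknown correspondence mode {self.correspondence!r}")


@dataclass(frozen=True)
class ScoreSet:
    """Per-trial scores and the alignment that produced them.

    ``environmental_geometry`` and ``object_identity`` are ``None`` when the
    trial is classified as failed (at or below chance level): a failed trial
    carries no evidence that allocentric encoding took place, so the
    decomposition is undefined.
    """

    sse_post: float
    pattern_accuracy: float
    raw_accuracy: float
    environmental_geometry: Optional[float]
    object_identity: Optional[int]
    failed: bool
    transform: SimilarityTransform
    correspondence: Correspondence

    def mark_failed(self, failed: bool) -> "ScoreSet":
        """Return a copy with the failed flag applied (masking the decomposition)."""
        if failed:
            return replace(
                self, failed=True, environmental_geometry=None, object_identity=None
            )
        return replace(
            self,
            failed=False,
            environmental_geometry=self.raw_accuracy - self.pattern_accuracy,
            object_identity=self.object_identity,
        )


# ---------------------------------------------------------------------------
# closed-form building blocks (paired points)
# ---------------------------------------------------------------------------


def _paired(source: PositionalPattern, target: PositionalPattern,
            corr: Correspondence) -> tuple[np.ndarray, np.ndarray]:
    if len(source) != len(target):
        raise InvalidInputError(
            f"patterns of unequal length: {len(source)} vs {len(target)}"
        )
    if len(corr) != len(source):
        raise InvalidInputError("correspondence length does not match patterns")
    return source.points, target.points[corr.as_array()]


def optimal_rotation(source: PositionalPattern, target: PositionalPattern,
                     corr: Correspondence) -> float:
    """Proper-rotation angle minimizing paired SSE of source against target.

    Both patterns are expected centered (centroid at the origin); the angle
    comes in closed form from the 2x2 cross-covariance of the paired points.
    """
    p, q = _paired(source, target, corr)
    if float(np.sum(p * p)) < _COINCIDENT_TOL:
        raise DegenerateGeometryError("all source points coincident; rotation undefined")
    a = float(np.sum(p * q))                      # trace term
    b = float(np.sum(p[:, 0] * q[:, 1] - p[:, 1] * q[:, 0]))  # cross term
    if math.hypot(a, b) < _COINCIDENT_TOL:
        return 0.0  # rotation indeterminate; any angle is equally good
    return wrap_angle(math.atan2(b, a))


def optimal_scale(source: PositionalPattern, target: PositionalPattern,
                  corr: Correspondence, scale_min: float = 1.0 / 3.0,
                  scale_max: float = 3.0) -> float:
    """Least-squares scale of (rotation-aligned, centered) source onto target.

    The unconstrained optimum ``sum(p.q) / sum(|p|^2)`` is clipped into
    ``[scale_min, scale_max]``.
    """
    p, q = _paired(source, target, corr)
    denom = float(np.sum(p * p))
    if denom < _COINCIDENT_TOL:
        raise DegenerateGeometryError("zero-norm source pattern; scale undefined")
    s = float(np.sum(p * q)) / denom
    return float(np.clip(s, scale_min, scale_max))


def _solve_transform(response: PositionalPattern, truth: PositionalPattern,
                     corr: Correspondence, config: AlignConfig) -> SimilarityTransform:
    """Closed-form similarity transform for a fixed correspondence.

    Centroids are matched, then rotation and (clipped) scale are solved on
    the centered paired points; the translation follows.
    """
    p = response.points - response.points.mean(axis=0)
    q = truth.points - truth.points.mean(axis=0)
    qp = q[corr.as_array()]
    a = float(np.sum(p * qp))
    b = float(np.sum(p[:, 0] * qp[:, 1] - p[:, 1] * qp[:, 0]))
    norm_p = float(np.sum(p * p))
    if norm_p < _COINCIDENT_TOL:
        raise DegenerateGeometryError("all response points coincident")
    if math.hypot(a, b) < _COINCIDENT_TOL:
        theta = 0.0
        s = 1.0
    else:
        theta = math.atan2(b, a)
        s = math.hypot(a, b) / norm_p  # = sum(q . R p) / sum(|p|^2) at optimal theta
    s = float(np.clip(s, config.scale_min, config.scale_max))
    r = rotation_matrix(theta)
    t = truth.points.mean(axis=0) - s * r @ response.points.mean(axis=0)
    return SimilarityTransform(theta, s, t)


def paired_sse(response: PositionalPattern, truth: PositionalPattern,
               corr: Correspondence, transform: SimilarityTransform) -> float:
    """Bijective SSE of the transformed response against its assigned truths."""
    moved = transform.apply(response.points)
    d = moved - truth.points[corr.as_array()]
    return float(np.sum(d * d))


# ---------------------------------------------------------------------------
# nearest-position residual and accuracy
# ---------------------------------------------------------------------------


def nn_sse(pattern: PositionalPattern, truth: PositionalPattern) -> float:
    """Sum over pattern points of squared distance to the nearest true position.

    The mapping need not be bijective: several recalled points may share a
    nearest true position.
    """
    if truth is None or len(truth) == 0:
        raise InvalidInputError("truth pattern must be non-empty")
    d2 = cdist(pattern.points, truth.points, metric="sqeuclidean")
    return float(d2.min(axis=1).sum())


def accuracy_from_sse(sse: float) -> float:
    """Map a sum of squared errors to an accuracy score in (0, 1].

    Uses ``1 / (1 + SSE)``: bounded, equal to 1 exactly at zero error, and
    strictly decreasing in the error.
    """
    if not np.isfinite(sse) or sse < 0:
        raise InvalidInputError(f"sse must be finite and >= 0, got {sse}")
    return 1.0 / (1.0 + float(sse))


# ---------------------------------------------------------------------------
# correspondence-free alignment
# ---------------------------------------------------------------------------


def _label_correspondence(response: PositionalPattern,
                          truth: PositionalPattern) -> Correspondence:
    idx = truth.label_index()
    return Correspondence(tuple(idx[lab] for lab in response.labels))


def _best_assignment(moved: np.ndarray, truth_pts: np.ndarray) -> tuple[int, ...]:
    cost = cdist(moved, truth_pts, metric="sqeuclidean")
    rows, cols = linear_sum_assignment(cost)
    out = np.empty(len(cols), dtype=int)
    out[rows] = cols
    return tuple(int(c) for c in out)


def align(response: PositionalPattern, truth: PositionalPattern,
          config: AlignConfig | None = None
          ) -> tuple[SimilarityTransform, Correspondence]:
    """Find the similarity transform and correspondence aligning a response to truth.

    Multi-start alternating optimization: candidate correspondences are
    seeded from the label matching and from minimal-cost assignments at a
    grid of rotations; each start alternates closed-form transform solves
    with optimal assignments (coordinate descent on the bijective paired
    SSE) until the assignment stabilizes.  The winner minimizes the
    bijective paired SSE; ties break toward the smaller rotation, then the
    smaller log-scale.  The identity transform is always kept as a
    candidate.

    Scoring additionally guarantees that aligning never hurts: see
    :func:`score_trial`, which falls back to the identity transform for the
    rare degenerate response whose best alignment leaves a larger
    nearest-position error than no alignment at all.
    """
    config = config or AlignConfig()
    if len(response) != len(truth):
        raise InvalidInputError(
            f"response has {len(response)} objects, truth has {len(truth)}"
        )
    if not response.same_label_set(truth):
        raise InvalidInputError(
            f"label sets differ: {sorted(response.labels)} vs {sorted(truth.labels)}"
        )

    label_corr = _label_correspondence(response, truth)
    p_cent = response.points - response.points.mean(axis=0)
    q_cent = truth.points - truth.points.mean(axis=0)

    starts: list[tuple[int, ...]] = [label_corr.assignment]
    if config.correspondence == "free":
        seen = {label_corr.assignment}
        for k in range(config.n_grid_rotations):
            ang = 2.0 * np.pi * k / config.n_grid_rotations
            perm = _best_assignment(p_cent @ rotation_matrix(ang).T, q_cent)
            if perm not in seen:
                seen.add(perm)
                starts.append(perm)

    candidates: list[tuple[SimilarityTransform, Correspondence]] = []
    for start in starts:
        perm = start
        transform = None
        for _ in range(config.max_iter):
            transform = _solve_transform(response, truth, Correspondence(perm), config)
            if config.correspondence == "label":
                break
            new_perm = _best_assignment(transform.apply(response.points), truth.points)
            if new_perm == perm:
                break
            perm = new_perm
        candidates.append((transform, Correspondence(perm)))

    ident = SimilarityTransform.identity()
    ident_perm = (_best_assignment(response.points, truth.points)
                  if config.correspondence == "free" else label_corr.assignment)
    ident_cand = (ident, Correspondence(ident_perm))
    candidates.append(ident_cand)

    best_sse = min(paired_sse(response, truth, c, t) for t, c in candidates)
    tol = 1e-9 * (1.0 + best_sse)
    tied = [c for c in candidates
            if paired_sse(response, truth, c[1], c[0]) <= best_sse + tol]
    return min(tied, key=lambda c: (abs(c[0].theta), abs(math.log(c[0].scale))))


def exhaustive_align(response: PositionalPattern, truth: PositionalPattern,
                     config: AlignConfig | None = None
                     ) -> tuple[SimilarityTransform, Correspondence, float]:
    """Global alignment by brute force over all n! correspondences.

    Each correspondence is solved in closed form; the minimum bijective SSE
    wins.  Exponential in n — intended as a verification oracle for small
    patterns, not for production scoring.
    """
    config = config or AlignConfig()
    if len(response) != len(truth):
        raise InvalidInputError("patterns of unequal length")
    best = None
    for perm in itertools.permutations(range(len(truth))):
        corr = Correspondence(perm)
        transform = _solve_transform(response, truth, corr, config)
        sse = paired_sse(response, truth, corr, transform)
        if best is None or sse < best[2] - 1e-15:
            best = (transform, corr, sse)
    return best


# ---------------------------------------------------------------------------
# trial-level measures
# ---------------------------------------------------------------------------


def raw_accuracy(response: PositionalPattern, truth: PositionalPattern) -> float:
    """Accuracy of the recalled layout with no transformation applied."""
    return accuracy_from_sse(nn_sse(response, truth))


def _aligned_or_identity(response: PositionalPattern,
                         truth: PositionalPattern,
                         config: AlignConfig
                         ) -> tuple[SimilarityTransform, Correspondence, float]:
    """Align, then fall back to no transformation if that scores better.

    The final error measure is the nearest-position SSE; on rare degenerate
    responses the bijective optimum can leave a larger nearest-position
    error than the untransformed response, and scoring must never reward
    alignment for its own sake.
    """
    transform, corr = align(response, truth, config)
    sse_post = nn_sse(transform.apply_pattern(response), truth)
    sse_raw = nn_sse(response, truth)
    if sse_post > sse_raw:
        transform = SimilarityTransform.identity()
        corr = Correspondence(_best_assignment(response.points, truth.points)
                              if config.correspondence == "free"
                              else _label_correspondence(response, truth)
                              .assignment)
        sse_post = sse_raw
    return transform, corr, sse_post


def pattern_accuracy(response: PositionalPattern, truth: PositionalPattern,
                     config: AlignConfig | None = None) -> float:
    """Similarity-invariant accuracy of the recalled positional pattern."""
    _, _, sse_post = _aligned_or_identity(response, truth,
                                          config or AlignConfig())
    return accuracy_from_sse(sse_post)


def score_trial(response: PositionalPattern, truth: PositionalPattern,
                config: AlignConfig | None = None) -> ScoreSet:
    """Full per-trial scoring: alignment, accuracy, and its decomposition.

    The returned ScoreSet has ``failed=False``; chance-level classification
    is applied afterwards (see :mod:`allomem.chance`) via ``mark_failed``.
    """
    config = config or AlignConfig()
    transform, corr, sse_post = _aligned_or_identity(response, truth, config)
    acc_post = accuracy_from_sse(sse_post)
    acc_pre = raw_accuracy(response, truth)
    truth_labels = truth.labels
    n_correct = sum(
        1 for i, j in enumerate(corr.assignment)
        if response.labels[i] == truth_labels[j]
    )
    return ScoreSet(
        sse_post=sse_post,
        pattern_accuracy=acc_post,
        raw_accuracy=acc_pre,
        environmental_geometry=acc_pre - acc_post,
        object_identity=n_correct,
        failed=False,
        transform=transform,
        correspondence=corr,
    )


def environmental_geometry(score_set: ScoreSet) -> Optional[float]:
    """Anchoring of the recalled pattern to the room: ``raw - pattern`` accuracy.

    Zero when the identity transform was already optimal, increasingly
    negative the more translation/rotation/scaling the response needed;
    ``None`` for failed trials.
    """
    if score_set.failed:
        return None
    return score_set.raw_accuracy - score_set.pattern_accuracy


def object_identity(score_set: ScoreSet, response: PositionalPattern,
                    truth: PositionalPattern) -> Optional[int]:
    """Count of objects whose label matches their assigned true position.

    Requires at least a coarse pattern-level match: ``None`` for failed
    trials, where the correspondence is meaningless.
    """
    if score_set.failed:
        return None
    return sum(
        1 for i, j in enumerate(score_set.correspondence.assignment)
        if response.labels[i] == truth.labels[j]
    )
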