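"""Unit and oracle tests for the similarity-invariant scoring pipeline."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from allomem import (
    AlignConfig,
    Correspondence,
    PositionalPattern,
    SimilarityTransform,
    accuracy_from_sse,
    align,
    environmental_geometry,
    exhaustive_align,
    nn_sse,
    object_identity,
    optimal_rotation,
    optimal_scale,
    pattern_accuracy,
    raw_accuracy,
    score_trial,
)
from allomem.errors import DegenerateGeometryError, InvalidInputError
from allomem.scoring import paired_sse

from conftest import random_pattern


def identity_corr(n):
    return Correspondence(tuple(range(n)))


# ---------------------------------------------------------------------------
# closed-form rotation and scale
# ---------------------------------------------------------------------------


class TestOptimalRotation:
    def test_aligned_patterns_need_no_rotation(self, rng):
        p = random_pattern(rng).centered()
        assert optimal_rotation(p, p, identity_corr(5)) == pytest.approx(0.0)

    def test_inverts_a_pure_rotation(self, rng):
        p = random_pattern(rng).centered()
        rotated = SimilarityTransform(np.pi / 2, 1.0, np.zeros(2)).apply_pattern(p)
        theta = optimal_rotation(rotated, p, identity_corr(5))
        assert theta == pytest.approx(-np.pi / 2, abs=1e-12)

    def test_matches_grid_search_on_jittered_patterns(self, rng):
        """Closed form equals a 0.0005-rad brute-force grid search."""
        grid = np.arange(-np.pi, np.pi, 0.0005)
        cos, sin = np.cos(grid), np.sin(grid)
        for _ in range(100):
            target = random_pattern(rng).centered()
            theta_true = rng.uniform(-np.pi, np.pi)
            source = SimilarityTransform(theta_true, 1.0, np.zeros(2)) \
                .apply_pattern(target)
            source = source.with_points(
                source.points + rng.normal(0, 0.3, (5, 2))).centered()
            theta = optimal_rotation(source, target, identity_corr(5))
            # paired SSE at every grid angle, vectorized over the grid
            x, y = source.points[:, 0], source.points[:, 1]
            rx = np.outer(cos, x) - np.outer(sin, y)
            ry = np.outer(sin, x) + np.outer(cos, y)
            sse = ((rx - target.points[:, 0]) ** 2
                   + (ry - target.points[:, 1]) ** 2).sum(axis=1)
            theta_grid = grid[np.argmin(sse)]
            assert abs(math.remainder(theta - theta_grid, 2 * np.pi)) < 1e-3

    def test_unequal_lengths_rejected(self, rng):
        p = random_pattern(rng, n=4)
        q = random_pattern(rng, n=5)
        with pytest.raises(InvalidInputError):
            optimal_rotation(p, q, identity_corr(4))

    def test_coincident_source_is_degenerate(self):
        p = PositionalPattern([(0, 0), (0, 0 + 1e-16)], ["a", "b"])
        q = PositionalPattern([(1, 0), (-1, 0)], ["a", "b"])
        with pytest.raises(DegenerateGeometryError):
            optimal_rotation(p, q, identity_corr(2))


class TestOptimalScale:
    def test_exact_shrink_factor(self, rng):
        q = random_pattern(rng).centered()
        p = q.with_points(q.points * 2.0)
        assert optimal_scale(p, q, identity_corr(5)) == pytest.approx(0.5)

    def test_identity_when_equal(self, rng):
        p = random_pattern(rng).centered()
        assert optimal_scale(p, p, identity_corr(5)) == pytest.approx(1.0)

    def test_matches_golden_section_search(self, rng):
        """Closed form equals a 1-D line search on the paired SSE."""
        for _ in range(100):
            q = random_pattern(rng).centered()
            s_true = np.exp(rng.uniform(-0.9, 0.9))
            p = q.with_points(q.points * s_true
                              + rng.normal(0, 0.2, (5, 2))).centered()
            s = optimal_scale(p, q, identity_corr(5))

            def sse(scale):
                return float(((scale * p.points - q.points) ** 2).sum())

            # bracket the minimum on a coarse grid, then golden-section
            grid = np.linspace(0.01, 10.0, 400)
            k = int(np.argmin([sse(g) for g in grid]))
            lo, mid, hi = grid[max(k - 1, 0)], grid[k], grid[min(k + 1, 399)]
            res = minimize_scalar(sse, bracket=(lo, mid, hi),
                                  method="golden", options={"xtol": 1e-12})
            s_oracle = float(np.clip(res.x, 1 / 3, 3.0))
            assert s == pytest.approx(s_oracle, abs=1e-4)

    def test_clipping_to_bounds(self, rng):
        q = random_pattern(rng).centered()
        p = q.with_points(q.points * 10.0)  # optimum 0.1, below s_min
        assert optimal_scale(p, q, identity_corr(5)) == pytest.approx(1 / 3)

    def test_zero_norm_source_degenerate(self):
        p = PositionalPattern([(0, 0), (0, 0 + 1e-18)], ["a", "b"])
        q = PositionalPattern([(1, 0), (-1, 0)], ["a", "b"])
        with pytest.raises(DegenerateGeometryError):
            optimal_scale(p, q, identity_corr(2))


# ---------------------------------------------------------------------------
# residual and accuracy transform
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "truth_pts, pattern_pts, expected",
    [
        ([(0, 0), (4, 0)], [(0, 0), (4, 0)], 0.0),
        ([(0, 0), (4, 0)], [(1, 0), (4, 0)], 1.0),
        ([(0, 0), (10, 10)], [(1, 0), (0, 1)], 2.0),  # both map to (0,0)
    ],
)
def test_nn_sse_examples(truth_pts, pattern_pts, expected):
    labels = ["a", "b"]
    truth = PositionalPattern(truth_pts, labels)
    pattern = PositionalPattern(pattern_pts, labels)
    assert nn_sse(pattern, truth) == pytest.approx(expected)


@pytest.mark.parametrize("sse, expected", [(0, 1.0), (1, 0.5), (3, 0.25)])
def test_accuracy_from_sse_closed_form(sse, expected):
    assert accuracy_from_sse(sse) == pytest.approx(expected)


def test_accuracy_from_sse_rejects_negative():
    with pytest.raises(InvalidInputError):
        accuracy_from_sse(-0.5)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


class TestAlign:
    def test_perfect_recall_gives_identity(self, rng):
        p = random_pattern(rng)
        transform, corr = align(p, p)
        assert transform.theta == pytest.approx(0.0)
        assert transform.scale == pytest.approx(1.0)
        assert np.allclose(transform.translation, 0.0)
        assert corr.assignment == tuple(range(5))

    def test_recovers_an_applied_similarity_transform(self, rng):
        truth = random_pattern(rng)
        applied = SimilarityTransform(np.deg2rad(37), 1.7, np.array([4.0, -2.0]))
        moved = applied.apply(truth.points)
        perm = rng.permutation(5)
        response = PositionalPattern(moved[perm],
                                     [truth.labels[i] for i in perm])
        transform, _ = align(response, truth)
        assert transform.theta == pytest.approx(-np.deg2rad(37), abs=1e-6)
        assert transform.scale == pytest.approx(1 / 1.7, abs=1e-6)
        aligned = transform.apply_pattern(response)
        assert nn_sse(aligned, truth) < 1e-10

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_matches_exhaustive_correspondence_search(self, rng, n):
        """The alternating multi-start optimum equals the global optimum
        over all n! correspondences (each solved in closed form)."""
        for _ in range(40):
            truth = random_pattern(rng, n=n)
            applied = SimilarityTransform(
                rng.uniform(-np.pi, np.pi),
                float(np.exp(rng.uniform(np.log(1 / 3), np.log(3)) / 2)),
                rng.uniform(-3, 3, 2),
            )
            pts = applied.apply(truth.points) + rng.normal(0, 0.5, (n, 2))
            perm = rng.permutation(n)
            response = PositionalPattern(pts[perm],
                                         [truth.labels[i] for i in perm])
            transform, corr = align(response, truth)
            sse = paired_sse(response, truth, corr, transform)
            _, _, sse_oracle = exhaustive_align(response, truth)
            assert sse <= sse_oracle + 1e-9

    def test_mismatched_label_sets_rejected(self, rng):
        p = random_pattern(rng, labels=list("abcde"))
        q = random_pattern(rng, labels=list("abcdX"))
        with pytest.raises(InvalidInputError):
            align(p, q)

    def test_label_mode_keeps_label_correspondence(self, rng):
        truth = random_pattern(rng)
        pts = truth.points + rng.normal(0, 0.3, (5, 2))
        perm = rng.permutation(5)
        response = PositionalPattern(pts[perm], [truth.labels[i] for i in perm])
        _, corr = align(response, truth, AlignConfig(correspondence="label"))
        for i, j in enumerate(corr.assignment):
            assert response.labels[i] == truth.labels[j]


# ---------------------------------------------------------------------------
# trial-level measures
# ---------------------------------------------------------------------------


class TestTrialMeasures:
    def test_pattern_accuracy_perfect(self, rng):
        p = random_pattern(rng)
        assert pattern_accuracy(p, p) == pytest.approx(1.0)

    def test_similarity_invariance(self, rng):
        """Any in-bounds similarity transform plus relabeling scores 1."""
        for _ in range(25):
            truth = random_pattern(rng)
            t = SimilarityTransform(
                rng.uniform(-np.pi, np.pi),
                float(np.exp(rng.uniform(np.log(1 / 3), np.log(3)))),
                rng.uniform(-20, 20, 2),
            )
            perm = rng.permutation(5)
            response = PositionalPattern(t.apply(truth.points)[perm],
                                         [truth.labels[i] for i in perm])
            assert pattern_accuracy(response, truth) >= 1 - 1e-6

    def test_raw_accuracy_distant_translation(self, rng):
        truth = random_pattern(rng)
        response = truth.with_points(truth.points + np.array([100.0, 0.0]))
        acc = raw_accuracy(response, truth)
        # each point is >= (100 - diameter) away from any true point
        assert acc < 1 / (1 + 5 * 90.0**2)
        assert acc > 0

    def test_dominance_pattern_at_least_raw(self, rng):
        """The identity transform is always a candidate, so aligning can
        never hurt."""
        for _ in range(25):
            truth = random_pattern(rng)
            response = truth.with_points(
                truth.points + rng.normal(0, rng.uniform(0, 2), (5, 2)))
            s = score_trial(response, truth)
            assert s.pattern_accuracy >= s.raw_accuracy - 1e-12
            assert -1.0 <= s.environmental_geometry <= 0.0

    def test_environmental_geometry_zero_when_perfect(self, rng):
        p = random_pattern(rng)
        s = score_trial(p, p)
        assert environmental_geometry(s) == pytest.approx(0.0)

    def test_environmental_geometry_negative_for_rotated_response(self, rng):
        truth = random_pattern(rng)
        c = truth.points.mean(axis=0)
        rotated = truth.with_points(
            (truth.points - c) @ np.array([[0.0, -1.0], [1.0, 0.0]]).T + c)
        s = score_trial(rotated, truth)
        assert s.pattern_accuracy == pytest.approx(1.0, abs=1e-9)
        assert environmental_geometry(s) == pytest.approx(
            s.raw_accuracy - 1.0, abs=1e-9)
        assert environmental_geometry(s) < 0

    def test_object_identity_counts_correct_labels(self, rng):
        truth = random_pattern(rng)
        s = score_trial(truth, truth)
        assert object_identity(s, truth, truth) == 5

        swapped_labels = list(truth.labels)
        swapped_labels[0], swapped_labels[1] = swapped_labels[1], swapped_labels[0]
        response = PositionalPattern(truth.points, swapped_labels)
        s = score_trial(response, truth)
        assert object_identity(s, response, truth) == 3

    def test_failed_trial_masks_decomposition(self, rng):
        truth = random_pattern(rng)
        s = score_trial(truth, truth).mark_failed(True)
        assert s.failed
        assert environmental_geometry(s) is None
        assert object_identity(s, truth, truth) is None
        assert s.environmental_geometry is None
        assert s.object_identity is None
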