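"""Labeled 2D point sets ("positional patterns") and basic geometry.

A positional pattern is the configuration of uniquely labeled objects in a
room, viewed from above: an ordered sequence of 2D points in continuous
Cartesian virtual meters (y increasing upward) paired with object-identity
labels.  Both the true layout of an environment and a participant's recalled
layout are represented this way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .errors import InvalidInputError


class Point2D(NamedTuple):
    x: float
    y: float


@dataclass(frozen=True)
class PositionalPattern:
    """An ordered set of labeled 2D object positions.

    Parameters
    ----------
    points
        ``(n, 2)`` array of coordinates in virtual meters.
    labels
        ``n`` unique object-identity tokens, aligned with ``points``.
    """

    points: np.ndarray
    labels: tuple[str, ...]

    def __init__(self, points: Iterable, labels: Sequence[str]):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidInputError(f"points must be (n, 2), got shape {pts.shape}")
        if pts.shape[0] == 0:
            raise InvalidInputError("pattern must contain at least one point")
        if not np.all(np.isfinite(pts)):
            raise InvalidInputError("all coordinates must be finite")
        labs = tuple(str(l) for l in labels)
        if len(labs) != pts.shape[0]:
            raise InvalidInputError(
                f"{len(labs)} labels for {pts.shape[0]} points"
            )
        if len(set(labs)) != len(labs):
            raise InvalidInputError(f"labels must be unique within a pattern: {labs}")
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "labels", labs)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def centroid(self) -> Point2D:
        """Arithmetic mean of the points (the pattern's geometric center)."""
        c = self.points.mean(axis=0)
        return Point2D(float(c[0]), float(c[1]))

    def centered(self) -> "PositionalPattern":
        """The same pattern translated so its centroid sits at the origin."""
        c = self.points.mean(axis=0)
        return PositionalPattern(self.points - c, self.labels)

    def with_points(self, points: np.ndarray) -> "PositionalPattern":
        return PositionalPattern(points, self.labels)

    def label_index(self) -> dict[str, int]:
        return {lab: i for i, lab in enumerate(self.labels)}

    def same_label_set(self, other: "PositionalPattern") -> bool:
        return set(self.labels) == set(other.labels)


def centroid(pattern: PositionalPattern) -> Point2D:
    """Geometric center (centroid) of a positional pattern."""
    return pattern.centroid()


def rotation_matrix(theta: float) -> np.ndarray:
    """Proper 2D rotation matrix for angle ``theta`` (radians, CCW)."""
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def wrap_angle(theta: float) -> float:
    """Wrap an angle into (-pi, pi]."""
    t = float((theta + np.pi) % (2.0 * np.pi) - np.pi)
    if t == -np.pi:
        t = np.pi
    return t
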