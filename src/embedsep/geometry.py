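"""Deterministic viewing-direction sampling and orthographic flattening.

Viewing directions are sampled with a Fibonacci-spiral construction on the
unit sphere, which is deterministic and close to uniform for any count. Each
direction carries a full rotation matrix so that the in-plane orientation of
the 2D projection is reproducible: the second in-plane axis is the
normalized projection of the world z-axis onto the viewing plane (falling
back to the world x-axis when the direction is within ~2.5 degrees of +-z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

#: |direction . z| above which the up-vector rule falls back to the x-axis.
_UP_FALLBACK = 0.999


@dataclass(frozen=True)
class ViewingDirection:
    """A unit viewing axis plus the rotation into view coordinates.

    ``rotation`` maps world coordinates to view coordinates; its third row
    equals ``direction`` (the axis collapsed by the orthographic
    projection), and the first two rows span the projection plane.
    """

    direction: np.ndarray
    rotation: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        r = np.asarray(self.rotation, dtype=float)
        if d.shape != (3,) or abs(np.linalg.norm(d) - 1.0) > 1e-12:
            raise ValidationError("direction must be a unit 3-vector")
        if r.shape != (3, 3):
            raise ValidationError("rotation must be 3x3")
        if np.max(np.abs(r @ r.T - np.eye(3))) > 1e-10:
            raise ValidationError("rotation is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValidationError("rotation must be proper (det +1)")
        object.__setattr__(self, "direction", d)
        object.__setattr__(self, "rotation", r)


@dataclass(frozen=True)
class AngleSet:
    """An ordered, deterministic set of viewing directions."""

    n: int
    directions: tuple[ViewingDirection, ...]

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.directions)

    def __getitem__(self, i: int) -> ViewingDirection:
        return self.directions[i]


def rotation_for_direction(direction: np.ndarray) -> np.ndarray:
    """Build the world-to-view rotation for a unit viewing axis.

    Rows are ``(e1, e2, direction)`` with ``e2`` the normalized projection
    of the world z-axis onto the viewing plane and ``e1 = e2 x direction``,
    giving a right-handed frame with determinant +1.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    up = np.array([0.0, 0.0, 1.0])
    if abs(d @ up) > _UP_FALLBACK:
        # near +-z: anchor on the world x-axis so the +z view is the identity
        e1 = np.array([1.0, 0.0, 0.0]) - d[0] * d
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
    else:
        e2 = up - d[2] * d
        e2 /= np.linalg.norm(e2)
        e1 = np.cross(e2, d)
    return np.array([e1, e2, d])


def sample_viewing_angles(n: int) -> AngleSet:
    """Sample ``n`` near-uniform unit directions via the Fibonacci spiral.

    The construction is closed-form in ``i`` and ``n``, hence bit-identical
    across runs. ``z_i = 1 - (2i + 1)/n`` and the azimuth advances by the
    golden angle ``pi (3 - sqrt 5)`` per step.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    golden = np.pi * (3.0 - np.sqrt(5.0))
    dirs = []
    for i in range(n):
        z = 1.0 - (2.0 * i + 1.0) / n
        r = np.sqrt(max(0.0, 1.0 - z * z))
        theta = golden * i
        d = np.array([r * np.cos(theta), r * np.sin(theta), z])
        d /= np.linalg.norm(d)
        dirs.append(ViewingDirection(d, rotation_for_direction(d)))
    return AngleSet(n, tuple(dirs))


def flatten(points: np.ndarray, view: ViewingDirection) -> np.ndarray:
    """Orthographically project ``(C, 3)`` points onto ``view``'s plane.

    Returns the first two view coordinates of ``rotation @ point``; the
    collapsed axis is ``view.direction``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError(f"points must be (C, 3), got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("points contain non-finite values")
    return pts @ view.rotation[:2].T
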