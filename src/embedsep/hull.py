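"""Convex-hull area-overlap percentage for a pair of populations.

Hulls are computed with the Quickhull algorithm, the intersection of two
convex hulls with convex polygon clipping, and the overlap is reported as a
percentage of the smaller hull's area. For 3D embeddings both populations
are orthographically flattened under every sampled viewing direction and
the direction with the least overlap is kept (exhaustive search).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .geometry import AngleSet, ViewingDirection, flatten


def _shoelace_signed(vertices: np.ndarray) -> float:
    if len(vertices) < 3:
        return 0.0
    x = vertices[:, 0]
    y = vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _fan_area(vertices: np.ndarray) -> float:
    # triangulation-based recomputation used as a consistency guard
    if len(vertices) < 3:
        return 0.0
    v0 = vertices[0]
    total = 0.0
    for i in range(1, len(vertices) - 1):
        a = vertices[i] - v0
        b = vertices[i + 1] - v0
        total += 0.5 * (a[0] * b[1] - a[1] * b[0])
    return total


@dataclass(frozen=True)
class ConvexPolygon:
    """A convex polygon with vertices in counter-clockwise order.

    Degenerate hulls (fewer than 3 vertices, or collinear input) are
    represented with their extreme points and have area 0.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) == 0:
            raise ValidationError("vertices must be a non-empty (V, 2) array")
        object.__setattr__(self, "vertices", v)

    @property
    def area(self) -> float:
        return max(_shoelace_signed(self.vertices), 0.0)

    @property
    def is_degenerate(self) -> bool:
        return len(self.vertices) < 3 or self.area == 0.0


@dataclass
class HullOverlapResult:
    """Hull overlap as a percentage of the smaller hull."""

    overlap_percent: float
    intersection_area: float
    area_a: float
    area_b: float
    view: ViewingDirection | None = None
    degenerate: bool = False


def _cross(o: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    return float((a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0]))


def _chain(a: np.ndarray, b: np.ndarray, pts: np.ndarray) -> list[np.ndarray]:
    """Quickhull recursion: hull vertices strictly right of a->b, ordered a->b."""
    if len(pts) == 0:
        return []
    cr = (pts[:, 0] - a[0]) * (b[1] - a[1]) - (pts[:, 1] - a[1]) * (b[0] - a[0])
    # right of a->b corresponds to positive cr with this sign arrangement
    outside = pts[cr > 0]
    if len(outside) == 0:
        return []
    cr_out = cr[cr > 0]
    far = outside[int(np.argmax(cr_out))]
    left = _chain(a, far, outside)
    right = _chain(far, b, outside)
    return left + [far] + right


def convex_hull_2d(points) -> ConvexPolygon:
    """Convex hull of 2D points via Quickhull, counter-clockwise.

    Inputs with fewer than 3 distinct points, or all-collinear points,
    yield a degenerate polygon of area 0.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValidationError("points must be a non-empty (C, 2) array")
    if not np.all(np.isfinite(pts)):
        raise ValidationError("points contain non-finite values")
    pts = np.unique(pts, axis=0)  # lexicographic sort; also dedupes
    if len(pts) == 1:
        return ConvexPolygon(pts)
    a = pts[0]   # lexicographically smallest = leftmost (lowest y on ties)
    b = pts[-1]  # rightmost
    below = _chain(a, b, pts)
    above = _chain(b, a, pts)
    hull = [a] + below + [b] + above
    return ConvexPolygon(np.array(hull))


def _clip_by_edge(poly: list[np.ndarray], e0: np.ndarray, e1: np.ndarray) -> list[np.ndarray]:
    """Sutherland-Hodgman step: keep the side left of (or on) e0->e1."""
    out: list[np.ndarray] = []
    n = len(poly)
    for i in range(n):
        cur = poly[i]
        prev = poly[i - 1]
        cur_in = _cross(e0, e1, cur) >= 0
        prev_in = _cross(e0, e1, prev) >= 0
        if cur_in:
            if not prev_in:
                out.append(_segment_line_intersection(prev, cur, e0, e1))
            out.append(cur)
        elif prev_in:
            out.append(_segment_line_intersection(prev, cur, e0, e1))
    return out


def _segment_line_intersection(p0, p1, e0, e1) -> np.ndarray:
    d = p1 - p0
    e = e1 - e0
    denom = d[0] * e[1] - d[1] * e[0]
    if denom == 0:  # parallel within float precision; fall back to endpoint
        return p1
    t = ((e0[0] - p0[0]) * e[1] - (e0[1] - p0[1]) * e[0]) / denom
    return p0 + t * d


def polygon_intersection_area(p: ConvexPolygon, q: ConvexPolygon) -> float:
    """Area of the intersection of two convex polygons.

    Uses convex clipping (Sutherland-Hodgman with a convex clip polygon);
    the resulting area is cross-checked against a triangulation-based
    recomputation. Returns 0 for disjoint or degenerate inputs; hulls that
    only touch at an edge or vertex have intersection area 0.
    """
    if p.is_degenerate or q.is_degenerate:
        return 0.0
    poly = [v for v in p.vertices]
    qv = q.vertices
    for i in range(len(qv)):
        poly = _clip_by_edge(poly, qv[i], qv[(i + 1) % len(qv)])
        if len(poly) == 0:
            return 0.0
    arr = np.array(poly)
    area = max(_shoelace_signed(arr), 0.0)
    fan = max(_fan_area(arr), 0.0)
    scale = max(area, fan, 1e-30)
    if abs(area - fan) > 1e-9 * scale + 1e-12:
        raise AssertionError(
            f"intersection area inconsistency: shoelace {area} vs fan {fan}"
        )
    return area


def hull_overlap_percent_2d(points_a, points_b) -> HullOverlapResult:
    """Overlap of two point sets' hulls as % of the smaller hull's area.

    If the smaller hull is degenerate (area 0) the overlap is defined as 0
    and the result carries ``degenerate=True``.
    """
    pa = np.asarray(points_a, dtype=float)
    pb = np.asarray(points_b, dtype=float)
    if len(pa) == 0 or len(pb) == 0:
        raise ValidationError("each population needs at least one point")
    hull_a = convex_hull_2d(pa)
    hull_b = convex_hull_2d(pb)
    area_a = hull_a.area
    area_b = hull_b.area
    smaller = min(area_a, area_b)
    if smaller == 0.0:
        return HullOverlapResult(0.0, 0.0, area_a, area_b, degenerate=True)
    inter = polygon_intersection_area(hull_a, hull_b)
    inter = min(inter, smaller)  # guard float overshoot
    return HullOverlapResult(100.0 * inter / smaller, inter, area_a, area_b)


def min_hull_overlap_over_angles(
    points3d_a, points3d_b, angles: AngleSet
) -> HullOverlapResult:
    """Exhaustive search for the viewing angle with least hull overlap.

    Both populations are flattened under every direction in ``angles`` and
    scored with :func:`hull_overlap_percent_2d`; the minimum is returned
    with its direction (ties keep the lowest direction index).
    """
    pa = np.asarray(points3d_a, dtype=float)
    pb = np.asarray(points3d_b, dtype=float)
    if len(pa) == 0 or len(pb) == 0:
        raise ValidationError("each population needs at least one point")
    if len(angles) == 0:
        raise ValidationError("angle set is empty")
    best: HullOverlapResult | None = None
    for view in angles:
        res = hull_overlap_percent_2d(flatten(pa, view), flatten(pb, view))
        if best is None or res.overlap_percent < best.overlap_percent:
            res.view = view
            best = res
    assert best is not None
    return best
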