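"""Shifted-grid Shannon-index mixing score for a pair of populations.

A rectangular grid is laid over a 2D projection; within each sector the
Shannon index ``SI = -sum_i p_i ln p_i`` of the two population proportions
is computed and the per-sector values are summed. Because the score depends
on where grid lines fall, the grid origin is shifted over a lattice of
offsets and the minimum total SI is kept. For 3D embeddings the projection
is additionally minimized over a set of viewing directions.

All logarithms are natural (scores are in nats); for a pair of populations
each sector's SI lies in ``[0, ln 2]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .geometry import AngleSet, ViewingDirection, flatten
from .io_formats import CellTypeTable, EmbeddingTable

#: Half-width used to inflate a zero-extent bounding-box axis.
DEGENERATE_HALF_WIDTH = 0.5


@dataclass(frozen=True)
class GridSpec:
    """Placement of a sector grid over a 2D bounding box.

    ``shift_fractions`` move the grid origin to ``min - f * sector_size``
    per axis, ``f`` in ``[0, 1)``; a shifted grid covers the box with one
    extra row/column of sectors.
    """

    sectors_per_axis: tuple[int, int]
    bounding_box: tuple[tuple[float, float], tuple[float, float]]
    shift_fractions: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        sx, sy = self.sectors_per_axis
        if sx < 1 or sy < 1:
            raise ValidationError("sectors_per_axis must be positive")
        for f in self.shift_fractions:
            if not (0.0 <= f < 1.0):
                raise ValidationError("shift fractions must lie in [0, 1)")

    def sector_sizes(self) -> tuple[float, float]:
        (x0, x1), (y0, y1) = self.bounding_box
        sx, sy = self.sectors_per_axis
        wx = (x1 - x0) / sx if x1 > x0 else 2.0 * DEGENERATE_HALF_WIDTH / sx
        wy = (y1 - y0) / sy if y1 > y0 else 2.0 * DEGENERATE_HALF_WIDTH / sy
        return wx, wy


@dataclass(frozen=True)
class EntropyConfig:
    """Parameters of the entropy overlap score."""

    sectors_per_axis: tuple[int, int] = (10, 10)
    n_shift_steps: int = 5

    def __post_init__(self) -> None:
        if self.n_shift_steps < 1:
            raise ValidationError("n_shift_steps must be >= 1")
        sx, sy = self.sectors_per_axis
        if sx < 1 or sy < 1:
            raise ValidationError("sectors_per_axis must be positive")


@dataclass
class EntropyResult:
    """Minimal total Shannon index with the grid (and angle) achieving it."""

    total_SI: float
    grid: GridSpec
    view: ViewingDirection | None = None
    n_cells_per_population: dict[str, int] = field(default_factory=dict)


def shannon_index(proportions) -> float:
    """Shannon index ``-sum p ln p`` in nats; terms with ``p = 0`` are 0.

    Proportions must be non-negative and sum to 1 within 1e-9.
    """
    p = np.asarray(proportions, dtype=float)
    if np.any(p < 0):
        raise ValidationError("proportions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError(f"proportions sum to {p.sum()!r}, expected 1")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def _sector_axis_index(values: np.ndarray, lo: float, width: float, n_sectors: int,
                       shift: float) -> np.ndarray:
    """Half-open sector index per value; the top edge clamps into the last
    covered sector (index ``n_sectors - 1`` unshifted, ``n_sectors`` shifted)."""
    idx = np.floor((values - lo) / width + shift).astype(np.int64)
    cap = n_sectors if shift > 0 else n_sectors - 1
    return np.clip(idx, 0, cap)


def _bounding_box(points: np.ndarray) -> tuple[tuple[float, float], tuple[float, float]]:
    return (
        (float(points[:, 0].min()), float(points[:, 0].max())),
        (float(points[:, 1].min()), float(points[:, 1].max())),
    )


def _grid_entropy_masked(points: np.ndarray, mask_a: np.ndarray, grid: GridSpec) -> float:
    sx, sy = grid.sectors_per_axis
    (x0, _), (y0, _) = grid.bounding_box
    wx, wy = grid.sector_sizes()
    fx, fy = grid.shift_fractions
    ix = _sector_axis_index(points[:, 0], x0, wx, sx, fx)
    iy = _sector_axis_index(points[:, 1], y0, wy, sy, fy)
    key = ix * (sy + 1) + iy
    length = (sx + 1) * (sy + 1)
    counts_a = np.bincount(key[mask_a], minlength=length).astype(float)
    counts_b = np.bincount(key[~mask_a], minlength=length).astype(float)
    total = counts_a + counts_b
    mixed = (counts_a > 0) & (counts_b > 0)
    if not np.any(mixed):
        return 0.0
    pa = counts_a[mixed] / total[mixed]
    pb = counts_b[mixed] / total[mixed]
    return float(-np.sum(pa * np.log(pa) + pb * np.log(pb)))


def grid_total_entropy(points2d, labels, grid: GridSpec) -> float:
    """Total Shannon index of a labelled point set under a fixed grid.

    Each point falls into a sector (half-open intervals, top/right edge
    points clamped into the last sector); per-sector SI is computed from
    the two population proportions and summed. Empty and single-population
    sectors contribute 0.
    """
    points = np.asarray(points2d, dtype=float)
    labels = np.asarray(labels)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValidationError(f"points must be (C, 2), got {points.shape}")
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValidationError(
            f"expected exactly 2 populations, found {len(uniq)}: {uniq.tolist()}"
        )
    mask_a = labels == uniq[0]
    if not np.any(mask_a) or np.all(mask_a):
        raise ValidationError("each population must have at least one point")
    return _grid_entropy_masked(points, mask_a, grid)


def min_entropy_over_shifts(
    points2d,
    labels,
    sectors_per_axis: tuple[int, int] = (10, 10),
    n_shift_steps: int = 5,
) -> EntropyResult:
    """Minimize :func:`grid_total_entropy` over a lattice of grid shifts.

    Shift fractions are ``k / n_shift_steps`` for ``k = 0..n-1`` on each
    axis, evaluated in row-major order starting at ``(0, 0)``; ties keep
    the first-evaluated shift. The bounding box spans the given points.
    """
    points = np.asarray(points2d, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValidationError(
            f"expected exactly 2 populations, found {len(uniq)}: {uniq.tolist()}"
        )
    mask_a = labels == uniq[0]
    if not np.any(mask_a) or np.all(mask_a):
        raise ValidationError("each population must have at least one point")
    if n_shift_steps < 1:
        raise ValidationError("n_shift_steps must be >= 1")
    box = _bounding_box(points)
    best: EntropyResult | None = None
    for kx in range(n_shift_steps):
        for ky in range(n_shift_steps):
            grid = GridSpec(
                sectors_per_axis, box, (kx / n_shift_steps, ky / n_shift_steps)
            )
            si = _grid_entropy_masked(points, mask_a, grid)
            if best is None or si < best.total_SI:
                best = EntropyResult(si, grid)
    assert best is not None
    return best


def _pair_subset(
    embedding: EmbeddingTable,
    annotations: CellTypeTable,
    pop_a: str,
    pop_b: str,
) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    cells_a = annotations.members(pop_a)
    cells_b = annotations.members(pop_b)
    if not cells_a or not cells_b:
        empty = pop_a if not cells_a else pop_b
        raise ValidationError(f"population {empty!r} has no cells")
    coords_a = embedding.subset(cells_a).coords
    coords_b = embedding.subset(cells_b).coords
    points = np.vstack([coords_a, coords_b])
    mask_a = np.zeros(len(points), dtype=bool)
    mask_a[: len(coords_a)] = True
    sizes = {pop_a: len(cells_a), pop_b: len(cells_b)}
    return points, mask_a, sizes


def entropy_overlap_pair_2d(
    embedding: EmbeddingTable,
    annotations: CellTypeTable,
    pop_a: str,
    pop_b: str,
    config: EntropyConfig = EntropyConfig(),
) -> EntropyResult:
    """Shift-minimized entropy score of one population pair in a 2D embedding."""
    if embedding.ndim != 2:
        raise ValidationError(f"expected a 2D embedding, got D={embedding.ndim}")
    points, mask_a, sizes = _pair_subset(embedding, annotations, pop_a, pop_b)
    labels = np.where(mask_a, "a", "b")
    result = min_entropy_over_shifts(
        points, labels, config.sectors_per_axis, config.n_shift_steps
    )
    result.n_cells_per_population = sizes
    return result


def entropy_overlap_pair_3d(
    embedding: EmbeddingTable,
    annotations: CellTypeTable,
    pop_a: str,
    pop_b: str,
    angles: AngleSet,
    config: EntropyConfig = EntropyConfig(),
) -> EntropyResult:
    """Best-viewing-angle entropy score of a pair in a 3D embedding.

    Every sampled direction is flattened and scored with
    :func:`min_entropy_over_shifts`; the global minimum is returned with
    the achieving direction (ties keep the lowest direction index).
    """
    if embedding.ndim != 3:
        raise ValidationError(f"expected a 3D embedding, got D={embedding.ndim}")
    points3d, mask_a, sizes = _pair_subset(embedding, annotations, pop_a, pop_b)
    labels = np.where(mask_a, "a", "b")
    best: EntropyResult | None = None
    for view in angles:
        points2d = flatten(points3d, view)
        res = min_entropy_over_shifts(
            points2d, labels, config.sectors_per_axis, config.n_shift_steps
        )
        if best is None or res.total_SI < best.total_SI:
            res.view = view
            best = res
    assert best is not None
    best.n_cells_per_population = sizes
    return best
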