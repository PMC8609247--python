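"""All-pairs 2D-vs-3D overlap comparison and difference-matrix assembly.

For every unordered pair of populations the selected metric (entropy or
hull overlap) is computed on the 2D embedding and at the best viewing angle
of the 3D embedding; the matrix stores ``score_3D_best - score_2D``, so a
negative entry means the pair is better separated in 3D.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .entropy import EntropyConfig, entropy_overlap_pair_2d, entropy_overlap_pair_3d
from .geometry import sample_viewing_angles
from .hull import hull_overlap_percent_2d, min_hull_overlap_over_angles
from .io_formats import CellTypeTable, EmbeddingTable

METHODS = ("entropy", "hull")


@dataclass(frozen=True)
class ComparisonConfig:
    """Parameters shared by all pairwise comparisons."""

    sectors_per_axis: tuple[int, int] = (10, 10)
    n_shift_steps: int = 5
    n_angles: int = 2048
    min_population: int = 10

    def __post_init__(self) -> None:
        if self.n_angles < 1 or self.min_population < 1:
            raise ValidationError("counts must be positive")
        if self.n_shift_steps < 1:
            raise ValidationError("n_shift_steps must be >= 1")

    def entropy_config(self) -> EntropyConfig:
        return EntropyConfig(self.sectors_per_axis, self.n_shift_steps)


@dataclass
class PairwiseOverlapMatrix:
    """Symmetric matrix of ``3D_best - 2D`` scores; diagonal is NaN-masked.

    Negative entries mean the best 3D viewing angle mixes the pair less
    than the 2D embedding does.
    """

    population_names: list[str]
    values: np.ndarray
    method: str
    metadata: dict = field(default_factory=dict)

    def entry(self, a: str, b: str) -> float:
        i = self.population_names.index(a)
        j = self.population_names.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.population_names, columns=self.population_names
        )

    def pair_table(self) -> pd.DataFrame:
        """Long-format table with one row per defined unordered pair."""
        rows = []
        names = self.population_names
        scores_2d = self.metadata.get("scores_2d", {})
        scores_3d = self.metadata.get("scores_3d", {})
        for i, j in itertools.combinations(range(len(names)), 2):
            key = (names[i], names[j])
            rows.append(
                {
                    "pop_a": names[i],
                    "pop_b": names[j],
                    "method": self.method,
                    "score_2d": scores_2d.get(key, np.nan),
                    "score_3d_best": scores_3d.get(key, np.nan),
                    "difference": self.values[i, j],
                }
            )
        return pd.DataFrame(rows)


def pairwise_matrix(
    embedding2d: EmbeddingTable,
    embedding3d: EmbeddingTable,
    annotations: CellTypeTable,
    method: str = "entropy",
    config: ComparisonConfig = ComparisonConfig(),
) -> PairwiseOverlapMatrix:
    """Compute the full 3D-best minus 2D difference matrix.

    Populations smaller than ``config.min_population`` are dropped and
    listed in ``metadata["dropped"]``; pairs of populations sharing cells
    (multi-label annotations) are flagged in ``metadata["shared_cells"]``.
    """
    if method not in METHODS:
        raise ValidationError(f"method must be one of {METHODS}, got {method!r}")
    if embedding2d.ndim != 2:
        raise ValidationError("embedding2d must have D = 2")
    if embedding3d.ndim != 3:
        raise ValidationError("embedding3d must have D = 3")
    if set(embedding2d.cell_ids) != set(embedding3d.cell_ids):
        raise ValidationError("2D and 3D embeddings cover different cell sets")

    members = {t: annotations.members(t) for t in annotations.type_names}
    eligible = [t for t in annotations.type_names if len(members[t]) >= config.min_population]
    dropped = [t for t in annotations.type_names if t not in eligible]
    if len(eligible) < 2:
        raise ValidationError(
            f"need >= 2 populations with >= {config.min_population} cells; "
            f"eligible: {eligible}"
        )

    angles = sample_viewing_angles(config.n_angles)
    econf = config.entropy_config()
    n = len(eligible)
    values = np.full((n, n), np.nan)
    scores_2d: dict[tuple[str, str], float] = {}
    scores_3d: dict[tuple[str, str], float] = {}
    shared: list[tuple[str, str]] = []

    for i, j in itertools.combinations(range(n), 2):
        a, b = eligible[i], eligible[j]
        if set(members[a]) & set(members[b]):
            shared.append((a, b))
        if method == "entropy":
            s2 = entropy_overlap_pair_2d(embedding2d, annotations, a, b, econf).total_SI
            s3 = entropy_overlap_pair_3d(
                embedding3d, annotations, a, b, angles, econf
            ).total_SI
        else:
            pa2 = embedding2d.subset(members[a]).coords
            pb2 = embedding2d.subset(members[b]).coords
            s2 = hull_overlap_percent_2d(pa2, pb2).overlap_percent
            pa3 = embedding3d.subset(members[a]).coords
            pb3 = embedding3d.subset(members[b]).coords
            s3 = min_hull_overlap_over_angles(pa3, pb3, angles).overlap_percent
        scores_2d[(a, b)] = s2
        scores_3d[(a, b)] = s3
        values[i, j] = values[j, i] = s3 - s2

    metadata = {
        "embedding_2d": embedding2d.name,
        "embedding_3d": embedding3d.name,
        "difference": "3d_best_minus_2d",
        "config": {
            "sectors_per_axis": list(config.sectors_per_axis),
            "n_shift_steps": config.n_shift_steps,
            "n_angles": config.n_angles,
            "min_population": config.min_population,
        },
        "dropped": dropped,
        "shared_cells": shared,
        "scores_2d": scores_2d,
        "scores_3d": scores_3d,
    }
    return PairwiseOverlapMatrix(eligible, values, method, metadata)


def summarize_matrix(matrix: PairwiseOverlapMatrix) -> dict:
    """Counts/fractions of pairs where 3D separates better, plus moments."""
    n = len(matrix.population_names)
    iu = np.triu_indices(n, k=1)
    entries = matrix.values[iu]
    entries = entries[~np.isnan(entries)]
    if len(entries) == 0:
        raise ValidationError("matrix has no defined entries")
    negative = int(np.sum(entries < 0))
    zero = int(np.sum(entries == 0))
    positive = int(np.sum(entries > 0))
    total = len(entries)
    return {
        "n_pairs": total,
        "n_negative": negative,
        "n_zero": zero,
        "n_positive": positive,
        "fraction_3d_better": negative / total,
        "fraction_zero": zero / total,
        "fraction_2d_better": positive / total,
        "mean_difference": float(np.mean(entries)),
        "median_difference": float(np.median(entries)),
    }


def render_matrix(
    matrix: PairwiseOverlapMatrix,
    path,
    upper: PairwiseOverlapMatrix | None = None,
):
    """Render a diverging heatmap centred at 0 (negative = 3D better).

    When ``upper`` is given, its entries fill the upper triangle and
    ``matrix`` fills the lower one (both must share population lists).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import TwoSlopeNorm

    values = matrix.values.copy()
    if upper is not None:
        if upper.population_names != matrix.population_names:
            raise ValidationError("population lists of the two matrices differ")
        n = len(values)
        iu = np.triu_indices(n, k=1)
        values[iu] = upper.values[iu]

    finite = values[~np.isnan(values)]
    vmax = float(np.max(np.abs(finite))) if len(finite) else 1.0
    vmax = vmax or 1.0
    norm = TwoSlopeNorm(vmin=-vmax, vcenter=0.0, vmax=vmax)

    fig, ax = plt.subplots(figsize=(1.2 + 0.5 * len(values),) * 2)
    masked = np.ma.masked_invalid(values)
    im = ax.imshow(masked, cmap="RdGy", norm=norm)
    names = matrix.population_names
    ax.set_xticks(range(len(names)), names, rotation=90)
    ax.set_yticks(range(len(names)), names)
    fig.colorbar(im, ax=ax, label=f"{matrix.method}: 3D best - 2D")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
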