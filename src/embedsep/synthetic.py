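"""Deterministic synthetic data with known ground truth.

Embeddings are simulated directly as Gaussian blobs in 3D (rather than by
running a DR method on simulated expression), keeping fixtures fast and
fully seed-determined. Expression matrices are negative-binomial counts
with log1p normalization and a designated set of differentially expressed
genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io_formats import (
    CellTypeTable,
    EmbeddingTable,
    ExpressionMatrix,
    export_bundle,
)

GROUND_TRUTH_NAME = "ground_truth.json"

PRESETS = ("fig2", "minimal", "de")


@dataclass
class BlobConfig:
    """Isotropic Gaussian blobs in 3D."""

    centers: list[tuple[float, float, float]]
    n_per_population: list[int]
    sigma: list[float]
    seed: int = 0
    population_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        p = len(self.centers)
        if len(self.n_per_population) != p or len(self.sigma) != p:
            raise ValidationError("centers, n_per_population and sigma must align")
        if any(s <= 0 for s in self.sigma):
            raise ValidationError("sigma must be positive")
        if not np.all(np.isfinite(np.asarray(self.centers, dtype=float))):
            raise ValidationError("centers must be finite")
        if not self.population_names:
            self.population_names = [f"pop_{i + 1}" for i in range(p)]


@dataclass
class ExprSimConfig:
    """Negative-binomial expression simulation with planted DE genes."""

    n_genes: int = 200
    de_fraction: float = 0.1
    effect: float = 2.0
    baseline_mean: float = 5.0
    dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValidationError("de_fraction must lie in [0, 1]")
        if self.effect < 0:
            raise ValidationError("effect must be >= 0")
        if self.n_genes < 1 or self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValidationError("invalid expression simulation parameters")


def _cell_ids(n: int, start: int = 1) -> list[str]:
    return [f"cell_{i:04d}" for i in range(start, start + n)]


def make_blobs_3d(config: BlobConfig) -> tuple[EmbeddingTable, CellTypeTable]:
    """Sample Gaussian blobs and their one-hot population table."""
    rng = np.random.default_rng(config.seed)
    coords = []
    labels = []
    for p, (center, n, s) in enumerate(
        zip(config.centers, config.n_per_population, config.sigma)
    ):
        coords.append(np.asarray(center, dtype=float) + s * rng.standard_normal((n, 3)))
        labels += [p] * n
    coords = np.vstack(coords)
    ids = _cell_ids(len(coords))
    membership = np.zeros((len(coords), len(config.centers)), dtype=np.int8)
    membership[np.arange(len(coords)), labels] = 1
    return (
        EmbeddingTable("blobs3d", ids, coords),
        CellTypeTable(ids, list(config.population_names), membership),
    )


def make_axis_hidden_pair(
    separation: float = 0.5,
    sigma: float = 0.05,
    n_per_pop: int = 200,
    seed: int = 0,
) -> tuple[EmbeddingTable, EmbeddingTable, CellTypeTable]:
    """Two populations identical in (x, y) but separated along z.

    The returned 2D embedding is the (x, y) projection of the 3D one, so
    the pair overlaps in 2D while some 3D viewing angle separates it. With
    ``separation = 0`` the populations are identically distributed and no
    hidden structure exists.
    """
    if separation < 0:
        raise ValidationError("separation must be >= 0")
    config = BlobConfig(
        centers=[(0.0, 0.0, 0.0), (0.0, 0.0, separation)],
        n_per_population=[n_per_pop, n_per_pop],
        sigma=[sigma, sigma],
        seed=seed,
        population_names=["pop_a", "pop_b"],
    )
    emb3d, celltypes = make_blobs_3d(config)
    emb2d = EmbeddingTable("proj2d", list(emb3d.cell_ids), emb3d.coords[:, :2])
    return emb3d, emb2d, celltypes


def make_expression(
    celltypes: CellTypeTable, config: ExprSimConfig
) -> tuple[ExpressionMatrix, list[str]]:
    """Simulate log1p-normalized NB counts with planted DE genes.

    With two populations every DE gene is upregulated (multiplicatively,
    by ``exp(effect)``) in the second population; with more populations
    the DE genes are assigned round-robin to populations 2..P, each
    upregulated one-vs-rest.
    """
    rng = np.random.default_rng(config.seed)
    n_cells = len(celltypes.cell_ids)
    n_pops = len(celltypes.type_names)
    if n_pops < 2:
        raise ValidationError("need at least 2 populations for the DE construction")
    pop_of_cell = np.argmax(celltypes.membership, axis=1)
    gene_names = [f"gene_{i:04d}" for i in range(1, config.n_genes + 1)]
    n_de = int(round(config.de_fraction * config.n_genes))
    de_gene_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    de_gene_idx.sort()
    up_pop = {int(g): 1 + (k % (n_pops - 1)) for k, g in enumerate(de_gene_idx)}

    mu = np.full((config.n_genes, n_cells), config.baseline_mean)
    for g, pop in up_pop.items():
        mu[g, pop_of_cell == pop] *= np.exp(config.effect)
    theta = config.dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))
    values = np.log1p(counts.astype(float))
    expr = ExpressionMatrix(gene_names, list(celltypes.cell_ids), values)
    return expr, [gene_names[g] for g in de_gene_idx]


def fixture_bundle(out_dir: str | Path, preset: str, seed: int = 0) -> Path:
    """Write a complete bundle for a named preset plus a ground-truth file.

    Presets:

    * ``"minimal"`` — expression matrix plus one 3D embedding only.
    * ``"fig2"`` — the axis-hidden pair (z-separation 10 sigma, n = 200
      per population) with both the 3D embedding and its 2D projection.
    * ``"de"`` — two well-separated blobs with 500 genes of which 50 are
      differentially expressed (effect 2, 100 cells per group).
    """
    out_dir = Path(out_dir)
    if preset == "minimal":
        blob = BlobConfig(
            centers=[(0.0, 0.0, 0.0), (5.0, 0.0, 0.0)],
            n_per_population=[15, 15],
            sigma=[1.0, 1.0],
            seed=seed,
        )
        emb3d, celltypes = make_blobs_3d(blob)
        expr, _ = make_expression(celltypes, ExprSimConfig(n_genes=20, seed=seed))
        export_bundle(expr, [emb3d], out_dir, overwrite=True)
        truth = {"preset": preset, "seed": seed, "n_cells": emb3d.n_cells}
    elif preset == "fig2":
        sigma, n_per_pop = 0.05, 200
        separation = 10 * sigma
        emb3d, emb2d, celltypes = make_axis_hidden_pair(
            separation=separation, sigma=sigma, n_per_pop=n_per_pop, seed=seed
        )
        expr, de_genes = make_expression(
            celltypes, ExprSimConfig(n_genes=50, seed=seed)
        )
        export_bundle(
            expr, [emb3d, emb2d], out_dir, celltypes=celltypes, overwrite=True
        )
        truth = {
            "preset": preset,
            "seed": seed,
            "separation": separation,
            "sigma": sigma,
            "n_per_population": n_per_pop,
            "hidden_pair": ["pop_a", "pop_b"],
            "true_de_genes": de_genes,
        }
    elif preset == "de":
        blob = BlobConfig(
            centers=[(0.0, 0.0, 0.0), (10.0, 0.0, 0.0)],
            n_per_population=[100, 100],
            sigma=[1.0, 1.0],
            seed=seed,
            population_names=["group_1", "group_2"],
        )
        emb3d, celltypes = make_blobs_3d(blob)
        sim = ExprSimConfig(
            n_genes=500, de_fraction=0.1, effect=2.0, seed=seed
        )
        expr, de_genes = make_expression(celltypes, sim)
        export_bundle(
            expr, [emb3d], out_dir, celltypes=celltypes, overwrite=True
        )
        truth = {
            "preset": preset,
            "seed": seed,
            "n_genes": sim.n_genes,
            "effect": sim.effect,
            "true_de_genes": de_genes,
            "upregulated_in": "group_2",
        }
    else:
        raise ValidationError(f"unknown preset {preset!r}; choose from {PRESETS}")
    (out_dir / GROUND_TRUTH_NAME).write_text(
        json.dumps(truth, indent=2, sort_keys=True) + "\n"
    )
    return out_dir
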