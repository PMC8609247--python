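"""In-session statistics on user-selected cell groups.

Implements the backend calculations performed on selections: Wilcoxon
rank-sum differential expression with Benjamini-Hochberg adjustment, top-N
marker ordering by hierarchical clustering, top-K transcription-factor
network edge selection, k-means partitioning for external trajectory
inference, pseudotime binning into equal-sized groups, and ranking genes by
correlation with pseudotime.

The Wilcoxon test and the BH adjustment are implemented in-package. The
test uses midranks for ties; the p-value is computed by exact enumeration
of the rank-sum null distribution when ``n1 + n2 <= 20`` and the pooled
sample has no ties, and otherwise by the normal approximation with tie and
continuity corrections.

The ``"rho"`` edge score is a transparent proportionality coefficient
``2 cov(a, b) / (var a + var b)`` on log1p expression — a documented
stand-in, not numerically identical to the propr package's estimator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.cluster import KMeans

from .errors import ValidationError
from .io_formats import ExpressionMatrix

#: Largest pooled sample size for which the exact p-value is enumerated.
EXACT_LIMIT = 20


@dataclass
class SelectionGroups:
    """Disjoint, non-empty cell groups selected for analysis."""

    assignments: dict[str, list[str]]

    def __post_init__(self) -> None:
        if len(self.assignments) < 2:
            raise ValidationError("need at least 2 groups")
        seen: set[str] = set()
        for name, cells in self.assignments.items():
            if not cells:
                raise ValidationError(f"group {name!r} is empty")
            overlap = seen & set(cells)
            if overlap:
                raise ValidationError(
                    f"groups are not disjoint; e.g. {sorted(overlap)[:3]}"
                )
            seen |= set(cells)

    @property
    def group_names(self) -> list[str]:
        return list(self.assignments)


@dataclass(frozen=True)
class AnalyticsConfig:
    """Defaults for the in-session calculations."""

    n_top_markers: int = 250
    k_top_edges: int = 130
    n_trajectory_clusters: int = 4
    n_pseudotime_bins: int = 10
    edge_score_method: str = "rho"

    def __post_init__(self) -> None:
        for v in (
            self.n_top_markers,
            self.k_top_edges,
            self.n_trajectory_clusters,
            self.n_pseudotime_bins,
        ):
            if v < 1:
                raise ValidationError("all counts must be positive")
        if self.edge_score_method not in ("pearson", "rho"):
            raise ValidationError("edge_score_method must be 'pearson' or 'rho'")


@dataclass
class DEResult:
    """Per-gene differential-expression table, ranked for the heatmap.

    ``table`` columns: gene, statistic, p_value, fdr, direction (+1 when
    group 1's mean is higher, -1 lower, 0 equal). Rows are ordered by
    p-value, ties broken by larger absolute mean difference then gene name.
    """

    table: pd.DataFrame
    group_a: str
    group_b: str


@dataclass
class NetworkResult:
    """Top-scoring TF-TF edges plus genes excluded for zero variance."""

    edges: pd.DataFrame
    excluded_genes: list[str] = field(default_factory=list)
    method: str = "rho"


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _exact_ranksum_distribution(n1: int, n: int) -> np.ndarray:
    """Counts of subsets of {1..n} of size n1 by rank sum (index = sum)."""
    max_sum = n * (n + 1) // 2
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for rank in range(1, n + 1):
        for k in range(min(n1, rank), 0, -1):
            counts[k, rank:] += counts[k - 1, : max_sum + 1 - rank]
    return counts[n1]


def wilcoxon_rank_sum(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns ``(W, p)``.

    ``W`` is the sum of midranks of ``x`` in the pooled sample. With
    ``method="auto"`` the null distribution is enumerated exactly for
    small tie-free samples (pooled ``n <= 20``); larger or tied samples
    use the normal approximation with tie and continuity corrections.
    ``method="exact"``/``"approx"`` force a regime (exact requires no
    ties).
    """
    if method not in ("auto", "exact", "approx"):
        raise ValidationError("method must be 'auto', 'exact' or 'approx'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both groups need at least one value")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(np.sum(ranks[:n1]))
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))

    use_exact = (
        method == "exact" or (method == "auto" and n <= EXACT_LIMIT and not has_ties)
    )
    if use_exact:
        if has_ties:
            raise ValidationError("exact enumeration requires a tie-free sample")
        dist = _exact_ranksum_distribution(n1, n)
        total = dist.sum()
        wi = int(round(w))
        p_low = dist[: wi + 1].sum() / total
        p_high = dist[wi:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return w, p

    mu = n1 * (n + 1) / 2.0
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return w, 1.0
    diff = w - mu
    # continuity correction shrinks |diff| by 0.5
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(var) if diff != 0 else 0.0
    p = min(1.0, 2.0 * _norm_sf(abs(z)))
    return w, p


def _norm_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for idx in range(m - 1, -1, -1):
        i = order[idx]
        value = p[i] * m / (idx + 1)
        running_min = min(running_min, value)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------


def _two_group_de(
    expr: ExpressionMatrix, cells_a: list[str], cells_b: list[str],
    name_a: str, name_b: str,
) -> DEResult:
    idx = {c: i for i, c in enumerate(expr.cell_ids)}
    missing = [c for c in cells_a + cells_b if c not in idx]
    if len(missing) == len(cells_a) + len(cells_b):
        raise ValidationError("selected cells have no overlap with expression matrix")
    ia = [idx[c] for c in cells_a if c in idx]
    ib = [idx[c] for c in cells_b if c in idx]
    if not ia or not ib:
        raise ValidationError("a group has no cells in the expression matrix")
    if len(ia) < 2 or len(ib) < 2:
        warnings.warn("a selection group has fewer than 2 cells; test power is minimal")
    a = expr.values[:, ia]
    b = expr.values[:, ib]
    stats = np.empty(expr.n_genes)
    pvals = np.empty(expr.n_genes)
    for g in range(expr.n_genes):
        stats[g], pvals[g] = wilcoxon_rank_sum(a[g], b[g])
    mean_diff = a.mean(axis=1) - b.mean(axis=1)
    table = pd.DataFrame(
        {
            "gene": expr.gene_names,
            "statistic": stats,
            "p_value": pvals,
            "fdr": bh_adjust(pvals),
            "direction": np.sign(mean_diff).astype(int),
            "mean_difference": mean_diff,
        }
    )
    return DEResult(_rank_de_table(table), name_a, name_b)


def _rank_de_table(table: pd.DataFrame) -> pd.DataFrame:
    tmp = table.assign(_absdiff=table["mean_difference"].abs())
    tmp = tmp.sort_values(
        by=["p_value", "_absdiff", "gene"],
        ascending=[True, False, True],
        kind="mergesort",
        ignore_index=True,
    )
    return tmp.drop(columns="_absdiff")


def differential_expression(
    expr: ExpressionMatrix,
    groups: SelectionGroups,
    config: AnalyticsConfig = AnalyticsConfig(),
) -> DEResult | dict[str, DEResult]:
    """Per-gene Wilcoxon DE between selection groups.

    With exactly 2 groups a single :class:`DEResult` is returned; with more
    groups each group is tested against the union of the rest and a dict of
    per-group results is returned.
    """
    names = groups.group_names
    if len(names) == 2:
        a, b = names
        return _two_group_de(
            expr, groups.assignments[a], groups.assignments[b], a, b
        )
    results: dict[str, DEResult] = {}
    for name in names:
        rest = [c for other in names if other != name for c in groups.assignments[other]]
        results[name] = _two_group_de(
            expr, groups.assignments[name], rest, name, "rest"
        )
    return results


def select_and_order_markers(
    de: DEResult,
    expr: ExpressionMatrix,
    config: AnalyticsConfig = AnalyticsConfig(),
) -> list[str]:
    """Top-N marker genes, ordered by hierarchical-clustering leaf order.

    Takes ``min(N, G)`` top-ranked genes, standardizes each gene's
    expression across cells, clusters with Euclidean distance and complete
    linkage, and returns genes in dendrogram leaf order.
    """
    top = de.table["gene"].head(min(config.n_top_markers, len(de.table))).tolist()
    if len(top) < 2:
        return top
    idx = {g: i for i, g in enumerate(expr.gene_names)}
    mat = expr.values[[idx[g] for g in top]]
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (mat - mu) / sd
    order = leaves_list(linkage(z, method="complete", metric="euclidean"))
    return [top[i] for i in order]


# ---------------------------------------------------------------------------
# Networks, trajectories, pseudotime
# ---------------------------------------------------------------------------


def _proportionality_rho(log_expr: np.ndarray) -> np.ndarray:
    cov = np.cov(log_expr)
    var = np.diag(cov)
    denom = var[:, None] + var[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = 2.0 * cov / denom
    return rho


def network_edges(
    expr: ExpressionMatrix,
    tf_genes,
    config: AnalyticsConfig = AnalyticsConfig(),
) -> NetworkResult:
    """Top-K TF-TF edges by absolute association score.

    Scores every pair of transcription-factor genes present in ``expr``
    with either the proportionality coefficient ``rho`` (default) or the
    Pearson correlation, both on log1p expression. Constant genes are
    excluded from scoring and listed in the result.
    """
    if expr.n_cells < 3:
        raise ValidationError("need at least 3 cells to score edges")
    present = [g for g in tf_genes if g in set(expr.gene_names)]
    idx = {g: i for i, g in enumerate(expr.gene_names)}
    log_expr = np.log1p(expr.values[[idx[g] for g in present]])
    variances = log_expr.var(axis=1)
    excluded = [g for g, v in zip(present, variances) if v == 0]
    kept = [g for g, v in zip(present, variances) if v > 0]
    if len(kept) < 2:
        raise ValidationError("need at least 2 non-constant TF genes")
    log_expr = log_expr[[present.index(g) for g in kept]]
    if config.edge_score_method == "rho":
        score_matrix = _proportionality_rho(log_expr)
    else:
        score_matrix = np.corrcoef(log_expr)
    rows = []
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            rows.append((kept[i], kept[j], float(score_matrix[i, j])))
    table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])
    table = table.assign(_abs=table["score"].abs()).sort_values(
        by=["_abs", "gene_a", "gene_b"],
        ascending=[False, True, True],
        kind="mergesort",
        ignore_index=True,
    ).drop(columns="_abs")
    return NetworkResult(
        table.head(config.k_top_edges).reset_index(drop=True),
        excluded,
        config.edge_score_method,
    )


def partition_for_trajectory(
    points3d,
    config: AnalyticsConfig = AnalyticsConfig(),
    seed: int = 0,
) -> np.ndarray:
    """K-means partition of selected cells used as trajectory-tool input."""
    pts = np.asarray(points3d, dtype=float)
    k = config.n_trajectory_clusters
    if len(pts) < k:
        raise ValidationError(f"need at least {k} cells, got {len(pts)}")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(pts)


def pseudotime_bins(
    pseudotime,
    cell_ids,
    config: AnalyticsConfig = AnalyticsConfig(),
) -> np.ndarray:
    """Cut cells into ``n_pseudotime_bins`` contiguous equal-sized groups.

    Cells are ranked by pseudotime (ties broken by cell-ID order) and split
    into contiguous groups whose sizes differ by at most 1, the earlier
    bins taking the extra cells. Returns a bin index per input cell.
    """
    values = np.asarray(pseudotime, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError("pseudotime values must be finite")
    ids = [str(c) for c in cell_ids]
    if len(ids) != len(values):
        raise ValidationError("cell_ids length does not match pseudotime")
    k = config.n_pseudotime_bins
    n = len(values)
    order = sorted(range(n), key=lambda i: (values[i], ids[i]))
    base, extra = divmod(n, k)
    bins = np.empty(n, dtype=int)
    pos = 0
    for b in range(k):
        size = base + (1 if b < extra else 0)
        for i in order[pos : pos + size]:
            bins[i] = b
        pos += size
    return bins


def correlate_to_pseudotime(expr: ExpressionMatrix, pseudotime) -> pd.DataFrame:
    """Rank genes by absolute Pearson correlation with pseudotime.

    Constant genes (and a constant pseudotime) get correlation 0.
    """
    t = np.asarray(pseudotime, dtype=float)
    if len(t) != expr.n_cells:
        raise ValidationError("pseudotime must cover all cells")
    tc = t - t.mean()
    t_ss = float(np.sum(tc**2))
    x = expr.values - expr.values.mean(axis=1, keepdims=True)
    x_ss = np.sum(x**2, axis=1)
    denom = np.sqrt(x_ss * t_ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, x @ tc / np.where(denom > 0, denom, 1.0), 0.0)
    table = pd.DataFrame({"gene": expr.gene_names, "correlation": r})
    return table.assign(_abs=table["correlation"].abs()).sort_values(
        by=["_abs", "gene"],
        ascending=[False, True],
        kind="mergesort",
        ignore_index=True,
    ).drop(columns="_abs")
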