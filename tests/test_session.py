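import itertools
import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from embedsep import (
    AnalyticsConfig,
    ExpressionMatrix,
    SelectionGroups,
    bh_adjust,
    correlate_to_pseudotime,
    differential_expression,
    network_edges,
    partition_for_trajectory,
    pseudotime_bins,
    select_and_order_markers,
    wilcoxon_rank_sum,
)
from embedsep.errors import ValidationError
from embedsep.synthetic import BlobConfig, ExprSimConfig, make_blobs_3d, make_expression


def exact_p_oracle(x, y):
    """Enumerate all group-1 allocations of the pooled tie-free sample."""
    pooled = sorted(x) + sorted(y)
    assert len(set(pooled)) == len(pooled), "oracle requires distinct values"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    w_obs = sum(ranks[v] for v in x)
    n1 = len(x)
    mu = n1 * (len(pooled) + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), n1):
        total += 1
        if abs(sum(combo) - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestWilcoxon:
    def test_extreme_allocation_exact(self):
        w, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_small(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(2, 5))
        n2 = int(rng.integers(2, 5))
        values = rng.permutation(np.arange(1.0, n1 + n2 + 1))
        x, y = values[:n1], values[n1:]
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(exact_p_oracle(list(x), list(y)), abs=1e-12)

    def test_approx_close_to_exact_n10(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            values = rng.permutation(np.arange(1.0, 21.0))
            x, y = values[:10], values[10:]
            _, p_exact = wilcoxon_rank_sum(x, y, method="exact")
            _, p_approx = wilcoxon_rank_sum(x, y, method="approx")
            assert abs(p_exact - p_approx) < 0.01

    def test_ties_use_midranks(self):
        w, p = wilcoxon_rank_sum([1.0, 2.0, 2.0], [2.0, 3.0, 4.0])
        # midrank of the three 2.0s is 3
        assert w == 1 + 3 + 3
        assert 0.0 <= p <= 1.0

    def test_matches_scipy_large(self, rng):
        from scipy.stats import mannwhitneyu

        x = rng.normal(size=40)
        y = rng.normal(loc=0.6, size=35)
        _, p = wilcoxon_rank_sum(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert p == pytest.approx(ref, abs=1e-6)


class TestBH:
    def test_hand_computation(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.5]
        adj = bh_adjust(p)
        # hand BH: p*(m/i) with monotone min from the largest p down
        expected = [0.05, 0.05, 0.05, 0.05, 0.5]
        np.testing.assert_allclose(adj, expected, atol=1e-12)

    def test_monotone_and_bounded(self, rng):
        p = rng.random(50)
        adj = bh_adjust(p)
        assert np.all(adj <= 1.0) and np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels(self, seed):
        p = np.random.default_rng(seed).random(30)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )


def de_fixture(seed=0, n_genes=100, n_per_group=30, effect=2.0):
    blob = BlobConfig(
        centers=[(0, 0, 0), (8, 0, 0)],
        n_per_population=[n_per_group, n_per_group],
        sigma=[1.0, 1.0],
        seed=seed,
        population_names=["g1", "g2"],
    )
    emb, ct = make_blobs_3d(blob)
    expr, de_genes = make_expression(
        ct, ExprSimConfig(n_genes=n_genes, de_fraction=0.2, effect=effect, seed=seed)
    )
    groups = SelectionGroups(
        {
            "g1": [c for c, m in zip(ct.cell_ids, ct.membership[:, 0]) if m],
            "g2": [c for c, m in zip(ct.cell_ids, ct.membership[:, 1]) if m],
        }
    )
    return expr, groups, de_genes, emb


class TestDifferentialExpression:
    def test_recovers_planted_genes(self):
        expr, groups, de_genes, _ = de_fixture()
        res = differential_expression(expr, groups)
        top = set(res.table["gene"].head(len(de_genes)))
        assert len(top & set(de_genes)) / len(de_genes) >= 0.9

    def test_direction_sign(self):
        expr, groups, de_genes, _ = de_fixture()
        res = differential_expression(expr, groups)
        # planted genes are upregulated in group 2 => group 1 mean lower
        planted = res.table[res.table["gene"].isin(de_genes)]
        assert (planted["direction"] == -1).mean() > 0.9

    def test_fdr_column_valid(self):
        expr, groups, _, _ = de_fixture()
        res = differential_expression(expr, groups)
        assert res.table["fdr"].between(0, 1).all()
        assert (res.table["fdr"] >= res.table["p_value"] - 1e-12).all()

    def test_multi_group_one_vs_rest(self):
        expr, groups, _, _ = de_fixture()
        three = SelectionGroups(
            {
                "a": groups.assignments["g1"][:15],
                "b": groups.assignments["g1"][15:],
                "c": groups.assignments["g2"],
            }
        )
        res = differential_expression(expr, three)
        assert set(res) == {"a", "b", "c"}

    def test_disjoint_groups_enforced(self):
        with pytest.raises(ValidationError, match="disjoint"):
            SelectionGroups({"a": ["c1", "c2"], "b": ["c2"]})

    def test_no_expression_overlap_rejected(self):
        expr, _, _, _ = de_fixture()
        bad = SelectionGroups({"a": ["zz1"], "b": ["zz2"]})
        with pytest.raises(ValidationError):
            differential_expression(expr, bad)

    def test_tiny_group_warns_but_runs(self):
        expr, groups, _, _ = de_fixture()
        tiny = SelectionGroups(
            {
                "a": groups.assignments["g1"][:1],
                "b": groups.assignments["g2"],
            }
        )
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = differential_expression(expr, tiny)
        assert len(res.table) == expr.n_genes


class TestMarkers:
    def test_truncation_when_few_genes(self):
        expr, groups, _, _ = de_fixture(n_genes=100)
        res = differential_expression(expr, groups)
        markers = select_and_order_markers(res, expr)  # default N = 250 > 100
        assert sorted(markers) == sorted(expr.gene_names)

    def test_top_n_limits(self):
        expr, groups, _, _ = de_fixture(n_genes=100)
        res = differential_expression(expr, groups)
        markers = select_and_order_markers(res, expr, AnalyticsConfig(n_top_markers=10))
        assert len(markers) == 10

    def test_identical_rows_adjacent(self):
        expr, groups, _, _ = de_fixture(n_genes=50)
        values = expr.values.copy()
        values[1] = values[0]  # duplicate gene profile
        dup = ExpressionMatrix(expr.gene_names, expr.cell_ids, values)
        res = differential_expression(dup, groups)
        markers = select_and_order_markers(res, dup)
        g0, g1 = expr.gene_names[0], expr.gene_names[1]
        assert abs(markers.index(g0) - markers.index(g1)) == 1


class TestNetwork:
    def _expr(self, rng, n_genes=10, n_cells=40):
        values = rng.random((n_genes, n_cells)) * 5
        return ExpressionMatrix(
            [f"tf{i}" for i in range(n_genes)],
            [f"c{i}" for i in range(n_cells)],
            values,
        )

    def test_duplicate_gene_scores_one(self, rng):
        expr = self._expr(rng)
        values = expr.values.copy()
        values[1] = values[0]
        dup = ExpressionMatrix(expr.gene_names, expr.cell_ids, values)
        res = network_edges(dup, dup.gene_names)
        first = res.edges.iloc[0]
        assert {first["gene_a"], first["gene_b"]} == {"tf0", "tf1"}
        assert first["score"] == pytest.approx(1.0)

    def test_fewer_pairs_than_k(self, rng):
        expr = self._expr(rng, n_genes=4)
        res = network_edges(expr, expr.gene_names)  # default K = 130 > 6 pairs
        assert len(res.edges) == 6

    def test_top_k_truncation(self, rng):
        expr = self._expr(rng, n_genes=10)
        res = network_edges(expr, expr.gene_names, AnalyticsConfig(k_top_edges=5))
        assert len(res.edges) == 5

    def test_constant_gene_excluded(self, rng):
        expr = self._expr(rng)
        values = expr.values.copy()
        values[3] = 2.0
        const = ExpressionMatrix(expr.gene_names, expr.cell_ids, values)
        res = network_edges(const, const.gene_names)
        assert res.excluded_genes == ["tf3"]
        assert "tf3" not in set(res.edges["gene_a"]) | set(res.edges["gene_b"])

    def test_pearson_method(self, rng):
        expr = self._expr(rng)
        res = network_edges(
            expr, expr.gene_names, AnalyticsConfig(edge_score_method="pearson")
        )
        assert res.edges["score"].abs().le(1 + 1e-9).all()

    def test_too_few_cells_rejected(self, rng):
        expr = ExpressionMatrix(["a", "b"], ["c1", "c2"], rng.random((2, 2)))
        with pytest.raises(ValidationError):
            network_edges(expr, ["a", "b"])


class TestTrajectoryAndPseudotime:
    def test_partition_labels(self, rng):
        pts = rng.normal(size=(40, 3))
        labels = partition_for_trajectory(pts)
        assert len(labels) == 40 and len(set(labels)) == 4

    def test_partition_deterministic(self, rng):
        pts = rng.normal(size=(30, 3))
        np.testing.assert_array_equal(
            partition_for_trajectory(pts, seed=1), partition_for_trajectory(pts, seed=1)
        )

    def test_partition_too_few_cells(self):
        with pytest.raises(ValidationError):
            partition_for_trajectory(np.zeros((3, 3)))

    def test_bins_divisible(self):
        bins = pseudotime_bins(np.arange(100.0), [f"c{i:03d}" for i in range(100)])
        sizes = np.bincount(bins)
        assert np.all(sizes == 10)

    def test_bins_103_cells(self):
        bins = pseudotime_bins(np.arange(103.0), [f"c{i:03d}" for i in range(103)])
        sizes = sorted(np.bincount(bins), reverse=True)
        assert sizes == [11, 11, 11] + [10] * 7

    def test_bins_monotone_in_rank(self, rng):
        values = rng.random(57)
        ids = [f"c{i:02d}" for i in range(57)]
        bins = pseudotime_bins(values, ids)
        order = np.argsort(values, kind="mergesort")
        assert np.all(np.diff(bins[order]) >= 0)

    def test_bins_tie_broken_by_cell_id(self):
        values = np.zeros(4)
        bins = pseudotime_bins(values, ["d", "c", "b", "a"], AnalyticsConfig(n_pseudotime_bins=2))
        # ranked by ID: a, b, c, d -> bins a=0, b=0, c=1, d=1
        np.testing.assert_array_equal(bins, [1, 1, 0, 0])

    def test_bins_deterministic(self, rng):
        values = rng.random(31)
        ids = [f"c{i}" for i in range(31)]
        np.testing.assert_array_equal(
            pseudotime_bins(values, ids), pseudotime_bins(values, ids)
        )

    def test_correlation_ranking(self, rng):
        t = np.linspace(0, 1, 50)
        values = rng.random((5, 50))
        values[2] = 3 * t + 1  # perfectly correlated
        values[4] = 1.0  # constant
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(5)], [f"c{i}" for i in range(50)], values
        )
        table = correlate_to_pseudotime(expr, t)
        assert table.iloc[0]["gene"] == "g2"
        assert table.iloc[0]["correlation"] == pytest.approx(1.0)
        assert table.set_index("gene").loc["g4", "correlation"] == 0.0

    def test_correlation_matches_pandas(self, rng):
        t = rng.random(30)
        expr = ExpressionMatrix(
            [f"g{i}" for i in range(4)], [f"c{i}" for i in range(30)], rng.random((4, 30))
        )
        table = correlate_to_pseudotime(expr, t).set_index("gene")
        for i, g in enumerate(expr.gene_names):
            ref = pd.Series(expr.values[i]).corr(pd.Series(t))
            assert table.loc[g, "correlation"] == pytest.approx(ref, abs=1e-12)


class TestConfigDefaults:
    def test_defaults_match_documented_values(self):
        config = AnalyticsConfig()
        assert config.n_top_markers == 250
        assert config.k_top_edges == 130
        assert config.n_trajectory_clusters == 4
        assert config.n_pseudotime_bins == 10
        assert config.edge_score_method == "rho"
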