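"""Path tree construction, split scoring, Fisher aggregation and ranking."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from epicdrem.associate import TFGeneMatrix
from epicdrem.genomic_io import ExpressionSeries
from epicdrem.grn import (
    aggregate_fisher,
    build_path_tree,
    correct_and_transform,
    filter_path_regulators,
    score_tree,
    split_score,
    top_regulators,
)


def hypergeom_tail_oracle(N, K, n, k):
    """P(X >= k) by exact enumeration of subsets-counting combinatorics."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1)
    ) / total


def two_group_series(n_genes=100, n_time=5, effect=3.0, noise=0.1, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    half = n_genes // 2
    values = np.full((n_genes, n_time), 5.0)
    values[:half, 1:] += effect
    values[half:, 1:] -= effect
    values += rng.normal(0, noise, size=values.shape)
    expr = ExpressionSeries(genes, [f"T{t}" for t in range(n_time)], values, "T0")
    labels = np.array(["up"] * half + ["down"] * (n_genes - half))
    return expr, labels


class TestPathTree:
    def test_homogeneous_profiles_give_single_path(self):
        expr, _ = two_group_series(effect=0.0, noise=0.01, seed=1)
        tree = build_path_tree(expr, n_states=4, min_path_genes=20, seed=0)
        assert tree.splits == []
        assert all(len(n.children) <= 1 for n in tree.nodes)

    def test_two_planted_groups_recovered_at_split_time(self):
        expr, labels = two_group_series(effect=3.0, noise=0.1, seed=2)
        tree = build_path_tree(expr, n_states=4, min_path_genes=20, seed=0)
        splits = tree.splits
        assert len(splits) >= 1
        root_split = splits[0]
        assert root_split.time_index == 0  # divergence happens into T1
        children = [tree.node(c) for c in root_split.children]
        assert len(children) == 2
        # >= 99% membership accuracy against planted labels
        for child in children:
            member_labels = [labels[int(g[1:])] for g in child.genes]
            majority = max(set(member_labels), key=member_labels.count)
            accuracy = member_labels.count(majority) / len(member_labels)
            assert accuracy >= 0.99

    def test_single_gene_gives_single_path(self):
        expr = ExpressionSeries(
            ["g0"], ["T0", "T1", "T2"], np.array([[0.0, 1.0, 2.0]]), "T0"
        )
        tree = build_path_tree(expr, n_states=4, min_path_genes=20, seed=0)
        assert tree.splits == []

    def test_n_states_below_two_rejected(self):
        expr, _ = two_group_series()
        with pytest.raises(ValueError, match="n_states"):
            build_path_tree(expr, n_states=1)

    def test_partition_conservation_at_every_time_point(self):
        expr, _ = two_group_series(n_genes=120, seed=3)
        tree = build_path_tree(expr, n_states=3, min_path_genes=10, seed=0)
        universe = set(expr.gene_ids)
        for t in range(len(expr.time_points)):
            nodes = tree.nodes_at(t)
            gene_sets = [n.genes for n in nodes]
            assert set().union(*gene_sets) == universe
            for a, b in combinations(gene_sets, 2):
                assert not (a & b)

    def test_children_partition_parent(self):
        expr, _ = two_group_series(seed=4)
        tree = build_path_tree(expr, n_states=4, min_path_genes=10, seed=0)
        for node in tree.nodes:
            if node.children:
                union = set()
                for c in node.children:
                    union |= tree.node(c).genes
                assert union == set(node.genes)

    def test_deterministic_under_seed(self):
        expr, _ = two_group_series(seed=5)
        t1 = build_path_tree(expr, seed=9)
        t2 = build_path_tree(expr, seed=9)
        assert [n.genes for n in t1.nodes] == [n.genes for n in t2.nodes]


class TestSplitScore:
    def test_exact_enumeration_example(self):
        # N=10, K=5, n=4, k=4 -> C(5,4)/C(10,4) = 5/210
        split = {f"g{i}" for i in range(10)}
        path = {"g0", "g1", "g2", "g3"}
        targets = {"g0", "g1", "g2", "g3", "g4"}
        assert split_score(split, path, targets) == pytest.approx(5 / 210, abs=1e-12)

    def test_zero_hits_gives_p_one(self):
        split = {f"g{i}" for i in range(10)}
        assert split_score(split, {"g5", "g6"}, {"g0"} - {"g0"} | set()) == 1.0

    def test_all_genes_targets_gives_p_one(self):
        split = {f"g{i}" for i in range(10)}
        assert split_score(split, {"g0", "g1"}, set(split)) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_combinatorial_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(5, 21))
        split = {f"g{i}" for i in range(N)}
        K = int(rng.integers(0, N + 1))
        targets = set(rng.choice(sorted(split), size=K, replace=False))
        n = int(rng.integers(1, N + 1))
        path = set(rng.choice(sorted(split), size=n, replace=False))
        k = len(path & targets)
        assert split_score(split, path, targets) == pytest.approx(
            hypergeom_tail_oracle(N, K, n, k), abs=1e-12
        )

    def test_empty_path_rejected(self):
        with pytest.raises(ValueError, match="empty path"):
            split_score({"g0"}, set(), {"g0"})

    def test_path_outside_split_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            split_score({"g0"}, {"g1"}, set())


class TestCorrectAndTransform:
    def test_bonferroni_and_log2(self):
        corrected, score = correct_and_transform(0.001, 100)
        assert corrected == pytest.approx(0.1)
        assert score == pytest.approx(-math.log2(0.1), abs=1e-9)  # ~3.3219

    def test_raw_one_gives_zero_score(self):
        assert correct_and_transform(1.0, 10) == (1.0, 0.0)

    def test_cap_at_one(self):
        corrected, score = correct_and_transform(0.5, 4)
        assert (corrected, score) == (1.0, 0.0)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            correct_and_transform(1.5, 10)


class TestFisherAggregate:
    def _table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["tf", "split_id", "path_id", "time_point", "raw_p",
                     "corrected_p", "drem_score", "path_fraction"],
        )

    def test_closed_form_two_splits(self):
        table = self._table(
            [("TF", "s1", "p1", "T1", 0.05, 0.05, 4.32, 0.5),
             ("TF", "s2", "p2", "T1", 0.05, 0.05, 4.32, 0.5)]
        )
        agg = aggregate_fisher(table, "T1")
        assert agg.loc[0, "X"] == pytest.approx(-4 * math.log(0.05), abs=1e-4)
        assert agg.loc[0, "s"] == 2

    def test_all_p_one_gives_zero(self):
        table = self._table([("TF", "s1", "p1", "T1", 1.0, 1.0, 0.0, 0.0)])
        assert aggregate_fisher(table, "T1").loc[0, "X"] == 0.0

    def test_single_split_monotone_in_p(self):
        xs = []
        for p in (0.5, 0.1, 0.01):
            table = self._table([("TF", "s1", "p1", "T1", p, p, 0.0, 0.5)])
            xs.append(aggregate_fisher(table, "T1").loc[0, "X"])
        assert xs == sorted(xs)

    def test_absent_split_contributes_p_one(self):
        table = self._table(
            [("A", "s1", "p1", "T1", 0.05, 0.05, 4.3, 0.5),
             ("A", "s2", "p2", "T1", 0.05, 0.05, 4.3, 0.5),
             ("B", "s1", "p1", "T1", 0.05, 0.05, 4.3, 0.5)]
        )
        agg = aggregate_fisher(table, "T1").set_index("tf")
        assert agg.loc["A", "X"] == pytest.approx(2 * agg.loc["B", "X"])

    def test_null_statistic_follows_chi2_mean(self):
        """Uniform p-values: X ~ chi2(2s), so E[X] = 2s (checked +/- 5%)."""
        rng = np.random.default_rng(42)
        s = 3
        n_rep = 10_000
        ps = rng.uniform(size=(n_rep, s))
        xs = -2 * np.log(ps).sum(axis=1)
        # the aggregate in code matches this formula on one replicate
        rows = [("TF", f"s{i}", f"p{i}", "T1", p, p, 0.0, 0.5)
                for i, p in enumerate(ps[0])]
        agg = aggregate_fisher(self._table(rows), "T1")
        assert agg.loc[0, "X"] == pytest.approx(xs[0], abs=1e-9)
        assert abs(xs.mean() - 2 * s) <= 0.05 * 2 * s


class TestRankingAndFilter:
    def _agg(self, xs):
        return pd.DataFrame(
            {"tf": [f"TF{i}" for i in range(len(xs))], "time_point": "T1",
             "X": xs, "s": 1, "rank": 0}
        )

    def test_top_k_by_descending_x(self):
        assert top_regulators(self._agg([5.0, 9.0, 1.0]), k=2) == ["TF1", "TF0"]

    def test_k_larger_than_tf_count_gives_full_ranking(self):
        assert len(top_regulators(self._agg([5.0, 9.0, 1.0]), k=10)) == 3

    def test_ties_broken_alphabetically(self):
        agg = pd.DataFrame(
            {"tf": ["ZZZ", "AAA"], "time_point": "T1", "X": [5.0, 5.0],
             "s": 1, "rank": 0}
        )
        assert top_regulators(agg, k=2) == ["AAA", "ZZZ"]

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            top_regulators(self._agg([1.0]), k=0)

    @pytest.mark.parametrize(
        "fraction,p,kept",
        [(0.29, 0.001, False), (0.5, 0.02, False), (0.5, 0.01, True),
         (0.30, 0.005, True)],
    )
    def test_path_regulator_filter_boundaries(self, fraction, p, kept):
        table = pd.DataFrame(
            [("TF", "s1", "p1", "T1", p, p, 1.0, fraction)],
            columns=["tf", "split_id", "path_id", "time_point", "raw_p",
                     "corrected_p", "drem_score", "path_fraction"],
        )
        out = filter_path_regulators(table)
        assert (len(out) == 1) == kept


class TestScoreTreeEndToEnd:
    def test_planted_regulator_scores_best_on_its_path(self):
        expr, labels = two_group_series(n_genes=200, seed=7)
        tree = build_path_tree(expr, n_states=4, min_path_genes=20, seed=0)
        genes = expr.gene_ids
        rng = np.random.default_rng(8)
        up_genes = [g for g, l in zip(genes, labels) if l == "up"]
        values = np.zeros((3, len(genes)), dtype=np.int8)
        tf_names = ["PLANTED", "decoy1", "decoy2"]
        planted_targets = set(rng.choice(up_genes, size=int(0.6 * len(up_genes)), replace=False))
        for j, g in enumerate(genes):
            values[0, j] = int(g in planted_targets)
            values[1, j] = int(rng.random() < 0.1)
            values[2, j] = int(rng.random() < 0.1)
        matrices = {
            tp: TFGeneMatrix(tfs=tf_names, genes=list(genes), values=values, time_point=tp)
            for tp in expr.time_points
        }
        scores = score_tree(tree, matrices)
        agg = aggregate_fisher(scores, "T1")
        assert top_regulators(agg, k=1) == ["PLANTED"]
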