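"""Temporal co-expression paths, TF split scores and regulator ranking.

Genes are clustered into a tree of co-expressed paths over the time course:
the root holds every gene at the reference time, and at each subsequent
time point a node splits when its genes diverge into two or more distinct
expression states. The path model here is intentionally simple — seeded 1-D
k-means on the per-gene expression change between consecutive time points,
with children linked to parents by gene flow and undersized children merged
into their largest sibling — a deliberate simplification of the
input-output hidden Markov machinery of the original dynamic-regulatory-map
tools, keeping only the tree semantics the downstream statistics need.

Each split is annotated with TFs: a hypergeometric over-representation test
asks whether a TF's targets (from the time-point-specific binary TF-gene
matrix) are enriched on one emanating path relative to the split's gene
population. Split p-values are Bonferroni-corrected per split, transformed
to -log2 ("split score"), and aggregated per TF per time point with
Fisher's method, X = -2 * sum(ln p); ranking X within a time point yields
the top regulators of that stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .associate import TFGeneMatrix
from .genomic_io import ExpressionSeries

__all__ = [
    "PathNode",
    "PathTree",
    "build_path_tree",
    "split_score",
    "correct_and_transform",
    "score_tree",
    "aggregate_fisher",
    "top_regulators",
    "filter_path_regulators",
]


@dataclass
class PathNode:
    node_id: int
    time_index: int
    time_point: str
    genes: frozenset[str]
    parent: int | None = None
    children: list[int] = field(default_factory=list)


@dataclass
class PathTree:
    nodes: list[PathNode]
    time_points: list[str]

    @property
    def root(self) -> PathNode:
        return self.nodes[0]

    def node(self, node_id: int) -> PathNode:
        return self.nodes[node_id]

    @property
    def splits(self) -> list[PathNode]:
        """Nodes with two or more children (bifurcation points)."""
        return [n for n in self.nodes if len(n.children) >= 2]

    def leaves(self) -> list[PathNode]:
        return [n for n in self.nodes if not n.children]

    def nodes_at(self, time_index: int) -> list[PathNode]:
        return [n for n in self.nodes if n.time_index == time_index]

    def assignments(self) -> pd.DataFrame:
        """Long-form (gene, time_point, node_id) path membership table."""
        rows = []
        for node in self.nodes:
            for g in sorted(node.genes):
                rows.append((g, node.time_point, node.node_id))
        return pd.DataFrame(rows, columns=["gene", "time_point", "node_id"])


def _cluster_deltas(
    deltas: np.ndarray, k: int, seed: int, min_separation: float
) -> np.ndarray:
    """Seeded 1-D k-means labels, relabeled by ascending cluster center.

    Adjacent clusters whose centers differ by less than ``min_separation``
    are merged: states must represent genuinely distinct expression
    changes, otherwise measurement noise alone would fragment every path.
    """
    k = min(k, len(np.unique(deltas)))
    if k <= 1:
        return np.zeros(deltas.size, dtype=int)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(deltas.reshape(-1, 1))
    order = np.argsort(km.cluster_centers_.ravel())
    centers = km.cluster_centers_.ravel()[order]
    remap = np.empty(k, dtype=int)
    # walk sorted centers, opening a new state only at a wide enough gap
    merged_ids = np.zeros(k, dtype=int)
    sid = 0
    for idx in range(1, k):
        if centers[idx] - centers[idx - 1] >= min_separation:
            sid += 1
        merged_ids[idx] = sid
    for rank, cluster in enumerate(order):
        remap[cluster] = merged_ids[rank]
    return remap[labels]


def build_path_tree(
    expr: ExpressionSeries,
    n_states: int = 4,
    min_path_genes: int = 20,
    seed: int = 0,
    min_state_separation: float = 1.0,
) -> PathTree:
    """Build the co-expression path tree over the time course.

    At each time point after the first, every gene's expression change from
    the previous time point is clustered into at most ``n_states`` states;
    states whose centers differ by less than ``min_state_separation`` log2
    units are merged, so a state marks a distinct expression change rather
    than a noise quantile.
    Within each current path, genes are partitioned by their state; child
    groups smaller than ``min_path_genes`` are absorbed into the largest
    sibling, and a node with >= 2 surviving children becomes a split.
    Deterministic for a fixed seed.
    """
    if n_states < 2:
        raise ValueError(f"n_states must be >= 2, got {n_states}")
    if len(expr.time_points) < 2:
        raise ValueError("need at least two time points")
    genes = np.array(expr.gene_ids)
    root = PathNode(0, 0, expr.time_points[0], frozenset(expr.gene_ids))
    nodes = [root]
    frontier = [root]
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    for t in range(1, len(expr.time_points)):
        deltas = expr.values[:, t] - expr.values[:, t - 1]
        labels = _cluster_deltas(deltas, n_states, seed + t, min_state_separation)
        new_frontier: list[PathNode] = []
        for parent in frontier:
            idx = np.array(sorted(gene_pos[g] for g in parent.genes))
            groups: dict[int, np.ndarray] = {}
            for state in np.unique(labels[idx]):
                groups[int(state)] = idx[labels[idx] == state]
            # absorb undersized groups into the largest one
            sizes = {s: len(v) for s, v in groups.items()}
            largest = max(sizes, key=lambda s: (sizes[s], -s))
            kept = {s for s, n in sizes.items() if n >= min_path_genes and s != largest}
            kept.add(largest)
            merged: dict[int, list[int]] = {s: list(groups[s]) for s in kept}
            for s, members in groups.items():
                if s not in kept:
                    merged[largest].extend(members)
            for s in sorted(merged):
                child = PathNode(
                    len(nodes),
                    t,
                    expr.time_points[t],
                    frozenset(genes[i] for i in merged[s]),
                    parent=parent.node_id,
                )
                nodes.append(child)
                parent.children.append(child.node_id)
                new_frontier.append(child)
        frontier = new_frontier
    return PathTree(nodes=nodes, time_points=list(expr.time_points))


def split_score(
    split_genes: set[str] | frozenset[str],
    path_genes: set[str] | frozenset[str],
    tf_targets: set[str],
) -> float:
    """One-sided hypergeometric over-representation p-value.

    Population: the ``split_genes`` at the bifurcation (size N), of which
    the TF targets K; draws: the ``path_genes`` on one emanating path
    (size n), of which k are targets. Returns P(X >= k).
    """
    if not path_genes:
        raise ValueError("empty path")
    if not path_genes <= set(split_genes):
        raise ValueError("path genes must be a subset of the split's genes")
    N = len(split_genes)
    K = len(tf_targets & set(split_genes))
    n = len(path_genes)
    k = len(tf_targets & set(path_genes))
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def correct_and_transform(raw_p: float, n_tests: int) -> tuple[float, float]:
    """Bonferroni-correct a split p-value and return (corrected, -log2)."""
    if not 0 <= raw_p <= 1:
        raise ValueError(f"p-value {raw_p} outside [0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    corrected = min(1.0, raw_p * n_tests)
    return corrected, float(-np.log2(corrected)) if corrected > 0 else float("inf")


def _nearest_matrix(
    matrices: dict[str, TFGeneMatrix], time_points: list[str], time_index: int
) -> TFGeneMatrix:
    """The TF-gene matrix of the nearest profiled time point at or before
    ``time_index``; falls back to the earliest profiled one."""
    for t in range(time_index, -1, -1):
        if time_points[t] in matrices:
            return matrices[time_points[t]]
    for t in range(time_index + 1, len(time_points)):
        if time_points[t] in matrices:
            return matrices[time_points[t]]
    raise ValueError("no TF-gene matrix for any time point")


def score_tree(
    tree: PathTree,
    matrices: dict[str, TFGeneMatrix],
    use_corrected: bool = True,
) -> pd.DataFrame:
    """Score every (TF, split, path) triple of the tree.

    Returns the split-score table with columns: tf, split_id, path_id,
    time_point (of the paths emanating from the split), raw_p, corrected_p,
    drem_score and path_fraction (fraction of the path's genes that are TF
    targets). Bonferroni ``n_tests`` is the number of TFs scored at the
    split. ``use_corrected=False`` leaves drem_score on raw p-values.
    """
    rows = []
    for split in tree.splits:
        child_time = split.time_index + 1
        matrix = _nearest_matrix(matrices, tree.time_points, child_time)
        n_tests = len(matrix.tfs)
        split_genes = set(split.genes)
        N = len(split_genes)
        gene_pos = {g: j for j, g in enumerate(matrix.genes)}
        split_idx = np.array(
            [gene_pos[g] for g in split_genes if g in gene_pos], dtype=int
        )
        K_vec = (
            matrix.values[:, split_idx].sum(axis=1)
            if split_idx.size
            else np.zeros(len(matrix.tfs), dtype=int)
        )
        for child_id in split.children:
            child = tree.node(child_id)
            child_genes = set(child.genes)
            n = len(child_genes)
            child_idx = np.array(
                [gene_pos[g] for g in child_genes if g in gene_pos], dtype=int
            )
            k_vec = (
                matrix.values[:, child_idx].sum(axis=1)
                if child_idx.size
                else np.zeros(len(matrix.tfs), dtype=int)
            )
            raw = stats.hypergeom.sf(k_vec - 1, N, K_vec, n)
            corrected = np.minimum(1.0, raw * n_tests)
            basis = corrected if use_corrected else raw
            with np.errstate(divide="ignore"):
                scores = -np.log2(basis)
            for i, tf in enumerate(matrix.tfs):
                rows.append(
                    (
                        tf,
                        f"split_{split.node_id}",
                        f"path_{child_id}",
                        tree.time_points[child_time],
                        float(raw[i]),
                        float(corrected[i]),
                        float(scores[i]),
                        float(k_vec[i] / n) if n else 0.0,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "tf",
            "split_id",
            "path_id",
            "time_point",
            "raw_p",
            "corrected_p",
            "drem_score",
            "path_fraction",
        ],
    )


def aggregate_fisher(
    table: pd.DataFrame, time_point: str, use_corrected: bool = True
) -> pd.DataFrame:
    """Fisher's-method aggregate X = -2 * sum(ln p) per TF at one time point.

    The sum runs over the splits whose emanating paths sit at
    ``time_point``; a TF keeps its single best (minimum) p per split, and a
    TF absent from a split contributes p = 1 there. Ranks are dense,
    descending in X, ties broken alphabetically by TF name.
    """
    sub = table[table["time_point"].astype(str) == str(time_point)]
    if sub.empty:
        raise ValueError(f"no splits at time point {time_point!r}")
    col = "corrected_p" if use_corrected else "raw_p"
    per_split = sub.groupby(["tf", "split_id"])[col].min().reset_index()
    s = sub["split_id"].nunique()
    rows = []
    for tf, grp in per_split.groupby("tf"):
        ps = grp[col].to_numpy()
        # absent splits contribute ln(1) = 0
        with np.errstate(divide="ignore"):
            x = float(-2.0 * np.sum(np.log(np.clip(ps, 1e-300, None))))
        rows.append((tf, time_point, x + 0.0, s))  # +0.0 normalizes -0.0
    agg = pd.DataFrame(rows, columns=["tf", "time_point", "X", "s"])
    agg = agg.sort_values(["X", "tf"], ascending=[False, True]).reset_index(drop=True)
    agg["rank"] = agg["X"].rank(method="dense", ascending=False).astype(int)
    return agg


def top_regulators(agg: pd.DataFrame, k: int = 15) -> list[str]:
    """Top-k TFs by aggregated Fisher score (descending, ties alphabetical)."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if agg.empty:
        raise ValueError("empty aggregate table")
    ordered = agg.sort_values(["X", "tf"], ascending=[False, True])
    return ordered["tf"].head(k).tolist()


def filter_path_regulators(
    table: pd.DataFrame,
    min_fraction: float = 0.30,
    max_corrected_p: float = 0.01,
) -> pd.DataFrame:
    """Keep (TF, path) rows where the TF targets at least ``min_fraction``
    of the path's genes and the corrected split p-value is at most
    ``max_corrected_p`` (both boundaries inclusive)."""
    mask = (table["path_fraction"] >= min_fraction) & (
        table["corrected_p"] <= max_corrected_p
    )
    return table[mask].reset_index(drop=True)
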