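"""TF-TF interaction networks for individual splits.

For a split of interest the top 25 regulators T (by split score) become
nodes; a directed edge t -> g exists when g is itself in T and the binary
association a_{g,t} = 1. To keep the graphs legible, at most 10 outgoing
edges are kept per TF, ranked by numerical binding affinity. Node size
encodes the regulator's total target count in six discrete levels
(breakpoints 2000/4000/6000/8000/10000) and node color its expression
direction versus the reference time (blue up, orange down).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .affinity import FootprintAffinityMatrix
from .associate import TFGeneMatrix
from .genomic_io import ExpressionSeries

__all__ = [
    "TFNetwork",
    "size_level",
    "node_direction",
    "build_split_network",
    "export_graph",
]

SIZE_BREAKPOINTS = (2000, 4000, 6000, 8000, 10_000)

DIRECTION_COLORS = {"up": "blue", "down": "orange", "unchanged": "grey"}


@dataclass
class TFNetwork:
    """Directed TF-TF graph for one split."""

    split_id: str
    nodes: pd.DataFrame  # tf, n_targets, size_level, direction
    edges: pd.DataFrame  # source, target, affinity

    def __post_init__(self) -> None:
        if len(self.nodes) > 25:
            raise ValueError("TF network limited to 25 nodes")
        if not self.edges.empty:
            out_deg = self.edges.groupby("source").size()
            if (out_deg > 10).any():
                raise ValueError("out-degree above 10")
            node_set = set(self.nodes["tf"])
            if not set(self.edges["source"]) <= node_set or not set(
                self.edges["target"]
            ) <= node_set:
                raise ValueError("edge endpoint outside the top-regulator set")


def size_level(n_targets: int) -> int:
    """Map a regulator's total target count to one of six node-size levels.

    Bins are half-open: level 1 covers [0, 2000), level 2 [2000, 4000), ...
    level 6 is everything >= 10000.
    """
    if n_targets < 0:
        raise ValueError("negative target count")
    return int(np.searchsorted(SIZE_BREAKPOINTS, n_targets, side="right")) + 1


def node_direction(
    tf: str,
    expr: ExpressionSeries,
    time_point: str,
    dead_zone: float = 0.1,
) -> str:
    """Expression direction of a TF at ``time_point`` vs the reference time.

    ``|log2FC| < dead_zone`` is reported as "unchanged".
    """
    i = expr.gene_index(tf)
    t = expr.time_points.index(time_point)
    fc = expr.values[i, t] - expr.values[i, expr.reference_index]
    if abs(fc) < dead_zone:
        return "unchanged"
    return "up" if fc > 0 else "down"


def _pair_affinities(
    tf_gene: TFGeneMatrix,
    affinities: FootprintAffinityMatrix | None,
    gene_windows: dict[str, tuple[str, int, int]] | None,
) -> dict[tuple[str, str], float]:
    """Numeric affinity per associated (tf, gene) pair.

    The score is the maximal raw single-footprint affinity among the TF's
    positive footprints inside the gene's window; when footprint-level
    affinities or windows are unavailable, every pair scores 1.0 and edge
    ranking degrades to the alphabetical tie-break.
    """
    pairs: dict[tuple[str, str], float] = {}
    tf_idx, gene_idx = np.nonzero(tf_gene.values)
    if affinities is None or gene_windows is None:
        for i, j in zip(tf_idx, gene_idx):
            pairs[(tf_gene.tfs[i], tf_gene.genes[j])] = 1.0
        return pairs
    col = {tf: c for c, tf in enumerate(affinities.tfs)}
    regions = affinities.regions
    for i, j in zip(tf_idx, gene_idx):
        tf, gene = tf_gene.tfs[i], tf_gene.genes[j]
        chrom, lo, hi = gene_windows[gene]
        best = 0.0
        for ri, r in enumerate(regions):
            if r.chrom == chrom and r.start <= hi and r.end > lo:
                best = max(best, float(affinities.raw[ri, col[tf]]))
        pairs[(tf, gene)] = best
    return pairs


def build_split_network(
    split_scores: pd.DataFrame,
    split_id: str,
    tf_gene: TFGeneMatrix,
    expr: ExpressionSeries,
    affinities: FootprintAffinityMatrix | None = None,
    top_n: int = 25,
    max_edges_per_tf: int = 10,
    rank_before_filter: bool = True,
    dead_zone: float = 0.1,
) -> TFNetwork:
    """Assemble the TF-TF network for one split.

    ``rank_before_filter`` selects the literal edge rule: a TF's targets
    are ranked by affinity across *all* its target genes, the 10 best kept,
    and only then restricted to the top-regulator set; the alternative
    restricts first and then takes the 10 best within the set.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    sub = split_scores[split_scores["split_id"] == split_id]
    if sub.empty:
        raise ValueError(f"no scores for split {split_id!r}")
    best = (
        sub.groupby("tf")["drem_score"].max().reset_index()
        .sort_values(["drem_score", "tf"], ascending=[False, True])
    )
    top = best["tf"].head(top_n).tolist()
    missing = [t for t in top if t not in tf_gene.tfs]
    if missing:
        raise ValueError(f"TFs scored but absent from association matrix: {missing}")
    top_set = set(top)
    time_point = str(sub["time_point"].iloc[0])

    gene_windows = None
    if tf_gene.tss_used is not None and tf_gene.window_bp is not None:
        # gene windows are reconstructed from the association matrix itself
        chrom_of: dict[str, str] = {}
        if affinities is not None:
            chroms = {r.chrom for r in affinities.regions}
            only = chroms.pop() if len(chroms) == 1 else None
            chrom_of = {g: only for g in tf_gene.genes} if only else {}
        gene_windows = {
            g: (
                chrom_of.get(g, ""),
                max(0, tss - tf_gene.window_bp),
                tss + tf_gene.window_bp,
            )
            for g, tss in tf_gene.tss_used.items()
        }
    pair_aff = _pair_affinities(tf_gene, affinities, gene_windows)

    node_rows = []
    for tf in top:
        n_targets = len(tf_gene.targets_of(tf))
        direction = (
            node_direction(tf, expr, time_point, dead_zone)
            if tf in expr.gene_ids
            else "unchanged"
        )
        node_rows.append((tf, n_targets, size_level(n_targets), direction))
    nodes = pd.DataFrame(node_rows, columns=["tf", "n_targets", "size_level", "direction"])

    edge_rows = []
    for tf in top:
        targets = tf_gene.targets_of(tf)
        ranked = sorted(
            ((pair_aff.get((tf, g), 0.0), g) for g in targets),
            key=lambda x: (-x[0], x[1]),
        )
        if rank_before_filter:
            kept = [g for _, g in ranked[:max_edges_per_tf] if g in top_set]
        else:
            in_set = [(a, g) for a, g in ranked if g in top_set]
            kept = [g for _, g in in_set[:max_edges_per_tf]]
        for g in kept:
            edge_rows.append((tf, g, pair_aff.get((tf, g), 0.0)))
    edges = pd.DataFrame(edge_rows, columns=["source", "target", "affinity"])
    return TFNetwork(split_id=split_id, nodes=nodes, edges=edges)


def to_networkx(net: TFNetwork) -> nx.DiGraph:
    g = nx.DiGraph(split_id=net.split_id)
    for row in net.nodes.itertuples(index=False):
        g.add_node(
            row.tf,
            n_targets=int(row.n_targets),
            size_level=int(row.size_level),
            direction=row.direction,
            fillcolor=DIRECTION_COLORS[row.direction],
        )
    for row in net.edges.itertuples(index=False):
        g.add_edge(row.source, row.target, affinity=float(row.affinity))
    return g


def export_graph(net: TFNetwork, path: str | Path, format: str = "DOT") -> None:
    """Write the network as Graphviz DOT (neato layout) or GraphML."""
    fmt = format.upper()
    if fmt == "GRAPHML":
        nx.write_graphml(to_networkx(net), path)
        return
    if fmt != "DOT":
        raise ValueError(f"unknown export format {format!r}")
    with open(path, "w") as fh:
        fh.write("digraph tf_network {\n")
        fh.write("  layout=neato;\n")
        fh.write("  node [style=filled, shape=circle];\n")
        for row in net.nodes.itertuples(index=False):
            width = 0.4 + 0.2 * (int(row.size_level) - 1)
            fh.write(
                f'  "{row.tf}" [width={width:.2f}, size_level={int(row.size_level)}, '
                f'fillcolor={DIRECTION_COLORS[row.direction]}];\n'
            )
        for row in net.edges.itertuples(index=False):
            fh.write(f'  "{row.source}" -> "{row.target}" [weight={row.affinity:.4g}];\n')
        fh.write("}\n")
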