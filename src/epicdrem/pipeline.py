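"""End-to-end pipeline: footprint affinities -> empirical thresholds ->
TF-gene association -> temporal GRN and regulator ranking, with the SE
dynamics branch alongside.

Every stage writes plain TSV/BED/JSON outputs into the run directory and a
completed stage is skipped on rerun (its outputs already exist) unless
``force`` is set, so a crashed run resumes where it stopped and every
intermediate stays inspectable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import associate as assoc_mod
from . import background as bg_mod
from . import grn as grn_mod
from . import networks as net_mod
from . import se_dynamics as se_mod
from .affinity import TrapParameters, score_footprints
from .genomic_io import (
    read_bedgraph,
    read_expression,
    read_fasta,
    read_pwms,
    read_regions,
    read_tss_table,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run.

    ``footprints``, ``se_calls`` and ``coverage`` map time-point labels to
    file paths; defaults mirror the standard analysis parameters (empirical
    P-value 0.05, +/-50 kb association window, 25-node networks with <= 10
    edges per TF, >= 10 kb SEs, unit change bound 2, dynamic cutoff 1.0
    log2 units, +/-500 kb target search).
    """

    genome: str
    pwms: str
    tss: str
    expression: str
    footprints: dict[str, str]
    se_calls: dict[str, str] = field(default_factory=dict)
    coverage: dict[str, str] = field(default_factory=dict)
    library_sizes: str | None = None
    out_dir: str = "epicdrem_run"
    p_value: float = 0.05
    window_bp: int = 50_000
    n_states: int = 4
    min_path_genes: int = 20
    top_n: int = 25
    max_edges_per_tf: int = 10
    se_min_width: int = 10_000
    max_unit_change: int = 2
    min_abs_change: float = 1.0
    target_window: int = 500_000
    per_footprint_samples: int = 10
    gc_bin_width: float = 0.05
    seed: int = 0
    lambda_: float = 0.7

    def __post_init__(self) -> None:
        if not 0 < self.p_value < 1:
            raise ValueError("p_value must be in (0, 1)")
        if self.window_bp < 0 or self.target_window < 0:
            raise ValueError("windows must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _stage_done(paths: list[Path]) -> bool:
    return all(p.exists() for p in paths)


def run_pipeline(config: PipelineConfig, force: bool = False) -> Path:
    """Execute all stages in dependency order; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    handler = logging.FileHandler(out / "pipeline.log")
    logger.addHandler(handler)
    try:
        return _run(config, out, force)
    except Exception as exc:
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)


def _run(config: PipelineConfig, out: Path, force: bool) -> Path:
    genome = read_fasta(config.genome)
    pwms = read_pwms(config.pwms)
    genes = read_tss_table(config.tss)
    expr = read_expression(config.expression)
    params = TrapParameters(lambda_=config.lambda_)
    time_points = [tp for tp in expr.time_points if tp in config.footprints]
    if not time_points:
        raise ValueError("no footprint file matches any expression time point")

    # --- affinity + threshold + association, per time point -----------------
    matrices: dict[str, assoc_mod.TFGeneMatrix] = {}
    assoc_paths = {tp: out / f"associations_{tp}.tsv" for tp in time_points}
    for tp in time_points:
        apath = assoc_paths[tp]
        if apath.exists() and not force:
            logger.info("stage associate[%s]: output exists, skipping", tp)
            df = pd.read_csv(apath, sep="\t")
            matrices[tp] = assoc_mod.TFGeneMatrix.from_long_frame(
                df, [p.tf_name for p in pwms], [g.gene_id for g in genes], tp
            )
            continue
        logger.info("stage affinity[%s]", tp)
        footprints = read_regions(config.footprints[tp])
        aff = score_footprints(pwms, footprints, genome, params=params, time_point=tp)
        aff_df = pd.DataFrame(aff.normalized, columns=aff.tfs)
        aff_df.insert(0, "region", [r.id or f"fp{i}" for i, r in enumerate(aff.regions)])
        aff_df.to_csv(out / f"affinities_{tp}.tsv", sep="\t", index=False)
        logger.info("stage threshold[%s]", tp)
        bg = bg_mod.sample_matched_background(
            footprints,
            genome,
            per_footprint_samples=config.per_footprint_samples,
            gc_bin_width=config.gc_bin_width,
            seed=config.seed,
        )
        bg_aff = score_footprints(pwms, bg.regions, genome, params=params)
        thresholds = bg_mod.empirical_threshold(
            {tf: bg_aff.tf_column(tf) for tf in bg_aff.tfs}, p=config.p_value
        )
        pd.Series(thresholds.thresholds, name="threshold").rename_axis("tf").to_csv(
            out / f"thresholds_{tp}.tsv", sep="\t"
        )
        binary = bg_mod.binarize_affinities(aff, thresholds)
        logger.info("stage associate[%s]", tp)
        matrices[tp] = assoc_mod.associate_tf_genes(
            binary, genes, window_bp=config.window_bp
        )
        matrices[tp].to_long_frame().to_csv(apath, sep="\t", index=False)

    # --- temporal GRN --------------------------------------------------------
    grn_paths = [out / "path_assignments.tsv", out / "split_scores.tsv",
                 out / "regulator_ranking.tsv", out / "grn_edges.tsv"]
    if _stage_done(grn_paths) and not force:
        logger.info("stage grn: outputs exist, skipping")
        scores = pd.read_csv(grn_paths[1], sep="\t")
    else:
        logger.info("stage grn")
        tree = grn_mod.build_path_tree(
            expr, n_states=config.n_states,
            min_path_genes=config.min_path_genes, seed=config.seed,
        )
        tree.assignments().to_csv(grn_paths[0], sep="\t", index=False)
        scores = grn_mod.score_tree(tree, matrices)
        scores.to_csv(grn_paths[1], sep="\t", index=False)
        aggs = []
        for tp in scores["time_point"].unique():
            aggs.append(grn_mod.aggregate_fisher(scores, tp))
        ranking = pd.concat(aggs, ignore_index=True) if aggs else pd.DataFrame(
            columns=["tf", "time_point", "X", "s", "rank"]
        )
        ranking.to_csv(grn_paths[2], sep="\t", index=False)
        edges = []
        for tp, m in matrices.items():
            long = m.to_long_frame()
            edges.append(long)
        pd.concat(edges, ignore_index=True).to_csv(grn_paths[3], sep="\t", index=False)

    # --- TF-TF networks per split -------------------------------------------
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    if not scores.empty:
        for split_id in scores["split_id"].unique():
            dot = net_dir / f"{split_id}.dot"
            if dot.exists() and not force:
                continue
            tp = str(scores.loc[scores["split_id"] == split_id, "time_point"].iloc[0])
            net = net_mod.build_split_network(
                scores, split_id, matrices[_nearest(tp, list(matrices))], expr,
                top_n=config.top_n, max_edges_per_tf=config.max_edges_per_tf,
            )
            net_mod.export_graph(net, dot, "DOT")
            net_mod.export_graph(net, net_dir / f"{split_id}.graphml", "GraphML")

    # --- SE dynamics branch ---------------------------------------------------
    se_table_path = out / "merged_se.tsv"
    if config.se_calls and config.coverage and (force or not se_table_path.exists()):
        logger.info("stage se-dynamics")
        se_sets = [read_regions(p) for p in config.se_calls.values()]
        merged = se_mod.merge_se_calls(se_sets, min_width=config.se_min_width)
        coverage = {tp: read_bedgraph(p) for tp, p in config.coverage.items()}
        if config.library_sizes:
            lib = (
                pd.read_csv(config.library_sizes, sep="\t", index_col=0)
                .iloc[:, 0].to_dict()
            )
            lib = {str(k): float(v) for k, v in lib.items()}
        else:
            lib = {tp: 1e7 for tp in coverage}
        se_tps = [tp for tp in expr.time_points if tp in coverage]
        merged = se_mod.quantify_merged_se(merged, coverage, lib)
        merged = se_mod.relative_profiles(merged, reference_time=se_tps[0])
        merged = se_mod.classify_dynamic(merged, min_abs=config.min_abs_change)
        if len(se_tps) >= 3:
            se_mod.stem_assign(
                merged, se_tps, max_unit_change=config.max_unit_change,
                min_abs_change=config.min_abs_change, seed=config.seed,
            )
            se_mod.assign_se_targets(
                merged, expr, genes, max_distance=config.target_window,
                time_points=se_tps,
            )
        se_mod.merged_se_table(merged, se_tps).to_csv(
            se_table_path, sep="\t", index=False
        )

    with open(out / "run_config.json", "w") as fh:
        json.dump({k: str(v) for k, v in vars(config).items()}, fh, indent=1)
    return out


def _nearest(tp: str, available: list[str]) -> str:
    return tp if tp in available else available[-1]
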