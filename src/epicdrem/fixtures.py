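"""Synthetic input generators: toy genome, motifs, footprints with planted
binding sites, expression time courses with planted regulator structure,
and a super-enhancer landscape with designated target genes.

Everything the pipeline consumes can be produced here at desk scale,
deterministically for a fixed seed, together with truth tables recording
what was planted. The generators emulate a two-lineage, multi-time-point
differentiation study: chromatin footprints whose motif content drives TF
affinity, genes whose expression diverges into paths at a bifurcation time,
a regulator whose targets concentrate on one path, and broad enhancer
regions whose coverage tracks a target gene's expression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .associate import TFGeneMatrix
from .genomic_io import (
    ExpressionSeries,
    GeneAnnotation,
    GenomicRegion,
    PWM,
    write_expression,
    write_fasta,
    write_regions,
    write_tss_table,
)
from .genomic_io import write_pwms_jaspar

__all__ = [
    "FixtureSpec",
    "generate_genome",
    "generate_pwms",
    "make_gene_annotations",
    "plant_footprints",
    "simulate_expression",
    "simulate_associations",
    "simulate_se_landscape",
    "write_fixtures",
]

_BASES = np.array(list("ACGT"))


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study.

    Defaults describe the standard desk-scale fixture: a 1 Mb genome, 10
    TFs with 8 bp motifs, 500 genes over 6 time points, one regulator
    planted on the upregulated path with a 3 log2FC effect and 60% target
    coverage, per-gene noise of 0.1 log2 units, and 40 super-enhancers of
    10-30 kb.
    """

    seed: int = 0
    genome_length: int = 1_000_000
    gc_content: float = 0.5
    n_tfs: int = 10
    motif_length: int = 8
    n_genes: int = 500
    n_time_points: int = 6
    n_footprints: int = 300
    footprint_width: tuple[int, int] = (40, 80)
    planted_fraction: float = 0.5
    copies_per_planted: int = 2
    planted_regulators: dict[str, tuple[str, float, float]] = field(
        default_factory=lambda: {"TF0": ("up", 3.0, 0.6)}
    )
    split_time_index: int = 1
    noise_sd: float = 0.1
    background_assoc_rate: float = 0.1
    n_se: int = 40
    se_width_range: tuple[int, int] = (10_000, 20_000)
    se_noise_sd: float = 0.2
    se_base_coverage: float = 2.0
    library_size: float = 1e7

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError(f"gc_content must be in (0, 1), got {self.gc_content}")
        for name in ("genome_length", "n_tfs", "motif_length", "n_genes",
                     "n_time_points", "n_footprints", "n_se"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or self.se_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        for tf, (_, effect, fraction) in self.planted_regulators.items():
            if not 0 < fraction <= 1:
                raise ValueError(f"target_fraction for {tf} must be in (0, 1]")

    @property
    def time_points(self) -> list[str]:
        return [f"T{i}" for i in range(self.n_time_points)]

    @property
    def tf_names(self) -> list[str]:
        return [f"TF{i}" for i in range(self.n_tfs)]


def generate_genome(spec: FixtureSpec, chrom: str = "chr1") -> dict[str, str]:
    """An i.i.d. random genome at the requested GC content."""
    if spec.genome_length < 1000:
        raise ValueError("genome_length must be >= 1000")
    rng = np.random.default_rng(spec.seed)
    p_gc = spec.gc_content / 2
    p_at = (1 - spec.gc_content) / 2
    bases = rng.choice(_BASES, size=spec.genome_length, p=[p_at, p_gc, p_gc, p_at])
    return {chrom: "".join(bases)}


def generate_pwms(
    spec: FixtureSpec, consensus_prob: float = 0.85, pseudocount: float = 0.01
) -> list[PWM]:
    """Informative PWMs around random consensus sequences.

    Each position gives ``consensus_prob`` to the consensus base and splits
    the remainder evenly — strong enough that planted consensus copies
    dominate the affinity of a footprint.
    """
    rng = np.random.default_rng(spec.seed + 1)
    pwms = []
    off = (1 - consensus_prob) / 3
    for name in spec.tf_names:
        consensus = rng.integers(0, 4, size=spec.motif_length)
        matrix = np.full((spec.motif_length, 4), off)
        matrix[np.arange(spec.motif_length), consensus] = consensus_prob
        pwms.append(PWM(name, matrix, pseudocount))
    return pwms


def make_gene_annotations(
    spec: FixtureSpec, chrom: str = "chr1", margin: int = 2_000
) -> list[GeneAnnotation]:
    """Random single-TSS genes spread over the genome, alternating strands."""
    rng = np.random.default_rng(spec.seed + 2)
    positions = np.sort(
        rng.choice(
            np.arange(margin, spec.genome_length - margin),
            size=spec.n_genes,
            replace=False,
        )
    )
    return [
        GeneAnnotation(f"gene{i}", chrom, "+" if i % 2 == 0 else "-", (int(pos),))
        for i, pos in enumerate(positions)
    ]


def plant_footprints(
    spec: FixtureSpec, genome: dict[str, str], pwms: list[PWM]
) -> tuple[dict[str, str], dict[str, list[GenomicRegion]], pd.DataFrame]:
    """Place footprints per time point and plant motif copies in a fraction.

    Returns a modified genome (consensus copies written into planted
    footprints), one footprint list per time point, and a truth table with
    one row per (time_point, footprint, tf) stating whether that TF's
    consensus was planted there.
    """
    chrom = next(iter(genome))
    seq = list(genome[chrom])
    rng = np.random.default_rng(spec.seed + 3)
    lo_w, hi_w = spec.footprint_width
    if spec.n_footprints * hi_w > spec.genome_length:
        raise ValueError("footprint count x width exceeds the genome")
    consensus = {p.tf_name: p.consensus for p in pwms}
    footprints: dict[str, list[GenomicRegion]] = {}
    truth_rows = []
    for tp in spec.time_points:
        regions = []
        starts = np.sort(
            rng.choice(
                np.arange(0, spec.genome_length - hi_w, hi_w * 2),
                size=spec.n_footprints,
                replace=False,
            )
        )
        for fi, start in enumerate(starts):
            width = int(rng.integers(lo_w, hi_w + 1))
            region = GenomicRegion(chrom, int(start), int(start) + width, id=f"{tp}_fp{fi}")
            regions.append(region)
            planted_tf = None
            if rng.random() < spec.planted_fraction:
                planted_tf = spec.tf_names[int(rng.integers(0, spec.n_tfs))]
                motif = consensus[planted_tf]
                for _ in range(spec.copies_per_planted):
                    pos = int(rng.integers(region.start, region.end - len(motif)))
                    seq[pos : pos + len(motif)] = list(motif)
            for tf in spec.tf_names:
                truth_rows.append((tp, region.id, tf, tf == planted_tf))
        footprints[tp] = regions
    truth = pd.DataFrame(truth_rows, columns=["time_point", "footprint", "tf", "planted"])
    return {chrom: "".join(seq)}, footprints, truth


def simulate_expression(
    spec: FixtureSpec, seed: int | None = None
) -> tuple[ExpressionSeries, pd.DataFrame, dict[str, set[str]]]:
    """Expression time course with two diverging paths and planted targets.

    Genes split evenly into an "up" and a "down" group whose log2
    expression diverges by +/- effect from ``split_time_index`` onward,
    plus i.i.d. Gaussian noise. Each planted regulator's target set is a
    ``target_fraction`` sample of its path's genes, topped up with a
    ``background_assoc_rate`` sample of all genes (regulators bind outside
    their signature path too). Returns the series, a gene->path truth
    table, and the regulator target sets.
    """
    if spec.n_time_points < 3:
        raise ValueError("need >= 3 time points")
    rng = np.random.default_rng(spec.seed + 4 if seed is None else seed)
    genes = [f"gene{i}" for i in range(spec.n_genes)]
    half = spec.n_genes // 2
    perm = rng.permutation(spec.n_genes)
    groups = np.empty(spec.n_genes, dtype=object)
    groups[perm[:half]] = "up"
    groups[perm[half:]] = "down"
    effect = next(iter(spec.planted_regulators.values()))[1] if spec.planted_regulators else 3.0
    if effect == 0 and spec.noise_sd == 0:
        import warnings

        warnings.warn("zero effect size with zero noise: degenerate expression")
    baseline = 5.0
    values = np.full((spec.n_genes, spec.n_time_points), baseline)
    for t in range(spec.split_time_index, spec.n_time_points):
        values[groups == "up", t] += effect
        values[groups == "down", t] -= effect
    values += rng.normal(0, spec.noise_sd, size=values.shape)
    expr = ExpressionSeries(
        gene_ids=genes,
        time_points=spec.time_points,
        values=values,
        reference_time=spec.time_points[0],
    )
    truth = pd.DataFrame({"gene": genes, "path": groups})
    targets: dict[str, set[str]] = {}
    for tf, (path_label, _, fraction) in spec.planted_regulators.items():
        path_genes = [g for g, grp in zip(genes, groups) if grp == path_label]
        n_core = max(1, int(round(fraction * len(path_genes))))
        core = set(rng.choice(path_genes, size=n_core, replace=False))
        extra_mask = rng.random(spec.n_genes) < spec.background_assoc_rate
        targets[tf] = core | {g for g, m in zip(genes, extra_mask) if m}
    return expr, truth, targets


def simulate_associations(
    spec: FixtureSpec,
    regulator_targets: dict[str, set[str]],
    seed: int | None = None,
) -> dict[str, TFGeneMatrix]:
    """Binary TF-gene matrices per time point from the planted truth.

    Planted regulators get their truth target sets; the remaining (decoy)
    TFs target a ``background_assoc_rate`` random sample of genes. The
    same matrix is emitted at every time point — binding in this fixture
    is constitutive, only expression carries the temporal signal.
    """
    rng = np.random.default_rng(spec.seed + 5 if seed is None else seed)
    genes = [f"gene{i}" for i in range(spec.n_genes)]
    gene_pos = {g: j for j, g in enumerate(genes)}
    values = np.zeros((spec.n_tfs, spec.n_genes), dtype=np.int8)
    for i, tf in enumerate(spec.tf_names):
        if tf in regulator_targets:
            for g in regulator_targets[tf]:
                values[i, gene_pos[g]] = 1
        else:
            mask = rng.random(spec.n_genes) < spec.background_assoc_rate
            values[i, mask] = 1
    return {
        tp: TFGeneMatrix(
            tfs=list(spec.tf_names), genes=genes, values=values.copy(), time_point=tp
        )
        for tp in spec.time_points
    }


def simulate_se_landscape(
    spec: FixtureSpec,
    expr: ExpressionSeries,
    genes: list[GeneAnnotation],
    seed: int | None = None,
    max_target_distance: int = 200_000,
) -> tuple[
    dict[str, list[GenomicRegion]],
    dict[str, dict[str, np.ndarray]],
    dict[str, float],
    pd.DataFrame,
]:
    """Super-enhancer calls, coverage tracks and library sizes.

    The genome is partitioned into ``n_se`` equal slots and each SE is
    jittered inside its own slot (keeping merged SEs disjoint, so the
    planted truth stays unambiguous); its designated target is a random
    gene with a TSS within ``max_target_distance`` of the span, falling
    back to the nearest gene. Coverage at time t is
    ``base * 2^(target log2FC at t + noise)``, constant over the span, so
    the SE's normalized log2FC profile tracks the target gene's expression
    profile up to N(0, se_noise_sd) noise. Returns per-time-point SE call
    lists, bedGraph-style tracks, library sizes and a truth table (se_id,
    target gene).
    """
    rng = np.random.default_rng(spec.seed + 6 if seed is None else seed)
    chrom = genes[0].chrom
    lo_w, hi_w = spec.se_width_range
    slot = spec.genome_length // spec.n_se
    if hi_w >= slot:
        raise ValueError(
            f"SE width up to {hi_w} cannot fit {spec.n_se} disjoint SEs in a "
            f"{spec.genome_length} bp genome (slot {slot} bp)"
        )
    log2fc = expr.log2fc_vs_reference()
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    tss_arr = np.array([g.tss_list[0] for g in genes])
    se_regions: list[GenomicRegion] = []
    truth_rows = []
    for si in range(spec.n_se):
        width = int(rng.integers(lo_w, hi_w + 1))
        start = si * slot + int(rng.integers(0, slot - width))
        end = start + width
        dist = np.where(
            (tss_arr >= start) & (tss_arr < end),
            0,
            np.minimum(np.abs(tss_arr - start), np.abs(tss_arr - end)),
        )
        near = np.flatnonzero(dist <= max_target_distance)
        gi = int(rng.choice(near)) if near.size else int(np.argmin(dist))
        se_regions.append(GenomicRegion(chrom, start, end, id=f"se{si}"))
        truth_rows.append((f"se{si}", genes[gi].gene_id, start, end))
    truth = pd.DataFrame(truth_rows, columns=["se_id", "target_gene", "start", "end"])

    se_calls: dict[str, list[GenomicRegion]] = {}
    coverage: dict[str, dict[str, np.ndarray]] = {}
    library_sizes: dict[str, float] = {}
    for t, tp in enumerate(expr.time_points):
        calls = []
        starts, ends, values = [], [], []
        for si, region in enumerate(se_regions):
            gi = gene_pos[truth.loc[si, "target_gene"]]
            fc = log2fc[gi, t] + rng.normal(0, spec.se_noise_sd)
            cov = spec.se_base_coverage * 2.0**fc
            calls.append(region)
            starts.append(region.start)
            ends.append(region.end)
            values.append(cov)
        order = np.argsort(starts)
        coverage[tp] = {
            chrom: np.array(
                [np.array(starts)[order], np.array(ends)[order], np.array(values)[order]],
                dtype=float,
            )
        }
        se_calls[tp] = calls
        library_sizes[tp] = spec.library_size
    return se_calls, coverage, library_sizes, truth


def write_fixtures(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate the full fixture set and write it to ``outdir``.

    Emits genome FASTA, per-time-point footprint BEDs, PWMs (JASPAR text),
    TSS table, expression TSV, SE BEDs and bedGraphs, library-size TSV and
    a truth JSON; returns the path of every artifact.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(spec)
    pwms = generate_pwms(spec)
    genome, footprints, fp_truth = plant_footprints(spec, genome, pwms)
    genes = make_gene_annotations(spec)
    expr, path_truth, targets = simulate_expression(spec)
    se_calls, coverage, library_sizes, se_truth = simulate_se_landscape(spec, expr, genes)

    paths: dict[str, Path] = {}
    paths["genome"] = out / "genome.fa"
    write_fasta(genome, paths["genome"])
    paths["pwms"] = out / "pwms.jaspar"
    write_pwms_jaspar(pwms, paths["pwms"])
    paths["tss"] = out / "tss.tsv"
    write_tss_table(genes, paths["tss"])
    paths["expression"] = out / "expression.tsv"
    write_expression(expr, paths["expression"])
    for tp in spec.time_points:
        p = out / f"footprints_{tp}.bed"
        write_regions(footprints[tp], p)
        paths[f"footprints_{tp}"] = p
        p = out / f"se_{tp}.bed"
        write_regions(se_calls[tp], p)
        paths[f"se_{tp}"] = p
        p = out / f"coverage_{tp}.bedgraph"
        with open(p, "w") as fh:
            for chrom, arr in coverage[tp].items():
                for s, e, v in arr.T:
                    fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:.6g}\n")
        paths[f"coverage_{tp}"] = p
    paths["library_sizes"] = out / "library_sizes.tsv"
    pd.Series(library_sizes, name="library_size").rename_axis("time_point").to_csv(
        paths["library_sizes"], sep="\t"
    )
    paths["truth"] = out / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "footprints": fp_truth.to_dict(orient="records"),
                "paths": path_truth.to_dict(orient="records"),
                "regulator_targets": {tf: sorted(t) for tf, t in targets.items()},
                "se_targets": se_truth.to_dict(orient="records"),
            },
            fh,
            indent=1,
        )
    return paths
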