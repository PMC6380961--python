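"""Time-point-specific binary TF-gene association matrices.

A gene is associated with a TF at a time point when at least one
binarized-positive footprint for that TF overlaps a window around the
gene's 5'-most TSS (default +/- 50 kb). Two baselines accompany the
footprint-driven matrix: a promoter-only variant that scores a 2 kb window
around the TSS directly from sequence (no chromatin information), and a
column-shuffle control that destroys the TF-gene-time mapping while
preserving all marginal counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .affinity import TrapParameters, score_footprints
from .background import (
    BinaryAffinityMatrix,
    binarize_affinities,
    empirical_threshold,
    sample_matched_background,
)
from .genomic_io import GeneAnnotation, GenomicRegion, PWM

__all__ = [
    "TFGeneMatrix",
    "select_primary_tss",
    "associate_tf_genes",
    "promoter_window_associations",
    "shuffle_association_matrix",
]


@dataclass
class TFGeneMatrix:
    """Binary TF x gene association matrix for one time point."""

    tfs: list[str]
    genes: list[str]
    values: np.ndarray
    time_point: str | None = None
    window_bp: int | None = None
    tss_used: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.tfs), len(self.genes)):
            raise ValueError("TF-gene matrix shape mismatch")
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            raise ValueError("TF-gene matrix must be binary")

    def targets_of(self, tf: str) -> set[str]:
        i = self.tfs.index(tf)
        return {g for g, v in zip(self.genes, self.values[i]) if v}

    def to_long_frame(self) -> pd.DataFrame:
        """Long-form (tf, gene, association, time_point) records — the
        4-column shape consumed by the shuffle control and written to disk."""
        tf_idx, gene_idx = np.nonzero(self.values)
        return pd.DataFrame(
            {
                "tf": [self.tfs[i] for i in tf_idx],
                "gene": [self.genes[j] for j in gene_idx],
                "association": 1,
                "time_point": self.time_point,
            }
        )

    @classmethod
    def from_long_frame(
        cls,
        records: pd.DataFrame,
        tfs: list[str],
        genes: list[str],
        time_point: str | None = None,
    ) -> "TFGeneMatrix":
        sub = records
        if time_point is not None and "time_point" in records.columns:
            sub = records[records["time_point"].astype(str) == str(time_point)]
        values = np.zeros((len(tfs), len(genes)), dtype=np.int8)
        tf_pos = {t: i for i, t in enumerate(tfs)}
        gene_pos = {g: j for j, g in enumerate(genes)}
        for tf, gene, assoc in zip(sub["tf"], sub["gene"], sub["association"]):
            if assoc and tf in tf_pos and gene in gene_pos:
                values[tf_pos[tf], gene_pos[gene]] = 1
        return cls(tfs=tfs, genes=genes, values=values, time_point=time_point)


def select_primary_tss(gene: GeneAnnotation) -> int:
    """The gene's 5'-most TSS: minimum coordinate on '+', maximum on '-'."""
    if gene.strand == "+":
        return min(gene.tss_list)
    if gene.strand == "-":
        return max(gene.tss_list)
    raise ValueError(f"gene {gene.gene_id}: strand must be '+' or '-'")


def _window(tss: int, half_width: int) -> tuple[int, int]:
    # closed window [tss - w, tss + w], clipped at the chromosome start
    return max(0, tss - half_width), tss + half_width


def associate_tf_genes(
    binary: BinaryAffinityMatrix,
    genes: list[GeneAnnotation],
    window_bp: int = 50_000,
    expressed_tfs: set[str] | None = None,
) -> TFGeneMatrix:
    """Overlap binarized footprints with TSS windows.

    ``window_bp`` is the half-width w: the window is ``[tss - w, tss + w]``
    and any >= 1 bp overlap with a positive footprint associates the gene
    with the footprint's TF. Genes whose windows contain no positive
    footprint get all-zero columns. ``expressed_tfs``, when given, restricts
    the TF rows to TFs expressed at this time point.
    """
    if window_bp < 0:
        raise ValueError(f"window_bp must be non-negative, got {window_bp}")
    tfs = list(binary.tfs)
    tf_rows = np.arange(len(tfs))
    if expressed_tfs is not None:
        keep = [i for i, t in enumerate(tfs) if t in expressed_tfs]
        tfs = [tfs[i] for i in keep]
        tf_rows = np.array(keep, dtype=int)

    # index positive footprints per chromosome, sorted by start
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {r.chrom for r in binary.regions}:
        idx = [i for i, r in enumerate(binary.regions) if r.chrom == chrom]
        idx.sort(key=lambda i: binary.regions[i].start)
        starts = np.array([binary.regions[i].start for i in idx], dtype=np.int64)
        ends = np.array([binary.regions[i].end for i in idx], dtype=np.int64)
        by_chrom[chrom] = (starts, ends, np.array(idx, dtype=int))

    values = np.zeros((len(tfs), len(genes)), dtype=np.int8)
    tss_used: dict[str, int] = {}
    for j, gene in enumerate(genes):
        tss = select_primary_tss(gene)
        tss_used[gene.gene_id] = tss
        lo, hi = _window(tss, window_bp)
        entry = by_chrom.get(gene.chrom)
        if entry is None:
            continue
        starts, ends, idx = entry
        # closed window [lo, hi] vs half-open region [s, e): overlap iff
        # s <= hi and e > lo
        first = np.searchsorted(starts, hi, side="right")
        cand = idx[:first][ends[:first] > lo]
        if cand.size:
            hit = binary.values[np.ix_(cand, tf_rows)].any(axis=0)
            values[:, j] = hit.astype(np.int8)
    return TFGeneMatrix(
        tfs=tfs,
        genes=[g.gene_id for g in genes],
        values=values,
        time_point=binary.time_point,
        window_bp=window_bp,
        tss_used=tss_used,
    )


def promoter_window_associations(
    pwms: list[PWM],
    genes: list[GeneAnnotation],
    genome: dict[str, str],
    window_total_bp: int = 2_000,
    p: float = 0.05,
    per_promoter_samples: int = 10,
    seed: int = 0,
    params: TrapParameters = TrapParameters(),
) -> TFGeneMatrix:
    """Promoter-only association baseline.

    Affinities are computed directly on the ``window_total_bp`` window
    centered on each gene's 5'-most TSS — no footprints, hence no chromatin
    time-dependence — then thresholded against a GC/length-matched random
    background with the same empirical P-value scheme and binarized. The
    result is a single time-invariant TF-gene matrix.
    """
    if window_total_bp <= 0:
        raise ValueError("window_total_bp must be positive")
    if not genes:
        return TFGeneMatrix(tfs=[p_.tf_name for p_ in pwms], genes=[], values=np.zeros((len(pwms), 0), dtype=np.int8))
    half = window_total_bp // 2
    promoters = []
    kept_genes = []
    for gene in genes:
        tss = select_primary_tss(gene)
        lo = max(0, tss - half)
        hi = min(len(genome[gene.chrom]), tss + half)
        if hi - lo < window_total_bp // 4:
            continue  # TSS too close to a contig edge to carry a promoter
        promoters.append(GenomicRegion(gene.chrom, lo, hi, id=gene.gene_id))
        kept_genes.append(gene.gene_id)
    aff = score_footprints(pwms, promoters, genome, params=params)
    # the threshold estimator needs >= 20 background values per TF
    samples = max(per_promoter_samples, -(-20 // len(promoters)))
    bg = sample_matched_background(
        promoters,
        genome,
        per_footprint_samples=samples,
        seed=seed,
        exclude_footprints=False,
        label="promoters",
    )
    bg_aff = score_footprints(pwms, bg.regions, genome, params=params)
    thresholds = empirical_threshold(
        {tf: bg_aff.tf_column(tf) for tf in bg_aff.tfs}, p=p
    )
    binary = binarize_affinities(aff, thresholds)
    values = binary.values.T.astype(np.int8)  # promoters x TFs -> TFs x genes
    return TFGeneMatrix(
        tfs=list(binary.tfs),
        genes=kept_genes,
        values=values,
        window_bp=half,
    )


def shuffle_association_matrix(records: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Independently permute the tf, gene and time_point columns.

    Each column's multiset of values is preserved; only the mapping between
    them is destroyed. This is the random-assignment control against which
    the footprint-informed network is compared.
    """
    if records.empty:
        raise ValueError("empty association record list")
    rng = np.random.default_rng(seed)
    out = records.reset_index(drop=True).copy()
    n = len(out)
    for col in ("tf", "gene", "time_point"):
        if col in out.columns:
            out[col] = out[col].to_numpy()[rng.permutation(n)]
    return out
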