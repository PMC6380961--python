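"""Merged super-enhancer (SE) profiling over a differentiation time course.

Per-sample SE calls are merged across time points and lineages into
disjoint union spans (any >= 1 bp overlap, book-ended intervals included,
matching bedtools-merge defaults), quantified from per-sample coverage
tracks with library-size normalization, and expressed as log2 fold changes
against the reference time point. An SE is *dynamic* when its signal moves
at least two-fold (|log2FC| >= 1) at some time point. Dynamic SEs are
clustered against a bank of canonical short-time-series model profiles with
bounded unit change per step, and each is assigned a putative target gene:
the gene with a TSS within +/- 500 kb whose expression profile correlates
best with the SE signal profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .associate import select_primary_tss
from .genomic_io import ExpressionSeries, GeneAnnotation, GenomicRegion

__all__ = [
    "MergedSE",
    "ModelProfileSet",
    "merge_se_calls",
    "quantify_merged_se",
    "relative_profiles",
    "classify_dynamic",
    "enumerate_model_profiles",
    "select_representatives",
    "stem_assign",
    "assign_se_targets",
]


@dataclass
class MergedSE:
    """Union span over per-sample SE calls with its temporal signal."""

    region: GenomicRegion
    source_count: int
    signal: dict[str, float] = field(default_factory=dict)
    log2fc: dict[str, float] = field(default_factory=dict)
    dynamic: bool = False
    profile_id: int | None = None
    profile_r: float | None = None
    target_gene: str | None = None
    target_r: float | None = None


@dataclass
class ModelProfileSet:
    """Candidate temporal model profiles and the selected representatives.

    Profiles are cumulative trajectories starting at 0 whose per-step
    change is an integer in [-c, c] with c = ``max_unit_change``; there are
    (2c+1)^(T-1) candidates for T time points.
    """

    profiles: np.ndarray  # n_candidates x T
    representative_ids: list[int]
    max_unit_change: int

    @property
    def representatives(self) -> np.ndarray:
        return self.profiles[self.representative_ids]


def merge_se_calls(
    se_sets: list[list[GenomicRegion]],
    min_width: int | None = None,
) -> list[MergedSE]:
    """Merge SE calls from all samples into disjoint union spans.

    Intervals overlapping by >= 1 bp — or exactly book-ended (end == start)
    — are combined transitively. ``min_width`` drops input calls narrower
    than the given span before merging (SE callers here are expected to
    emit >= 10 kb regions; enforcement is optional).
    """
    calls: list[GenomicRegion] = []
    for se_set in se_sets:
        for r in se_set:
            if min_width is None or r.length >= min_width:
                calls.append(r)
    if not calls:
        return []
    merged: list[MergedSE] = []
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in calls:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        cur_start, cur_end, count = ivs[0].start, ivs[0].end, 1
        for r in ivs[1:]:
            if r.start <= cur_end:  # overlap or book-ended
                cur_end = max(cur_end, r.end)
                count += 1
            else:
                merged.append(
                    MergedSE(GenomicRegion(chrom, cur_start, cur_end), count)
                )
                cur_start, cur_end, count = r.start, r.end, 1
        merged.append(MergedSE(GenomicRegion(chrom, cur_start, cur_end), count))
    return merged


def _coverage_sum(track: dict[str, np.ndarray], region: GenomicRegion) -> float:
    """Sum of per-bp coverage over ``region`` from a bedGraph step function."""
    arr = track.get(region.chrom)
    if arr is None:
        return 0.0
    starts, ends, values = arr
    if (values < 0).any():
        raise ValueError("negative coverage")
    lo = np.clip(starts, region.start, region.end)
    hi = np.clip(ends, region.start, region.end)
    return float(((hi - lo) * values).sum())


def quantify_merged_se(
    merged: list[MergedSE],
    coverage: dict[str, dict[str, np.ndarray]],
    library_sizes: dict[str, float],
    scale: float = 1e7,
) -> list[MergedSE]:
    """Fill in normalized per-time-point signal for every merged SE.

    Signal = sum of per-bp coverage over the full merged span, scaled to a
    fixed library size (``scale`` reads): signal * scale / library_size.
    """
    for tp, track in coverage.items():
        lib = library_sizes[tp]
        if lib <= 0:
            raise ValueError(f"library size for {tp} must be positive")
        for se in merged:
            se.signal[tp] = _coverage_sum(track, se.region) * scale / lib
    return merged


def relative_profiles(
    merged: list[MergedSE], reference_time: str, pseudocount: float = 1.0
) -> list[MergedSE]:
    """log2((s_t + eps) / (s_ref + eps)) per time point, eps guarding zeros."""
    for se in merged:
        if reference_time not in se.signal:
            raise ValueError(f"reference time {reference_time!r} not quantified")
        ref = se.signal[reference_time] + pseudocount
        se.log2fc = {
            tp: float(np.log2((s + pseudocount) / ref)) for tp, s in se.signal.items()
        }
    return merged


def classify_dynamic(merged: list[MergedSE], min_abs: float = 1.0) -> list[MergedSE]:
    """Flag SEs whose |log2FC| reaches ``min_abs`` at some time point.

    The cutoff is direction-agnostic: SEs losing signal over time are as
    dynamic as SEs gaining it (both rising and falling profile classes
    occur in real time courses).
    """
    for se in merged:
        if len(se.log2fc) < 2:
            raise ValueError("need log2fc at >= 2 time points")
        se.dynamic = bool(max(abs(v) for v in se.log2fc.values()) >= min_abs)
    return merged


def enumerate_model_profiles(n_time_points: int, max_unit_change: int = 2) -> np.ndarray:
    """All (2c+1)^(T-1) cumulative profiles with integer steps in [-c, c]."""
    if n_time_points < 3:
        raise ValueError("model profiles need at least 3 time points")
    steps = range(-max_unit_change, max_unit_change + 1)
    combos = np.array(list(product(steps, repeat=n_time_points - 1)), dtype=float)
    profiles = np.concatenate(
        [np.zeros((combos.shape[0], 1)), np.cumsum(combos, axis=1)], axis=1
    )
    return profiles


def _pearson_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pairwise Pearson r between rows of x and rows of y; rows with zero
    variance yield NaN."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xs = np.sqrt((xc**2).sum(axis=1))
    ys = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc.T) / np.outer(xs, ys)
    return r


def select_representatives(
    profiles: np.ndarray, n_representatives: int = 20, seed: int = 0
) -> list[int]:
    """Greedy max-min selection of representative profiles.

    Starting from a seeded random non-constant profile, repeatedly add the
    candidate maximizing its minimum Pearson distance (1 - r) to the
    profiles already chosen. Constant profiles (undefined correlation) are
    excluded from candidacy.
    """
    variable = np.flatnonzero(profiles.std(axis=1) > 0)
    if variable.size == 0:
        raise ValueError("no non-constant candidate profiles")
    rng = np.random.default_rng(seed)
    n_representatives = min(n_representatives, variable.size)
    first = int(rng.choice(variable))
    chosen = [first]
    r = _pearson_matrix(profiles[variable], profiles[chosen])
    min_dist = 1.0 - r[:, 0]
    min_dist[variable == first] = -np.inf
    while len(chosen) < n_representatives:
        order = np.argsort(-min_dist, kind="stable")  # ties -> lower index
        nxt = int(variable[order[0]])
        chosen.append(nxt)
        r_new = _pearson_matrix(profiles[variable], profiles[[nxt]])[:, 0]
        min_dist = np.minimum(min_dist, 1.0 - r_new)
        min_dist[variable == nxt] = -np.inf
    return chosen


def stem_assign(
    merged: list[MergedSE],
    time_points: list[str],
    max_unit_change: int = 2,
    n_representatives: int = 20,
    min_abs_change: float = 1.0,
    seed: int = 0,
) -> ModelProfileSet:
    """Assign each sufficiently changing SE to its best model profile.

    SEs whose maximal |log2FC| stays below ``min_abs_change`` remain
    unassigned. Assignment maximizes Pearson correlation between the SE's
    log2FC profile and each representative; exact ties go to the lower
    profile index.
    """
    if len(time_points) < 3:
        raise ValueError("need at least 3 time points for profile clustering")
    profiles = enumerate_model_profiles(len(time_points), max_unit_change)
    rep_ids = select_representatives(profiles, n_representatives, seed)
    reps = profiles[rep_ids]
    for se in merged:
        vec = np.array([se.log2fc[tp] for tp in time_points])
        if np.max(np.abs(vec)) < min_abs_change or vec.std() == 0:
            se.profile_id = None
            se.profile_r = None
            continue
        r = _pearson_matrix(vec[None, :], reps)[0]
        r = np.where(np.isnan(r), -np.inf, r)
        best = int(np.argmax(r))  # argmax takes the first (lowest) index on ties
        se.profile_id = rep_ids[best]
        se.profile_r = float(r[best])
    return ModelProfileSet(
        profiles=profiles, representative_ids=rep_ids, max_unit_change=max_unit_change
    )


def _distance_to_span(tss: int, region: GenomicRegion) -> int:
    if region.start <= tss < region.end:
        return 0
    return tss - region.end + 1 if tss >= region.end else region.start - tss


def assign_se_targets(
    merged: list[MergedSE],
    expr: ExpressionSeries,
    genes: list[GeneAnnotation],
    max_distance: int = 500_000,
    time_points: list[str] | None = None,
    use_absolute_r: bool = False,
) -> list[MergedSE]:
    """Assign each dynamic SE the best-correlated gene within reach.

    Candidates are genes whose 5'-most TSS lies within ``max_distance`` of
    the merged span's nearest edge (0 inside the span); among them the gene
    maximizing the signed Pearson correlation between the SE log2FC profile
    and the gene's expression profile wins (``use_absolute_r`` switches to
    max |r|). Genes with a constant expression profile are skipped —
    correlation is undefined there. SEs with no candidate keep
    ``target_gene = None``.
    """
    tps = time_points or expr.time_points
    if len(tps) < 3:
        raise ValueError("need >= 3 time points of SE signal")
    t_idx = [expr.time_points.index(t) for t in tps]
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    for se in merged:
        if not se.dynamic:
            continue
        vec = np.array([se.log2fc[tp] for tp in tps])
        best_gene, best_r = None, -np.inf
        for gene in genes:
            if gene.chrom != se.region.chrom or gene.gene_id not in gene_pos:
                continue
            tss = select_primary_tss(gene)
            if _distance_to_span(tss, se.region) > max_distance:
                continue
            prof = expr.values[gene_pos[gene.gene_id], t_idx]
            if prof.std() == 0 or vec.std() == 0:
                continue  # correlation undefined for flat profiles
            r = float(np.corrcoef(vec, prof)[0, 1])
            score = abs(r) if use_absolute_r else r
            if score > best_r or (score == best_r and best_gene and gene.gene_id < best_gene):
                best_gene, best_r = gene.gene_id, score
        se.target_gene = best_gene
        se.target_r = best_r if best_gene is not None else None
    return merged


def merged_se_table(merged: list[MergedSE], time_points: list[str]) -> pd.DataFrame:
    """Flat table of merged SEs: span, signal, dynamics, profile, target."""
    rows = []
    for se in merged:
        row: dict[str, object] = {
            "chrom": se.region.chrom,
            "start": se.region.start,
            "end": se.region.end,
            "source_count": se.source_count,
            "dynamic": se.dynamic,
            "profile_id": se.profile_id,
            "target_gene": se.target_gene,
            "target_r": se.target_r,
        }
        for tp in time_points:
            row[f"signal_{tp}"] = se.signal.get(tp)
            row[f"log2fc_{tp}"] = se.log2fc.get(tp)
        rows.append(row)
    return pd.DataFrame(rows)
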