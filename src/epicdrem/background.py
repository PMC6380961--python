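"""Empirical background model for binarizing TF affinities.

Footprint affinities carry no intrinsic scale, so the cutoff separating
"bound" from "unbound" is derived empirically: random genomic regions
matched to the footprints in length and GC content are scored with the same
occupancy model, and the per-TF threshold is the affinity exceeded by a
fraction ``p`` (default 0.05) of the matched background. Each time point has
its own footprint set and hence its own background and thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .affinity import FootprintAffinityMatrix
from .genomic_io import GenomicRegion

__all__ = [
    "BackgroundSet",
    "ThresholdTable",
    "BinaryAffinityMatrix",
    "sample_matched_background",
    "empirical_threshold",
    "binarize_affinities",
]

logger = logging.getLogger(__name__)


@dataclass
class BackgroundSet:
    """GC/length-matched random regions mirroring a footprint set."""

    regions: list[GenomicRegion]
    matched_to: str
    seed: int
    gc_bin_width: float
    per_footprint_samples: int
    relaxed: list[int] = field(default_factory=list)  # footprint indices that needed a wider GC bin


@dataclass
class ThresholdTable:
    """Per-TF per-bp affinity thresholds at one empirical P-value."""

    thresholds: dict[str, float]
    p_value: float

    def __post_init__(self) -> None:
        for tf, t in self.thresholds.items():
            if t < 0:
                raise ValueError(f"negative threshold for {tf}")

    def __getitem__(self, tf: str) -> float:
        return self.thresholds[tf]


@dataclass
class BinaryAffinityMatrix:
    """Regions x TFs binary occupancy calls (1 iff normalized affinity
    strictly exceeds the TF's threshold)."""

    regions: list[GenomicRegion]
    tfs: list[str]
    values: np.ndarray
    thresholds: ThresholdTable
    time_point: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary matrix must contain only 0/1")


def _gc_prefix(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    out = np.zeros(arr.size + 1, dtype=np.int64)
    np.cumsum(is_gc, out=out[1:])
    return out


def _n_prefix(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_n = arr == ord("N")
    out = np.zeros(arr.size + 1, dtype=np.int64)
    np.cumsum(is_n, out=out[1:])
    return out


def gc_content(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def sample_matched_background(
    footprints: list[GenomicRegion],
    genome: dict[str, str],
    per_footprint_samples: int = 10,
    gc_bin_width: float = 0.05,
    max_tries: int = 1000,
    seed: int = 0,
    exclude_footprints: bool = True,
    label: str = "footprints",
) -> BackgroundSet:
    """Draw random genomic regions matched to each footprint.

    For every footprint, ``per_footprint_samples`` regions of identical
    length are drawn uniformly over N-free genome positions and accepted iff
    their GC content lies within ``gc_bin_width`` of the footprint's. After
    ``max_tries`` rejected draws the GC bin is doubled (and doubling
    repeats if needed), with a logged warning — this keeps degenerate
    genomes (e.g. uniform GC) from stalling the sampler. Background regions
    never overlap any footprint when ``exclude_footprints`` is set.
    """
    if not footprints:
        raise ValueError("footprint set is empty")
    rng = np.random.default_rng(seed)
    chroms = sorted(genome)
    lengths = {c: len(genome[c]) for c in chroms}
    gc_pref = {c: _gc_prefix(genome[c]) for c in chroms}
    n_pref = {c: _n_prefix(genome[c]) for c in chroms}

    # sorted footprint intervals per chromosome for overlap rejection
    fp_by_chrom: dict[str, np.ndarray] = {}
    if exclude_footprints:
        tmp: dict[str, list[tuple[int, int]]] = {}
        for fp in footprints:
            tmp.setdefault(fp.chrom, []).append((fp.start, fp.end))
        fp_by_chrom = {
            c: np.array(sorted(ivs), dtype=np.int64).reshape(-1, 2)
            for c, ivs in tmp.items()
        }

    def overlaps_footprint(chrom: str, start: int, end: int) -> bool:
        ivs = fp_by_chrom.get(chrom)
        if ivs is None or ivs.size == 0:
            return False
        i = np.searchsorted(ivs[:, 0], end)  # footprints starting before `end`
        return bool((ivs[:i, 1] > start).any())

    chrom_weights = np.array([lengths[c] for c in chroms], dtype=float)
    chrom_weights /= chrom_weights.sum()

    regions: list[GenomicRegion] = []
    relaxed: list[int] = []
    for fi, fp in enumerate(footprints):
        if fp.length > max(lengths.values()):
            raise ValueError(
                f"footprint {fp} longer than every chromosome in the genome"
            )
        fp_seq = genome[fp.chrom][fp.start : fp.end]
        fp_gc = gc_content(fp_seq)
        bin_width = gc_bin_width
        accepted = 0
        tries = 0
        while accepted < per_footprint_samples:
            tries += 1
            if tries > max_tries:
                bin_width *= 2
                tries = 0
                if fi not in relaxed:
                    relaxed.append(fi)
                    logger.warning(
                        "background sampling for footprint %d (%s:%d-%d) exceeded "
                        "%d tries; GC bin relaxed to +/-%.3f",
                        fi, fp.chrom, fp.start, fp.end, max_tries, bin_width,
                    )
            ci = rng.choice(len(chroms), p=chrom_weights)
            chrom = chroms[ci]
            span = lengths[chrom] - fp.length
            if span < 0:
                continue
            start = int(rng.integers(0, span + 1))
            end = start + fp.length
            if n_pref[chrom][end] - n_pref[chrom][start] > 0:
                continue
            gc = (gc_pref[chrom][end] - gc_pref[chrom][start]) / fp.length
            if abs(gc - fp_gc) > bin_width:
                continue
            if overlaps_footprint(chrom, start, end):
                continue
            regions.append(
                GenomicRegion(chrom, start, end, id=f"bg_{fi}_{accepted}")
            )
            accepted += 1
    return BackgroundSet(
        regions=regions,
        matched_to=label,
        seed=seed,
        gc_bin_width=gc_bin_width,
        per_footprint_samples=per_footprint_samples,
        relaxed=relaxed,
    )


def empirical_threshold(
    background_affinities: dict[str, np.ndarray], p: float = 0.05
) -> ThresholdTable:
    """Derive per-TF thresholds from background normalized affinities.

    The threshold is the smallest value present in the background data such
    that the fraction of background values *strictly* greater than it is at
    most ``p`` — i.e. the tightest empirically attainable (1-p) cut. With
    ties this errs on the conservative side (fewer exceedances than ``p``).
    """
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0, 1), got {p}")
    thresholds: dict[str, float] = {}
    for tf, values in background_affinities.items():
        v = np.sort(np.asarray(values, dtype=float))
        n = v.size
        if n < 20:
            raise ValueError(
                f"only {n} background values for {tf}; increase "
                "per_footprint_samples to estimate a stable threshold"
            )
        max_exceed = int(np.floor(p * n))
        # v[n-1-max_exceed] is the smallest data value with at most
        # max_exceed strictly greater values; ties only push the strict
        # exceedance count further below p, never above it
        thresholds[tf] = float(v[n - 1 - max_exceed])
    return ThresholdTable(thresholds=thresholds, p_value=p)


def binarize_affinities(
    matrix: FootprintAffinityMatrix, thresholds: ThresholdTable
) -> BinaryAffinityMatrix:
    """Apply per-TF thresholds to normalized affinities (strict ``>``)."""
    missing = [tf for tf in matrix.tfs if tf not in thresholds.thresholds]
    if missing:
        raise ValueError(f"no threshold for TFs: {missing}")
    t = np.array([thresholds[tf] for tf in matrix.tfs])
    values = (matrix.normalized > t[None, :]).astype(np.int8)
    return BinaryAffinityMatrix(
        regions=matrix.regions,
        tfs=list(matrix.tfs),
        values=values,
        thresholds=thresholds,
        time_point=matrix.time_point,
    )
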