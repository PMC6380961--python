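"""Validation statistics for the binding predictions and target calls.

Three independent checks are implemented: (i) a peak-centric
precision/recall evaluation against TF ChIP-seq gold standards, where ChIP
peaks containing a motif hit are positives and the rest negatives; (ii) a
Kolmogorov-Smirnov shift test asking whether predicted targets of a TF
move in expression after a perturbation of that TF; and (iii) a
hypergeometric enrichment of predicted targets in an externally validated
target set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .affinity import FootprintAffinityMatrix
from .background import binarize_affinities, empirical_threshold
from .genomic_io import GenomicRegion, PWM

__all__ = [
    "GoldStandard",
    "EvalCounts",
    "build_gold_standard",
    "precision_recall",
    "pr_threshold_sweep",
    "target_shift_test",
    "target_overlap_enrichment",
    "scan_motif_hits",
]


@dataclass
class GoldStandard:
    """ChIP peaks split into motif-containing positives and the rest."""

    positives: list[GenomicRegion]
    negatives: list[GenomicRegion]
    tf_name: str


@dataclass
class EvalCounts:
    TP: int
    FP: int
    FN: int

    @property
    def PR(self) -> float:
        if self.TP + self.FP == 0:
            warnings.warn("no positive predictions; precision undefined")
            return float("nan")
        return self.TP / (self.TP + self.FP)

    @property
    def REC(self) -> float:
        if self.TP + self.FN == 0:
            return float("nan")
        return self.TP / (self.TP + self.FN)


def _any_overlap(region: GenomicRegion, others: list[GenomicRegion]) -> bool:
    return any(region.overlaps(o) for o in others)


def build_gold_standard(
    chip_peaks: list[GenomicRegion],
    motif_hits: list[GenomicRegion],
    tf_name: str = "",
) -> GoldStandard:
    """Partition ChIP peaks by >= 1 bp overlap with any motif hit."""
    if not chip_peaks:
        raise ValueError("empty ChIP peak set")
    positives, negatives = [], []
    for peak in chip_peaks:
        (positives if _any_overlap(peak, motif_hits) else negatives).append(peak)
    return GoldStandard(positives=positives, negatives=negatives, tf_name=tf_name)


def precision_recall(
    predictions: list[GenomicRegion], gold: GoldStandard
) -> EvalCounts:
    """Peak-centric counts: a prediction overlapping the positive set is a
    TP, one overlapping the negative set an FP (a prediction straddling
    both counts once in each); FN is the number of positives no prediction
    touches. Predictions overlapping neither set count toward neither."""
    if not gold.positives and not gold.negatives:
        raise ValueError("empty gold standard")
    tp = sum(1 for p in predictions if _any_overlap(p, gold.positives))
    fp = sum(1 for p in predictions if _any_overlap(p, gold.negatives))
    fn = sum(1 for pos in gold.positives if not _any_overlap(pos, predictions))
    return EvalCounts(TP=tp, FP=fp, FN=fn)


def pr_threshold_sweep(
    affinities: dict[str, FootprintAffinityMatrix],
    background_affinities: dict[str, dict[str, np.ndarray]],
    gold_standards: dict[str, GoldStandard],
    p_values: list[float] = (0.01, 0.025, 0.05, 0.075, 0.1, 0.2, 0.3, 0.4, 0.5),
) -> pd.DataFrame:
    """Median precision/recall across TFs for each empirical P-value cutoff.

    ``affinities``, ``background_affinities`` and ``gold_standards`` are
    keyed by TF name; the medians are pooled over all supplied TFs. Rows:
    (p, median_PR, median_REC).
    """
    rows = []
    for p in p_values:
        prs, recs = [], []
        for tf, aff in affinities.items():
            thr = empirical_threshold(background_affinities[tf], p=p)
            binary = binarize_affinities(aff, thr)
            j = binary.tfs.index(tf)
            predictions = [
                r for r, v in zip(binary.regions, binary.values[:, j]) if v
            ]
            counts = precision_recall(predictions, gold_standards[tf])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                prs.append(counts.PR)
                recs.append(counts.REC)
        rows.append((p, float(np.nanmedian(prs)), float(np.nanmedian(recs))))
    return pd.DataFrame(rows, columns=["p", "median_PR", "median_REC"])


def target_shift_test(
    predicted_targets: set[str], fold_changes: dict[str, float]
) -> tuple[float, float]:
    """Two-sample KS test: target log2FCs against the all-gene background.

    Returns (D, p). Requires at least 5 targets with measured fold
    changes.
    """
    target_fc = np.array(
        [fc for g, fc in fold_changes.items() if g in predicted_targets]
    )
    if target_fc.size < 5:
        raise ValueError(
            f"only {target_fc.size} predicted targets with fold changes (need >= 5)"
        )
    all_fc = np.array(list(fold_changes.values()))
    res = stats.ks_2samp(target_fc, all_fc)
    return float(res.statistic), float(res.pvalue)


def target_overlap_enrichment(
    predicted: set[str], reference: set[str], universe: set[str]
) -> float:
    """One-sided hypergeometric over-representation of ``reference`` genes
    among ``predicted``, drawn from ``universe``."""
    if not universe:
        raise ValueError("empty gene universe")
    if not predicted <= universe or not reference <= universe:
        raise ValueError("predicted and reference sets must lie in the universe")
    N = len(universe)
    K = len(reference)
    n = len(predicted)
    k = len(predicted & reference)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def scan_motif_hits(
    pwm: PWM,
    regions: list[GenomicRegion],
    genome: dict[str, str],
    p_threshold: float = 1e-4,
) -> list[GenomicRegion]:
    """Naive log-odds motif scanner (synthetic stand-in for a dedicated
    motif-hit caller) for building gold standards on fixtures.

    Windows are scored with the log-odds of the PWM against a uniform
    background; the score cutoff is the (1 - p_threshold) quantile of the
    exact null score distribution, computed by dynamic programming over
    positions (discretized to 1e-3 bins). Both strands are scanned.
    """
    logodds = np.log2(pwm.matrix / 0.25)  # L x 4
    cutoff = _score_cutoff(logodds, p_threshold)
    hits: list[GenomicRegion] = []
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = pwm.motif_length
    for region in regions:
        seq = genome[region.chrom][region.start : region.end].upper()
        rc = "".join(comp[b] for b in reversed(seq))
        for strand, s in (("+", seq), ("-", rc)):
            for i in range(len(s) - L + 1):
                window = s[i : i + L]
                if "N" in window:
                    continue
                score = sum(logodds[j, base_idx[b]] for j, b in enumerate(window))
                if score >= cutoff:
                    if strand == "+":
                        start = region.start + i
                    else:
                        start = region.end - i - L
                    hits.append(
                        GenomicRegion(region.chrom, start, start + L, strand=strand)
                    )
    return hits


def _score_cutoff(logodds: np.ndarray, p: float, bin_width: float = 1e-3) -> float:
    """(1 - p) quantile of the null log-odds score under uniform bases,
    via dynamic programming on discretized scores."""
    scaled = np.round(logodds / bin_width).astype(np.int64)
    dist = {0: 1.0}
    for row in scaled:
        new: dict[int, float] = {}
        for s, prob in dist.items():
            for v in row:
                key = s + int(v)
                new[key] = new.get(key, 0.0) + prob * 0.25
        dist = new
    scores = np.array(sorted(dist))
    probs = np.array([dist[int(s)] for s in scores])
    tail = np.cumsum(probs[::-1])[::-1]
    idx = np.searchsorted(tail <= p, True)
    if idx >= scores.size:
        idx = scores.size - 1
    return float(scores[idx] * bin_width)
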