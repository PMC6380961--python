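"""Merged super-enhancers: merging, quantification, dynamics, profiles,
target assignment."""

import numpy as np
import pytest

from epicdrem.genomic_io import ExpressionSeries, GeneAnnotation, GenomicRegion
from epicdrem.se_dynamics import (
    MergedSE,
    assign_se_targets,
    classify_dynamic,
    enumerate_model_profiles,
    merge_se_calls,
    quantify_merged_se,
    relative_profiles,
    select_representatives,
    stem_assign,
)


def interval_closure_oracle(intervals):
    """Brute-force transitive closure of the overlap-or-book-ended relation."""
    items = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a and b and a[0] <= b[1] and b[0] <= a[1]:
                    items[i] = [min(a[0], b[0]), max(a[1], b[1])]
                    items[j] = []
                    changed = True
        items = [iv for iv in items if iv]
    return sorted(tuple(iv) for iv in items)


def spans(merged):
    return sorted((m.region.start, m.region.end) for m in merged)


class TestMerge:
    def test_direct_overlap_merges(self):
        regions = [
            GenomicRegion("chr1", 0, 100),
            GenomicRegion("chr1", 90, 200),
            GenomicRegion("chr1", 300, 400),
        ]
        assert spans(merge_se_calls([regions])) == [(0, 200), (300, 400)]

    def test_transitive_chain_merges_to_one(self):
        regions = [
            GenomicRegion("chr1", 0, 10_000),
            GenomicRegion("chr1", 9_000, 20_000),
            GenomicRegion("chr1", 19_000, 30_000),
        ]
        merged = merge_se_calls([regions])
        assert spans(merged) == [(0, 30_000)]
        assert merged[0].source_count == 3

    def test_book_ended_intervals_merge(self):
        regions = [GenomicRegion("chr1", 0, 10_000), GenomicRegion("chr1", 10_000, 20_000)]
        assert spans(merge_se_calls([regions])) == [(0, 20_000)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_interval_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        starts = rng.integers(0, 100_000, 40)
        widths = rng.integers(1_000, 20_000, 40)
        regions = [
            GenomicRegion("chr1", int(s), int(s + w)) for s, w in zip(starts, widths)
        ]
        expected = interval_closure_oracle([(r.start, r.end) for r in regions])
        assert spans(merge_se_calls([regions])) == expected

    def test_idempotent_and_order_invariant(self, rng):
        regions = [
            GenomicRegion("chr1", int(s), int(s) + 5_000)
            for s in rng.integers(0, 200_000, 30)
        ]
        once = merge_se_calls([regions])
        twice = merge_se_calls([[m.region for m in once]])
        assert spans(once) == spans(twice)
        shuffled = list(regions)
        rng.shuffle(shuffled)
        assert spans(merge_se_calls([shuffled])) == spans(once)

    def test_constituents_covered_by_merged_span(self, rng):
        regions = [
            GenomicRegion("chr1", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 50_000, 20), rng.integers(500, 5_000, 20))
        ]
        merged = merge_se_calls([regions])
        for r in regions:
            assert any(
                m.region.start <= r.start and r.end <= m.region.end for m in merged
            )

    def test_min_width_filter(self):
        regions = [GenomicRegion("chr1", 0, 5_000), GenomicRegion("chr1", 100_000, 115_000)]
        merged = merge_se_calls([regions], min_width=10_000)
        assert spans(merged) == [(100_000, 115_000)]


class TestQuantify:
    def test_constant_coverage_arithmetic(self):
        merged = [MergedSE(GenomicRegion("chr1", 1_000, 2_000), 1)]
        track = {"chr1": np.array([[0.0], [5_000.0], [2.0]])}
        quantify_merged_se(merged, {"T0": track}, {"T0": 1e7})
        assert merged[0].signal["T0"] == pytest.approx(2_000.0)

    def test_zero_coverage_gives_zero(self):
        merged = [MergedSE(GenomicRegion("chr1", 0, 1_000), 1)]
        quantify_merged_se(merged, {"T0": {}}, {"T0": 1e7})
        assert merged[0].signal["T0"] == 0.0

    def test_doubling_library_halves_signal(self):
        track = {"chr1": np.array([[0.0], [5_000.0], [2.0]])}
        a = [MergedSE(GenomicRegion("chr1", 0, 1_000), 1)]
        b = [MergedSE(GenomicRegion("chr1", 0, 1_000), 1)]
        quantify_merged_se(a, {"T0": track}, {"T0": 1e7})
        quantify_merged_se(b, {"T0": track}, {"T0": 2e7})
        assert b[0].signal["T0"] == pytest.approx(a[0].signal["T0"] / 2)

    def test_negative_coverage_rejected(self):
        merged = [MergedSE(GenomicRegion("chr1", 0, 100), 1)]
        track = {"chr1": np.array([[0.0], [100.0], [-1.0]])}
        with pytest.raises(ValueError, match="negative"):
            quantify_merged_se(merged, {"T0": track}, {"T0": 1e7})

    def test_partial_overlap_counts_only_covered_bases(self):
        merged = [MergedSE(GenomicRegion("chr1", 500, 1_500), 1)]
        track = {"chr1": np.array([[0.0], [1_000.0], [3.0]])}
        quantify_merged_se(merged, {"T0": track}, {"T0": 1e7})
        assert merged[0].signal["T0"] == pytest.approx(500 * 3.0)


class TestProfilesAndDynamics:
    def _se(self, signals):
        se = MergedSE(GenomicRegion("chr1", 0, 10_000), 1)
        se.signal = {f"T{i}": s for i, s in enumerate(signals)}
        return se

    def test_equal_signal_gives_zero_log2fc(self):
        (se,) = relative_profiles([self._se([100, 100])], "T0")
        assert se.log2fc["T1"] == 0.0

    def test_fourfold_signal_near_two(self):
        (se,) = relative_profiles([self._se([1000, 4000])], "T0")
        assert se.log2fc["T1"] == pytest.approx(2.0, abs=0.01)

    def test_zero_over_zero_guarded_by_pseudocount(self):
        (se,) = relative_profiles([self._se([0, 0])], "T0")
        assert se.log2fc["T1"] == 0.0

    @pytest.mark.parametrize(
        "profile,expected",
        [((0, 0.5, 0.9), False), ((0, -1.2, -0.3), True), ((0, 1.0), True)],
    )
    def test_dynamic_boundary_inclusive_and_direction_agnostic(self, profile, expected):
        se = MergedSE(GenomicRegion("chr1", 0, 10_000), 1)
        se.log2fc = {f"T{i}": v for i, v in enumerate(profile)}
        classify_dynamic([se])
        assert se.dynamic is expected


class TestModelProfiles:
    def test_candidate_count_is_power(self):
        assert enumerate_model_profiles(3, 2).shape == (25, 3)  # (2*2+1)^2
        assert enumerate_model_profiles(4, 1).shape == (27, 4)  # 3^3

    def test_profiles_start_at_zero_with_bounded_steps(self):
        profiles = enumerate_model_profiles(5, 2)
        assert (profiles[:, 0] == 0).all()
        steps = np.diff(profiles, axis=1)
        assert steps.min() >= -2 and steps.max() <= 2

    def test_representatives_distinct_and_seeded(self):
        profiles = enumerate_model_profiles(4, 2)
        a = select_representatives(profiles, 10, seed=1)
        b = select_representatives(profiles, 10, seed=1)
        assert a == b
        assert len(set(a)) == 10

    def test_exact_profile_match_assigned_r_one(self):
        tps = ["T0", "T1", "T2", "T3"]
        profiles = enumerate_model_profiles(4, 2)
        rep_ids = select_representatives(profiles, 25, seed=0)
        rep = profiles[rep_ids[3]]  # an arbitrary representative
        se = MergedSE(GenomicRegion("chr1", 0, 10_000), 1)
        se.log2fc = {tp: float(v) for tp, v in zip(tps, rep)}
        pset = stem_assign([se], tps, n_representatives=25, seed=0)
        assert se.profile_id is not None
        assert se.profile_r == pytest.approx(1.0, abs=1e-9)
        assigned = pset.profiles[se.profile_id]
        assert np.corrcoef(assigned, rep)[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_flat_se_filtered_out(self):
        tps = ["T0", "T1", "T2"]
        se = MergedSE(GenomicRegion("chr1", 0, 10_000), 1)
        se.log2fc = {tp: 0.0 for tp in tps}
        stem_assign([se], tps, seed=0)
        assert se.profile_id is None

    def test_too_few_time_points_rejected(self):
        with pytest.raises(ValueError):
            enumerate_model_profiles(2, 2)


class TestTargetAssignment:
    def _setup(self, rng, n_decoys=5, noise=0.0):
        tps = [f"T{i}" for i in range(6)]
        n = n_decoys + 1
        # distinct random-walk profiles per gene
        values = np.cumsum(rng.normal(0, 1.0, size=(n, 6)), axis=1)
        genes_ids = [f"g{i}" for i in range(n)]
        expr = ExpressionSeries(genes_ids, tps, values, "T0")
        genes = [
            GeneAnnotation(f"g{i}", "chr1", "+", (100_000 + 10_000 * i,))
            for i in range(n)
        ]
        se = MergedSE(GenomicRegion("chr1", 150_000, 170_000), 1)
        se.dynamic = True
        target_fc = values[0] - values[0, 0]
        se.log2fc = {
            tp: float(target_fc[t] + rng.normal(0, noise)) for t, tp in enumerate(tps)
        }
        return se, expr, genes

    def test_identical_profile_selected_with_r_one(self, rng):
        se, expr, genes = self._setup(rng, noise=0.0)
        assign_se_targets([se], expr, genes)
        assert se.target_gene == "g0"
        assert se.target_r == pytest.approx(1.0, abs=1e-9)

    def test_signed_maximum_prefers_positive_correlation(self):
        tps = ["T0", "T1", "T2", "T3"]
        prof = np.array([0.0, 1.0, 2.0, 3.0])
        values = np.vstack([prof * 0.9, -prof * 0.9])
        expr = ExpressionSeries(["pos", "neg"], tps, values, "T0")
        genes = [
            GeneAnnotation("pos", "chr1", "+", (100_000,)),
            GeneAnnotation("neg", "chr1", "+", (110_000,)),
        ]
        se = MergedSE(GenomicRegion("chr1", 120_000, 140_000), 1)
        se.dynamic = True
        se.log2fc = dict(zip(tps, prof))
        assign_se_targets([se], expr, genes)
        assert se.target_gene == "pos"

    def test_no_tss_in_reach_gives_none(self, rng):
        se, expr, genes = self._setup(rng)
        far = [
            GeneAnnotation(g.gene_id, "chr2", g.strand, g.tss_list) for g in genes
        ]
        assign_se_targets([se], expr, far)
        assert se.target_gene is None

    def test_constant_gene_profile_skipped(self):
        tps = ["T0", "T1", "T2"]
        values = np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        expr = ExpressionSeries(["flat", "rising"], tps, values, "T0")
        genes = [
            GeneAnnotation("flat", "chr1", "+", (100_000,)),
            GeneAnnotation("rising", "chr1", "+", (110_000,)),
        ]
        se = MergedSE(GenomicRegion("chr1", 100_000, 120_000), 1)
        se.dynamic = True
        se.log2fc = {"T0": 0.0, "T1": 1.0, "T2": 2.0}
        assign_se_targets([se], expr, genes)
        assert se.target_gene == "rising"

    def test_generating_gene_recovered_under_noise(self):
        """SE profile = gene profile + N(0, 0.2): >= 90% recovery over 100
        seeded SEs with >= 5 decoys."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            se, expr, genes = self._setup(rng, n_decoys=5, noise=0.2)
            assign_se_targets([se], expr, genes)
            hits += int(se.target_gene == "g0")
        assert hits >= 90
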