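"""Replicate consensus, control subtraction, knockdown differencing, and
platform combination."""

import numpy as np
import pytest

from neurogrn.intervals import GenomicInterval, IntervalSet, covered_bp, merge_union
from neurogrn.peaks import (
    ConsensusParams,
    PeakSet,
    combine_platforms,
    consensus_peaks,
    knockdown_sensitive_peaks,
    subtract_control,
    threshold_fdr,
)
from neurogrn.synth import SyntheticConfig, simulate_genome, simulate_knockdown_arms

from conftest import random_interval_set


def _ps(pairs, factor="F", condition="NE", replicate=1, scores=None):
    ivs = [
        GenomicInterval("chr1", s, e, name=f"p{i}",
                        score=scores[i] if scores else 0.01)
        for i, (s, e) in enumerate(pairs)
    ]
    return PeakSet(IntervalSet(ivs).normalize(), factor=factor,
                   condition=condition, replicate=replicate)


class TestThreshold:
    def test_strict_inequality_at_boundary(self):
        ps = _ps([(0, 10), (20, 30), (40, 50)], scores=[0.01, 0.05, 0.049])
        assert len(threshold_fdr(ps, 0.05)) == 2

    def test_fdr_one_keeps_everything_below(self):
        scores = list(np.random.default_rng(0).uniform(0, 1, 50))
        ps = _ps([(i * 20, i * 20 + 10) for i in range(50)], scores=scores)
        assert len(threshold_fdr(ps, 1.0)) == sum(s < 1.0 for s in scores)

    def test_count_matches_direct_enumeration(self):
        rng = np.random.default_rng(4)
        scores = list(rng.uniform(0, 0.2, 200))
        ps = _ps([(i * 20, i * 20 + 10) for i in range(200)], scores=scores)
        for cut in (0.01, 0.05, 0.1):
            assert len(threshold_fdr(ps, cut)) == sum(s < cut for s in scores)

    def test_missing_score_is_error(self):
        ps = PeakSet(IntervalSet([GenomicInterval("chr1", 0, 10)]), "F", "NE")
        with pytest.raises(ValueError, match="no FDR"):
            threshold_fdr(ps, 0.05)


class TestConsensus:
    def test_two_of_three_with_merge(self):
        reps = [_ps([(100, 200)], replicate=1), _ps([(150, 250)], replicate=2),
                _ps([], replicate=3)]
        out = consensus_peaks(reps, ConsensusParams())
        assert [(iv.start, iv.end) for iv in out.intervals] == [(100, 250)]
        assert "support=2" in out.intervals[0].name
        assert out.replicate == "consensus"

    def test_single_replicate_peak_dropped(self):
        reps = [_ps([], replicate=1), _ps([], replicate=2),
                _ps([(500, 600)], replicate=3)]
        out = consensus_peaks(reps, ConsensusParams())
        assert len(out) == 0

    def test_min_support_one_equals_merged_union(self):
        rng = np.random.default_rng(8)
        reps = [
            PeakSet(random_interval_set(rng, 50, scored=True), "F", "NE", r + 1)
            for r in range(3)
        ]
        params = ConsensusParams(fdr_max=1.0, min_support=1)
        out = consensus_peaks(reps, params)
        pooled = IntervalSet(
            [iv for p in reps for iv in p.intervals if iv.score < 1.0]
        ).normalize()
        assert [(iv.start, iv.end) for iv in out.intervals] == [
            (iv.start, iv.end) for iv in merge_union(pooled)
        ]

    def test_mixed_factors_rejected(self):
        reps = [_ps([(0, 10)], factor="A"), _ps([(0, 10)], factor="B")]
        with pytest.raises(ValueError, match="mixed"):
            consensus_peaks(reps, ConsensusParams(min_support=2, n_replicates=2))

    def test_monotone_in_min_support_and_fdr(self):
        rng = np.random.default_rng(9)
        reps = [
            PeakSet(random_interval_set(rng, 80, scored=True), "F", "NE", r + 1)
            for r in range(3)
        ]
        # stricter support never covers new ground (count can change through
        # region merging, so coverage is the monotone quantity)
        cov_by_support = [
            covered_bp(consensus_peaks(reps, ConsensusParams(fdr_max=0.5, min_support=k)).intervals)
            for k in (1, 2, 3)
        ]
        assert cov_by_support == sorted(cov_by_support, reverse=True)
        cov_by_fdr = [
            covered_bp(consensus_peaks(reps, ConsensusParams(fdr_max=f, min_support=2)).intervals)
            for f in (0.1, 0.3, 0.8)
        ]
        assert cov_by_fdr == sorted(cov_by_fdr)

    def test_survival_fraction_matches_closed_form(self):
        """Planted true peaks survive 2-of-3 consensus at rate r^3 + 3r^2(1-r)."""
        from scipy.stats import binom

        from neurogrn.synth import simulate_peak_replicates

        r = 0.8
        cfg = SyntheticConfig(
            seed=123, peaks_per_replicate=1000, replicate_reproducibility=r,
            chrom_length_bp=5_000_000, noise_peak_rate=0.0,
        )
        annotation, _, _ = simulate_genome(cfg)
        reps, _, truth = simulate_peak_replicates(cfg, annotation)
        cons = consensus_peaks(reps, ConsensusParams(fdr_max=0.05))
        trees = cons.intervals.trees()
        survived = 0
        for row in truth.peaks.itertuples():
            tree = trees.get(row.chrom)
            if tree is not None and tree.overlaps(row.start, row.end):
                survived += 1
        p_expected = r**3 + 3 * r**2 * (1 - r)
        lo, hi = binom.interval(0.99, 1000, p_expected)
        assert lo <= survived <= hi


class TestControlSubtraction:
    def test_empty_controls_identity(self):
        exp = _ps([(0, 10), (20, 30)])
        out = subtract_control(exp, [])
        assert out.intervals == exp.intervals

    def test_total_control_coverage_empties(self):
        exp = _ps([(0, 10), (20, 30)])
        ctrl = _ps([(0, 100)], factor="control")
        assert len(subtract_control(exp, [ctrl])) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_invariant_to_control_order(self, seed):
        rng = np.random.default_rng(seed)
        exp = PeakSet(random_interval_set(rng, 100), "F", "NE")
        ctrls = [
            PeakSet(random_interval_set(rng, 30), "control", "NE", i)
            for i in range(4)
        ]
        forward = subtract_control(exp, ctrls)
        backward = subtract_control(exp, ctrls[::-1])
        assert forward.intervals == backward.intervals


class TestKnockdownDifference:
    def test_identical_arms_cancel(self):
        reps = [_ps([(0, 100)], factor="H3K9ac", condition="noDox", replicate=i)
                for i in (1, 2, 3)]
        reps_kd = [_ps([(0, 100)], factor="H3K9ac", condition="Dox", replicate=i)
                   for i in (1, 2, 3)]
        out = knockdown_sensitive_peaks(reps, reps_kd)
        assert len(out) == 0

    def test_empty_knockdown_arm_keeps_untreated_consensus(self):
        reps = [_ps([(0, 100)], factor="H3K9ac", condition="noDox", replicate=i)
                for i in (1, 2, 3)]
        empty = [_ps([], factor="H3K9ac", condition="Dox", replicate=i)
                 for i in (1, 2, 3)]
        out = knockdown_sensitive_peaks(reps, empty)
        assert len(out) == 1

    def test_planted_dependent_fraction_recovered(self):
        """30% of true acetylation peaks omitted from the knockdown arm are
        recovered as knockdown-sensitive, within the 99% binomial interval."""
        from scipy.stats import binom

        cfg = SyntheticConfig(
            seed=77, peaks_per_replicate=1000, replicate_reproducibility=0.9,
            chrom_length_bp=5_000_000,
        )
        annotation, _, _ = simulate_genome(cfg)
        nodox, dox, truth = simulate_knockdown_arms(cfg, annotation, dependent_fraction=0.3)
        sensitive = knockdown_sensitive_peaks(nodox, dox)
        trees = sensitive.intervals.trees()
        flagged = 0
        for row in truth.peaks.itertuples():
            tree = trees.get(row.chrom)
            if tree is not None and tree.overlaps(row.start, row.end):
                flagged += 1
        # survival of a dependent peak also requires 2-of-3 replicate presence
        r = 0.9
        p_surv = r**3 + 3 * r**2 * (1 - r)
        lo, hi = binom.interval(0.995, 1000, 0.3 * p_surv)
        # non-dependent peaks bordering dependent ones add a small excess;
        # allow the interval's upper edge to stretch by the collision rate
        assert lo * 0.9 <= flagged <= hi * 1.1


class TestCombinePlatforms:
    def test_disjoint_counts_add(self):
        a = _ps([(0, 10), (20, 30), (40, 50)])
        b = PeakSet(
            IntervalSet([GenomicInterval("chr1", s, e) for s, e in
                         [(100, 110), (120, 130), (140, 150), (160, 170)]]).normalize(),
            "F", "NE", platform="chip_chip",
        )
        assert len(combine_platforms(a, b)) == 7

    def test_identical_sets_idempotent(self):
        a = _ps([(0, 10), (20, 30)])
        assert len(combine_platforms(a, a)) == 2

    def test_coverage_matches_union_oracle(self):
        rng = np.random.default_rng(12)
        a = PeakSet(random_interval_set(rng, 150), "F", "NE", platform="chip_seq")
        b = PeakSet(random_interval_set(rng, 150), "F", "NE", platform="chip_chip")
        combined = combine_platforms(a, b)
        pooled = IntervalSet(list(a.intervals) + list(b.intervals)).normalize()
        assert covered_bp(combined.intervals) == covered_bp(pooled)

    def test_factor_mismatch_rejected(self):
        with pytest.raises(ValueError, match="factor"):
            combine_platforms(_ps([(0, 10)], factor="A"), _ps([(0, 10)], factor="B"))
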