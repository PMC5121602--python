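"""Per-replicate scored peaks to high-confidence factor-associated peak sets.

The processing chain mirrors standard replicate-consensus ChIP analysis:
FDR-threshold each replicate (strict ``score < fdr_max``; 0.05 for factor
ChIP, 0.2 for H3K9ac), retain candidate regions supported by at least
``min_support`` of the replicates (default 2 of 3), subtract control peaks
(input / untagged-line ChIP) whole, and, for knockdown-sensitive histone
acetylation, subtract the consensus of the knockdown arm from the consensus of
the untreated arm. ChIP-chip and ChIP-seq peak sets for the same factor are
combined as a merged union.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .intervals import GenomicInterval, IntervalSet, merge_union, subtract

__all__ = [
    "PeakSet",
    "ConsensusParams",
    "threshold_fdr",
    "consensus_peaks",
    "subtract_control",
    "knockdown_sensitive_peaks",
    "combine_platforms",
]

FDR_MAX_FACTOR = 0.05
FDR_MAX_ACETYL = 0.2


@dataclass
class PeakSet:
    """An :class:`IntervalSet` with assay metadata.

    ``replicate`` is an integer for raw replicates and ``"consensus"`` for
    replicate-consensus sets; ``platform`` is ``chip_chip`` or ``chip_seq``.
    """

    intervals: IntervalSet
    factor: str
    condition: str
    replicate: int | str = 1
    platform: str = "chip_seq"

    def __len__(self) -> int:
        return len(self.intervals)

    def with_intervals(self, ivs: IntervalSet) -> "PeakSet":
        return replace(self, intervals=ivs)


@dataclass
class ConsensusParams:
    """Replicate-consensus parameters: FDR cutoff, support, replicate count."""

    fdr_max: float = FDR_MAX_FACTOR
    min_support: int = 2
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.fdr_max <= 1:
            raise ValueError("fdr_max must be in (0, 1]")
        if not 1 <= self.min_support <= self.n_replicates:
            raise ValueError("require 1 <= min_support <= n_replicates")


def threshold_fdr(peaks: PeakSet, fdr_max: float) -> PeakSet:
    """Retain peaks with FDR strictly below ``fdr_max``."""
    for iv in peaks.intervals:
        if iv.score is None:
            raise ValueError(f"peak {iv.name} has no FDR score")
    kept = [iv for iv in peaks.intervals if iv.score < fdr_max]
    return peaks.with_intervals(IntervalSet(kept).normalize())


def consensus_peaks(replicates: list[PeakSet], params: ConsensusParams) -> PeakSet:
    """Merged candidate regions supported by >= ``min_support`` replicates.

    Each replicate is FDR-thresholded; all surviving peaks are pooled and
    fused into maximal candidate regions; a candidate is retained iff peaks
    from at least ``min_support`` distinct replicates overlap it by >= 1 bp.
    Retained regions carry their support count in the name
    (``consensus_<i>|support=<k>``).
    """
    if len(replicates) < params.min_support:
        raise ValueError(
            f"need >= {params.min_support} replicate sets, got {len(replicates)}"
        )
    factors = {p.factor for p in replicates}
    conditions = {p.condition for p in replicates}
    if len(factors) > 1 or len(conditions) > 1:
        raise ValueError(f"mixed factors/conditions in consensus: {factors}, {conditions}")

    thresholded = [threshold_fdr(p, params.fdr_max) for p in replicates]
    pooled = IntervalSet([iv for p in thresholded for iv in p.intervals]).normalize()
    if len(pooled) == 0:
        return PeakSet(
            IntervalSet(), factor=replicates[0].factor,
            condition=replicates[0].condition, replicate="consensus",
            platform=replicates[0].platform,
        )
    candidates = merge_union(pooled)
    rep_trees = [p.intervals.trees() for p in thresholded]

    kept = []
    for i, cand in enumerate(candidates):
        support = 0
        for trees in rep_trees:
            tree = trees.get(cand.chrom)
            if tree is not None and tree.overlaps(cand.start, cand.end):
                support += 1
        if support >= params.min_support:
            kept.append(
                GenomicInterval(
                    cand.chrom, cand.start, cand.end,
                    name=f"consensus_{len(kept)}|support={support}",
                )
            )
    return PeakSet(
        IntervalSet(kept, sorted_flag=True),
        factor=replicates[0].factor,
        condition=replicates[0].condition,
        replicate="consensus",
        platform=replicates[0].platform,
    )


def subtract_control(exp: PeakSet, controls: list[PeakSet]) -> PeakSet:
    """Drop every experimental peak overlapping any control peak (whole-interval).

    The result is invariant to the order of the control list.
    """
    pooled = IntervalSet(
        [iv for c in controls for iv in c.intervals]
    ).normalize()
    return exp.with_intervals(subtract(exp.intervals, pooled))


def knockdown_sensitive_peaks(
    untreated_reps: list[PeakSet],
    knockdown_reps: list[PeakSet],
    params: ConsensusParams | None = None,
) -> PeakSet:
    """Consensus peaks of the untreated arm lost upon factor knockdown.

    Used for Gmnn-dependent H3K9ac: the replicate consensus of the
    doxycycline-induced knockdown arm is subtracted (whole-interval) from the
    consensus of the untreated arm. Default FDR cutoff 0.2, as for histone
    acetylation peak scores.
    """
    if params is None:
        params = ConsensusParams(fdr_max=FDR_MAX_ACETYL)
    untreated = consensus_peaks(untreated_reps, params)
    knockdown = consensus_peaks(knockdown_reps, params)
    result = untreated.with_intervals(subtract(untreated.intervals, knockdown.intervals))
    return replace(result, condition=f"{untreated.condition}-sensitive")


def combine_platforms(a: PeakSet, b: PeakSet) -> PeakSet:
    """Union peak sets from two platforms for the same factor and condition.

    Provenance of each merged region (which platforms contributed) is recorded
    in the interval name.
    """
    if a.factor != b.factor:
        raise ValueError(f"factor mismatch: {a.factor!r} vs {b.factor!r}")
    if a.condition != b.condition:
        raise ValueError(f"condition mismatch: {a.condition!r} vs {b.condition!r}")
    pooled = IntervalSet(list(a.intervals) + list(b.intervals)).normalize()
    merged = merge_union(pooled)
    a_trees = a.intervals.trees()
    b_trees = b.intervals.trees()
    named = []
    for i, iv in enumerate(merged):
        sources = []
        ta = a_trees.get(iv.chrom)
        tb = b_trees.get(iv.chrom)
        if ta is not None and ta.overlaps(iv.start, iv.end):
            sources.append(a.platform)
        if tb is not None and tb.overlaps(iv.start, iv.end):
            sources.append(b.platform)
        named.append(
            GenomicInterval(iv.chrom, iv.start, iv.end, name=f"peak_{i}|{'+'.join(sources)}")
        )
    return PeakSet(
        IntervalSet(named, sorted_flag=True),
        factor=a.factor,
        condition=a.condition,
        replicate="consensus",
        platform="combined",
    )
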