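"""Gene models, promoter definition, nearest-TSS assignment, and the
genomic-feature fold-enrichment statistic.

Promoters span 2 kb upstream through 0.5 kb downstream of the TSS,
strand-aware (2,500 bp total). Feature enrichment for a peak set is

    enrichment = (n_feature / n_peak) / (N_feature / N_background)

where ``n_feature`` counts peaks overlapping >= 1 feature interval,
``N_feature`` is the number of annotated features of that class, and
``N_background = floor(genome_length / avg_feature_length)`` is the number of
feature-sized windows tiling the genome. Canonical average feature lengths:
CpG island 601 bp, promoter 2,500 bp, enhancer 271 bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .intervals import (
    ChromSizes,
    GenomicInterval,
    IntervalSet,
    merge_union,
    midpoint,
    read_bed,
)

__all__ = [
    "PROMOTER_UPSTREAM_BP",
    "PROMOTER_DOWNSTREAM_BP",
    "DEFAULT_AVG_FEATURE_LENGTH_BP",
    "GeneModel",
    "GenomeAnnotation",
    "FeatureEnrichment",
    "PeakGeneAssignment",
    "gene_models_from_bed12",
    "define_promoters",
    "nearest_tss",
    "classify_genomic_location",
    "location_histogram",
    "feature_enrichment",
    "enrichment_from_counts",
]

logger = logging.getLogger(__name__)

PROMOTER_UPSTREAM_BP = 2000
PROMOTER_DOWNSTREAM_BP = 500

#: Canonical per-class average feature lengths (bp) used to size background
#: windows; classes not listed fall back to the empirical mean length.
DEFAULT_AVG_FEATURE_LENGTH_BP = {
    "cpg_island": 601,
    "promoter": 2500,
    "enhancer": 271,
}

#: Classification priority when a peak midpoint falls in several classes.
LOCATION_PRIORITY = ("promoter", "utr5", "utr3", "exon", "intron", "intergenic")


@dataclass
class GeneModel:
    """A gene with strand-aware TSS and exon/intron/UTR structure from BED12.

    ``tss`` is the biological 5' end: ``start`` on +, ``end - 1`` on -.
    For several isoform records sharing a ``gene_id`` the 5'-most TSS is kept
    and exon structure is taken from that 5'-most isoform.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    tss: int
    exons: IntervalSet
    introns: IntervalSet
    utr5: IntervalSet
    utr3: IntervalSet


def _record_tss(iv: GenomicInterval) -> int:
    return iv.start if iv.strand == "+" else iv.end - 1


def _is_more_5prime(candidate: GenomicInterval, incumbent: GenomicInterval) -> bool:
    if candidate.strand == "+":
        return _record_tss(candidate) < _record_tss(incumbent)
    return _record_tss(candidate) > _record_tss(incumbent)


def _split_utrs(
    exons: list[tuple[int, int]], thick_start: int, thick_end: int, strand: str
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Exonic sequence outside [thick_start, thick_end) split into 5'/3' UTR."""
    left, right = [], []
    for s, e in exons:
        if s < thick_start:
            left.append((s, min(e, thick_start)))
        if e > thick_end:
            right.append((max(s, thick_end), e))
    return (left, right) if strand == "+" else (right, left)


def gene_models_from_bed12(records: IntervalSet) -> list[GeneModel]:
    """Build one :class:`GeneModel` per gene_id from BED12 records (name column)."""
    chosen: dict[str, GenomicInterval] = {}
    for iv in records:
        if iv.strand not in ("+", "-"):
            raise ValueError(f"gene record {iv.name} lacks a strand")
        prev = chosen.get(iv.name)
        if prev is None or _is_more_5prime(iv, prev):
            chosen[iv.name] = iv

    models = []
    for gene_id, iv in sorted(chosen.items()):
        sizes = iv.block_sizes or (len(iv),)
        starts = iv.block_starts or (0,)
        exon_tuples = [(iv.start + o, iv.start + o + s) for o, s in zip(starts, sizes)]
        exons = IntervalSet(
            [GenomicInterval(iv.chrom, s, e, name=gene_id, strand=iv.strand) for s, e in exon_tuples]
        ).normalize()
        introns = []
        for (s1, e1), (s2, e2) in zip(exon_tuples, exon_tuples[1:]):
            if e1 < s2:
                introns.append(GenomicInterval(iv.chrom, e1, s2, name=gene_id, strand=iv.strand))
        ts = iv.thick_start if iv.thick_start is not None else iv.start
        te = iv.thick_end if iv.thick_end is not None else iv.end
        u5, u3 = _split_utrs(exon_tuples, ts, te, iv.strand)
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=iv.chrom,
                strand=iv.strand,
                start=iv.start,
                end=iv.end,
                tss=_record_tss(iv),
                exons=exons,
                introns=IntervalSet(introns, sorted_flag=True),
                utr5=IntervalSet(
                    [GenomicInterval(iv.chrom, s, e, name=gene_id, strand=iv.strand) for s, e in u5]
                ).normalize(),
                utr3=IntervalSet(
                    [GenomicInterval(iv.chrom, s, e, name=gene_id, strand=iv.strand) for s, e in u3]
                ).normalize(),
            )
        )
    return models


@dataclass
class GenomeAnnotation:
    """Gene models plus regulatory feature sets and the chromosome-size table."""

    genes: list[GeneModel]
    cpg_islands: IntervalSet
    enhancers: IntervalSet
    chrom_sizes: ChromSizes
    promoters: IntervalSet = field(init=False)

    def __post_init__(self) -> None:
        self.promoters = define_promoters(self)

    @classmethod
    def load(
        cls,
        genes_bed12: str | Path,
        chrom_sizes: ChromSizes,
        cpg_bed: str | Path | None = None,
        enhancer_bed: str | Path | None = None,
    ) -> "GenomeAnnotation":
        genes = gene_models_from_bed12(read_bed(genes_bed12, "bed12"))
        cpg = read_bed(cpg_bed, "bed3").normalize() if cpg_bed else IntervalSet()
        enh = read_bed(enhancer_bed, "bed3").normalize() if enhancer_bed else IntervalSet()
        return cls(genes=genes, cpg_islands=cpg, enhancers=enh, chrom_sizes=chrom_sizes)

    def feature_set(self, name: str) -> IntervalSet:
        if name == "promoter":
            return self.promoters
        if name == "cpg_island":
            return self.cpg_islands
        if name == "enhancer":
            return self.enhancers
        raise KeyError(f"unknown feature class {name!r}")


def define_promoters(annotation: GenomeAnnotation) -> IntervalSet:
    """Strand-aware promoter intervals, clipped to chromosome bounds.

    + strand: [TSS - 2000, TSS + 500); - strand: [TSS - 499, TSS + 2001) —
    2,500 bp around the 5'-most TSS in both cases.
    """
    out = []
    for g in annotation.genes:
        if g.strand == "+":
            s, e = g.tss - PROMOTER_UPSTREAM_BP, g.tss + PROMOTER_DOWNSTREAM_BP
        else:
            s, e = g.tss - PROMOTER_DOWNSTREAM_BP + 1, g.tss + PROMOTER_UPSTREAM_BP + 1
        s = max(0, s)
        e = min(e, annotation.chrom_sizes[g.chrom])
        if s < e:
            out.append(GenomicInterval(g.chrom, s, e, name=g.gene_id, strand=g.strand))
    return IntervalSet(out).normalize()


@dataclass
class PeakGeneAssignment:
    """A peak mapped to its nearest-TSS gene (strand-ignored midpoint distance)."""

    peak: GenomicInterval
    gene_id: str | None
    distance_bp: int | None


def nearest_tss(peaks: IntervalSet, annotation: GenomeAnnotation) -> list[PeakGeneAssignment]:
    """Assign each peak to the gene minimizing |peak midpoint - TSS| on its chromosome.

    Ties break to the smaller TSS coordinate, then lexicographic gene_id.
    Peaks on chromosomes without genes get a null assignment with a warning.
    """
    # (tss, gene_id) sorted per chromosome; sort order realises the tie-break
    per_chrom: dict[str, list[tuple[int, str]]] = {}
    for g in annotation.genes:
        per_chrom.setdefault(g.chrom, []).append((g.tss, g.gene_id))
    arrays = {}
    for chrom, pairs in per_chrom.items():
        pairs.sort()
        arrays[chrom] = (np.array([p[0] for p in pairs]), [p[1] for p in pairs])

    out = []
    warned: set[str] = set()
    for peak in peaks:
        entry = arrays.get(peak.chrom)
        if entry is None:
            if peak.chrom not in warned:
                logger.warning("no genes on chromosome %s; peaks left unassigned", peak.chrom)
                warned.add(peak.chrom)
            out.append(PeakGeneAssignment(peak, None, None))
            continue
        tss_arr, gene_ids = entry
        mid = midpoint(peak)
        i = int(np.searchsorted(tss_arr, mid))
        best = None  # (distance, tss, gene_id)
        for j in (i - 1, i):
            if 0 <= j < len(tss_arr):
                cand = (abs(mid - int(tss_arr[j])), int(tss_arr[j]), gene_ids[j])
                if best is None or cand < best:
                    best = cand
        assert best is not None
        out.append(PeakGeneAssignment(peak, best[2], best[0]))
    return out


def classify_genomic_location(peak: GenomicInterval, annotation: GenomeAnnotation) -> str:
    """Single feature class of the peak midpoint.

    Priority when the midpoint lies in several classes:
    promoter > 5'UTR > 3'UTR > exon > intron > intergenic.
    """
    mid = midpoint(peak)

    def _contains(ivs: IntervalSet) -> bool:
        return any(iv.chrom == peak.chrom and iv.start <= mid < iv.end for iv in ivs)

    if _contains(annotation.promoters):
        return "promoter"
    for g in annotation.genes:
        if g.chrom != peak.chrom:
            continue
        if _contains(g.utr5):
            return "utr5"
    for g in annotation.genes:
        if g.chrom != peak.chrom:
            continue
        if _contains(g.utr3):
            return "utr3"
    for g in annotation.genes:
        if g.chrom != peak.chrom:
            continue
        if _contains(g.exons):
            return "exon"
    for g in annotation.genes:
        if g.chrom != peak.chrom:
            continue
        if _contains(g.introns):
            return "intron"
    return "intergenic"


def location_histogram(peaks: IntervalSet, annotation: GenomeAnnotation) -> dict[str, int]:
    """Category -> peak count; categories partition the peak set.

    Uses per-class interval trees so classifying thousands of peaks stays fast.
    """
    class_sets = {
        "promoter": annotation.promoters,
        "utr5": IntervalSet([iv for g in annotation.genes for iv in g.utr5]),
        "utr3": IntervalSet([iv for g in annotation.genes for iv in g.utr3]),
        "exon": IntervalSet([iv for g in annotation.genes for iv in g.exons]),
        "intron": IntervalSet([iv for g in annotation.genes for iv in g.introns]),
    }
    trees = {name: ivs.trees() for name, ivs in class_sets.items()}
    hist = {name: 0 for name in LOCATION_PRIORITY}
    for peak in peaks:
        mid = midpoint(peak)
        for name in LOCATION_PRIORITY[:-1]:
            tree = trees[name].get(peak.chrom)
            if tree is not None and tree.overlaps_point(mid):
                hist[name] += 1
                break
        else:
            hist["intergenic"] += 1
    return hist


@dataclass
class FeatureEnrichment:
    """Fold enrichment of a peak set for one genomic feature class."""

    feature_name: str
    n_feature: int
    n_peak: int
    N_feature: int
    N_background: int
    avg_feature_length_bp: float
    enrichment: float


def enrichment_from_counts(
    n_feature: int,
    n_peak: int,
    N_feature: int,
    genome_length: int,
    avg_feature_length_bp: float,
) -> FeatureEnrichment:
    """Evaluate the fold-enrichment formula from pre-tabulated counts."""
    if n_peak <= 0:
        raise ValueError("n_peak must be positive")
    if not 0 <= n_feature <= n_peak:
        raise ValueError("require 0 <= n_feature <= n_peak")
    if avg_feature_length_bp <= 0:
        raise ValueError("avg_feature_length_bp must be positive")
    N_background = int(genome_length // avg_feature_length_bp)
    return FeatureEnrichment(
        feature_name="feature",
        n_feature=n_feature,
        n_peak=n_peak,
        N_feature=N_feature,
        N_background=N_background,
        avg_feature_length_bp=float(avg_feature_length_bp),
        enrichment=(n_feature / n_peak) / (N_feature / N_background),
    )


def feature_enrichment(
    peaks: IntervalSet,
    feature_set: IntervalSet,
    chrom_sizes: ChromSizes,
    feature_name: str = "feature",
    avg_feature_length_bp: float | None = None,
) -> FeatureEnrichment:
    """Fold enrichment of peaks for a feature class over genome-wide windows.

    ``avg_feature_length_bp`` defaults to the canonical per-class value
    (601 / 2500 / 271 bp for CpG islands / promoters / enhancers) when
    ``feature_name`` matches, else the empirical mean feature length.
    """
    n_peak = len(peaks)
    if n_peak == 0:
        raise ValueError("feature enrichment is undefined for an empty peak set")
    if avg_feature_length_bp is None:
        avg_feature_length_bp = DEFAULT_AVG_FEATURE_LENGTH_BP.get(feature_name)
    if avg_feature_length_bp is None:
        if len(feature_set) == 0:
            raise ValueError("empty feature set and no average length supplied")
        avg_feature_length_bp = sum(len(iv) for iv in feature_set) / len(feature_set)
    if avg_feature_length_bp <= 0:
        raise ValueError("avg_feature_length_bp must be positive")

    trees = feature_set.trees()
    n_feature = 0
    for peak in peaks:
        tree = trees.get(peak.chrom)
        if tree is not None and tree.overlaps(peak.start, peak.end):
            n_feature += 1

    N_feature = len(feature_set)
    N_background = int(chrom_sizes.genome_length // avg_feature_length_bp)
    enrichment = (n_feature / n_peak) / (N_feature / N_background)
    return FeatureEnrichment(
        feature_name=feature_name,
        n_feature=n_feature,
        n_peak=n_peak,
        N_feature=N_feature,
        N_background=N_background,
        avg_feature_length_bp=float(avg_feature_length_bp),
        enrichment=enrichment,
    )
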