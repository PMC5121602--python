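import numpy as np
import pytest

from neurogrn.annotation import GenomeAnnotation, gene_models_from_bed12
from neurogrn.intervals import ChromSizes, GenomicInterval, IntervalSet


def random_interval_set(rng, n, chrom_len=10_000, chrom="chr1", max_width=500, scored=False):
    ivs = []
    for i in range(n):
        start = int(rng.integers(0, chrom_len - 1))
        width = int(rng.integers(1, max_width))
        end = min(start + width, chrom_len)
        score = float(rng.uniform(0, 1)) if scored else None
        ivs.append(GenomicInterval(chrom, start, end, name=f"iv{i}", score=score))
    return IntervalSet(ivs).normalize()


def per_base_mask(ivs, chrom_len, chrom="chr1"):
    """Brute-force per-base occupancy oracle."""
    mask = np.zeros(chrom_len, dtype=bool)
    for iv in ivs:
        if iv.chrom == chrom:
            mask[iv.start : iv.end] = True
    return mask


@pytest.fixture(scope="session")
def toy_annotation():
    """Two-chromosome annotation: 3 genes with exon/UTR structure, plus
    CpG-island and enhancer intervals, built by hand."""
    sizes = ChromSizes({"chr1": 100_000, "chr2": 50_000})
    genes = gene_models_from_bed12(
        IntervalSet(
            [
                # + strand gene: TSS 10_000, exons [10000,10400) [12000,12800)
                GenomicInterval(
                    "chr1", 10_000, 12_800, name="gA", strand="+",
                    thick_start=10_200, thick_end=12_400,
                    block_sizes=(400, 800), block_starts=(0, 2_000),
                ),
                # - strand gene: TSS 49_999 on chr1
                GenomicInterval(
                    "chr1", 45_000, 50_000, name="gB", strand="-",
                    thick_start=45_500, thick_end=49_500,
                    block_sizes=(1_000, 1_000), block_starts=(0, 4_000),
                ),
                # + strand gene on chr2
                GenomicInterval(
                    "chr2", 20_000, 24_000, name="gC", strand="+",
                    thick_start=20_100, thick_end=23_900,
                    block_sizes=(500, 500), block_starts=(0, 3_500),
                ),
            ]
        )
    )
    cpg = IntervalSet([GenomicInterval("chr1", 9_800, 10_401)]).normalize()
    enh = IntervalSet([GenomicInterval("chr1", 30_000, 30_271)]).normalize()
    return GenomeAnnotation(genes=genes, cpg_islands=cpg, enhancers=enh, chrom_sizes=sizes)
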