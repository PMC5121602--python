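"""Synthetic genomes, replicate ChIP peak sets, expression counts, and
motif-planted sequences with known ground truth.

The generator emulates the statistical structure of a replicate ChIP study of
two neural transcription factors (plus a histone-acetylation assay) in a
differentiating ES-cell system: 2-3 scored peak replicates per condition with
tunable reproducibility and planted promoter enrichment, untagged-line control
peaks, a second factor sharing a planted co-binding fraction, a tissue panel
of negative-binomial expression counts with a planted embryonic-CNS-enriched
gene subset, and sequences carrying a planted motif at a stated rate. Every
planted parameter is recorded in a :class:`PlantedTruth` so downstream modules
can be tested as parameter-recovery problems.

Everything is deterministic under the master seed: each generator draws from
an independent child stream derived from ``(seed, stream index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation, gene_models_from_bed12
from .intervals import ChromSizes, GenomicInterval, IntervalSet
from .motifs import MotifPWM
from .peaks import PeakSet

__all__ = [
    "SyntheticConfig",
    "PlantedTruth",
    "simulate_genome",
    "simulate_peak_replicates",
    "simulate_cobound_factor",
    "simulate_knockdown_arms",
    "simulate_expression",
    "plant_motif",
    "write_fasta",
]

# child-stream indices under the master seed
_STREAM_GENOME = 0
_STREAM_PEAKS = 1
_STREAM_COBOUND = 2
_STREAM_EXPRESSION = 3
_STREAM_MOTIF = 4


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic study, with defaults matching the emulated
    design: three scored replicates per condition at 80% reproducibility,
    ~400 bp peaks, FDR cutoff 0.05, a three-sample tissue panel per group, a
    four-fold planted embryonic-CNS enrichment, and a motif planted in half
    the target sequences."""

    seed: int = 0
    # genome
    n_chroms: int = 3
    chrom_length_bp: int = 1_000_000
    n_genes: int = 300
    n_cpg_islands: int = 150
    n_enhancers: int = 200
    # peaks
    peaks_per_replicate: int = 300
    n_replicates: int = 3
    replicate_reproducibility: float = 0.8
    promoter_planting_fraction: float = 0.4
    noise_peak_rate: float = 0.3
    control_peak_rate: float = 0.1
    control_contamination: float = 0.05
    cobinding_fraction: float = 0.2
    fdr_threshold: float = 0.05
    peak_width_mean_bp: float = 400.0
    peak_width_sd_bp: float = 100.0
    width_jitter_frac: float = 0.1
    # expression
    n_samples_per_group: int = 3
    planted_cns_fraction: float = 0.2
    planted_fold: float = 4.0
    nb_dispersion: float = 0.05
    tf_fraction: float = 0.3
    # motifs
    motif_planting_rate: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "replicate_reproducibility", "promoter_planting_fraction",
            "control_contamination", "cobinding_fraction",
            "motif_planting_rate", "tf_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.planted_fold <= 0:
            raise ValueError("planted_fold must be positive")
        for name in ("n_chroms", "n_genes", "peaks_per_replicate", "n_replicates"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


@dataclass
class PlantedTruth:
    """Ground-truth labels for every generated record.

    ``peaks`` columns: peak_id, chrom, start, end, is_true, promoter_planted,
    cobound. ``genes`` columns: gene_id, cns_enriched, true_fold.
    ``sequences`` columns: seq_id, motif_planted.
    """

    peaks: pd.DataFrame = field(default_factory=pd.DataFrame)
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    sequences: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_tsv(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        for name in ("peaks", "genes", "sequences"):
            df = getattr(self, name)
            if len(df):
                df.to_csv(f"{prefix}.truth_{name}.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genome and annotation
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return bytes(np.array([65, 67, 71, 84], dtype=np.uint8)[rng.integers(0, 4, length)]).decode()


def simulate_genome(
    cfg: SyntheticConfig,
) -> tuple[GenomeAnnotation, dict[str, str], ChromSizes]:
    """Random genome: non-overlapping genes with exon/UTR structure, CpG
    islands (half placed at promoters), enhancers, and i.i.d. uniform sequence.

    Raises a capacity error when the requested genes cannot fit.
    """
    rng = cfg.rng(_STREAM_GENOME)
    sizes = {f"chr{i + 1}": cfg.chrom_length_bp for i in range(cfg.n_chroms)}
    chrom_sizes = ChromSizes(sizes)
    chroms = list(sizes)

    gene_records = []
    if cfg.n_genes > 0:
        if cfg.n_chroms == 0:
            raise ValueError("cannot place genes on an empty genome")
        per_chrom = np.full(cfg.n_chroms, cfg.n_genes // cfg.n_chroms)
        per_chrom[: cfg.n_genes % cfg.n_chroms] += 1
        gi = 0
        for ci, chrom in enumerate(chroms):
            n = int(per_chrom[ci])
            if n == 0:
                continue
            slot = cfg.chrom_length_bp // n
            if slot < 3000:
                raise ValueError(
                    f"capacity error: {n} genes do not fit on a "
                    f"{cfg.chrom_length_bp} bp chromosome"
                )
            for k in range(n):
                slot_start, slot_end = k * slot, (k + 1) * slot
                glen = int(rng.integers(2000, min(20000, slot - 500)))
                gstart = int(rng.integers(slot_start, slot_end - glen))
                strand = "+" if rng.random() < 0.5 else "-"
                n_exons = int(rng.integers(2, 6))
                # split the gene body into alternating exon/intron runs
                cuts = np.sort(rng.choice(np.arange(1, glen), 2 * n_exons - 1, replace=False))
                bounds = np.concatenate([[0], cuts, [glen]])
                block_starts, block_sizes = [], []
                for e in range(n_exons):
                    s, t = int(bounds[2 * e]), int(bounds[2 * e + 1])
                    if t > s:
                        block_starts.append(s)
                        block_sizes.append(t - s)
                # trim the gene body to end at the last exon (BED12 convention)
                glen = block_starts[-1] + block_sizes[-1]
                thick_start = gstart + block_starts[0] + block_sizes[0] // 2
                thick_end = gstart + block_starts[-1] + block_sizes[-1] // 2
                if thick_end <= thick_start:
                    thick_start, thick_end = gstart, gstart + glen
                gene_records.append(
                    GenomicInterval(
                        chrom, gstart, gstart + glen,
                        name=f"gene_{gi:04d}", strand=strand,
                        thick_start=thick_start, thick_end=thick_end,
                        block_sizes=tuple(block_sizes),
                        block_starts=tuple(block_starts),
                    )
                )
                gi += 1

    genes = gene_models_from_bed12(IntervalSet(gene_records))

    def _place_features(n: int, mean_len: float, sd_len: float, at_tss: bool) -> list[GenomicInterval]:
        out = []
        tss_list = [(g.chrom, g.tss) for g in genes]
        for i in range(n):
            length = max(100, int(rng.normal(mean_len, sd_len)))
            if at_tss and tss_list:
                chrom, tss = tss_list[int(rng.integers(len(tss_list)))]
                start = max(0, tss - length // 2)
            else:
                chrom = chroms[int(rng.integers(len(chroms)))]
                start = int(rng.integers(0, sizes[chrom] - length))
            end = min(start + length, sizes[chrom])
            out.append(GenomicInterval(chrom, start, end))
        return out

    cpg = _place_features(cfg.n_cpg_islands // 2, 601, 150, at_tss=True)
    cpg += _place_features(cfg.n_cpg_islands - len(cpg), 601, 150, at_tss=False)
    enh = _place_features(cfg.n_enhancers, 271, 60, at_tss=False)

    annotation = GenomeAnnotation(
        genes=genes,
        cpg_islands=IntervalSet(cpg).normalize(chrom_sizes),
        enhancers=IntervalSet(enh).normalize(chrom_sizes),
        chrom_sizes=chrom_sizes,
    )
    sequences = {c: _random_sequence(rng, sizes[c]) for c in chroms}
    return annotation, sequences, chrom_sizes


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

def _draw_width(cfg: SyntheticConfig, rng: np.random.Generator) -> int:
    return max(50, int(rng.normal(cfg.peak_width_mean_bp, cfg.peak_width_sd_bp)))


def _place_peak(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    annotation: GenomeAnnotation,
    in_promoter: bool,
    prom_trees: dict | None = None,
) -> GenomicInterval:
    """A peak whose midpoint lies inside (or outside) a promoter."""
    sizes = annotation.chrom_sizes
    chroms = list(sizes.sizes)
    width = _draw_width(cfg, rng)
    promoters = annotation.promoters
    if prom_trees is None:
        prom_trees = promoters.trees()
    for _ in range(1000):
        if in_promoter:
            if len(promoters) == 0:
                raise ValueError("no promoters to plant peaks in")
            prom = promoters[int(rng.integers(len(promoters)))]
            mid = int(rng.integers(prom.start, prom.end))
            chrom = prom.chrom
        else:
            chrom = chroms[int(rng.integers(len(chroms)))]
            mid = int(rng.integers(0, sizes[chrom]))
            tree = prom_trees.get(chrom)
            if tree is not None and tree.overlaps_point(mid):
                continue
        start = max(0, mid - width // 2)
        end = min(start + width, sizes[chrom])
        if end > start:
            return GenomicInterval(chrom, start, end)
    raise RuntimeError("could not place peak after bounded retries")


def _jitter(iv: GenomicInterval, cfg: SyntheticConfig, rng: np.random.Generator,
            sizes: ChromSizes, name: str, score: float) -> GenomicInterval:
    width = len(iv)
    f = cfg.width_jitter_frac
    shift = int(rng.uniform(-f / 2, f / 2) * width)
    new_width = max(50, int(width * rng.uniform(1 - f, 1 + f)))
    start = max(0, iv.start + shift)
    end = min(start + new_width, sizes[iv.chrom])
    return GenomicInterval(iv.chrom, start, max(end, start + 1), name=name, score=score)


def simulate_peak_replicates(
    cfg: SyntheticConfig,
    annotation: GenomeAnnotation,
    factor: str = "factorA",
    condition: str = "NE",
) -> tuple[list[PeakSet], list[PeakSet], PlantedTruth]:
    """Replicate peak sets with planted promoter enrichment plus controls.

    True peaks land in promoters with probability
    ``promoter_planting_fraction`` and elsewhere otherwise; each true peak
    enters each replicate with probability ``replicate_reproducibility``
    (jittered +/-10% in width and position) and an FDR drawn
    Uniform(0, threshold/2); per-replicate noise peaks draw FDR Uniform(0, 1).
    Controls contain ``control_peak_rate x peaks_per_replicate`` intervals, a
    ``control_contamination`` fraction of which coincide with true peaks.
    """
    rng = cfg.rng(_STREAM_PEAKS)
    sizes = annotation.chrom_sizes
    prom_trees = annotation.promoters.trees()

    n_true = cfg.peaks_per_replicate
    true_peaks, rows = [], []
    for i in range(n_true):
        in_prom = rng.random() < cfg.promoter_planting_fraction
        iv = _place_peak(cfg, rng, annotation, in_prom, prom_trees)
        iv = GenomicInterval(iv.chrom, iv.start, iv.end, name=f"true_{i:04d}")
        true_peaks.append(iv)
        rows.append(
            dict(peak_id=iv.name, chrom=iv.chrom, start=iv.start, end=iv.end,
                 is_true=True, promoter_planted=in_prom, cobound=False)
        )

    replicates = []
    n_noise = int(round(cfg.noise_peak_rate * cfg.peaks_per_replicate))
    for r in range(cfg.n_replicates):
        ivs = []
        for iv in true_peaks:
            if rng.random() < cfg.replicate_reproducibility:
                score = float(rng.uniform(0, cfg.fdr_threshold / 2))
                ivs.append(_jitter(iv, cfg, rng, sizes, f"{iv.name}_rep{r + 1}", score))
        for j in range(n_noise):
            iv = _place_peak(cfg, rng, annotation, False, prom_trees)
            score = float(rng.uniform(0, 1))
            ivs.append(GenomicInterval(iv.chrom, iv.start, iv.end,
                                       name=f"noise_r{r + 1}_{j:04d}", score=score))
        replicates.append(
            PeakSet(IntervalSet(ivs).normalize(), factor=factor,
                    condition=condition, replicate=r + 1)
        )

    n_control = int(round(cfg.control_peak_rate * cfg.peaks_per_replicate))
    n_contam = int(round(cfg.control_contamination * n_control))
    control_ivs = []
    true_set = IntervalSet(true_peaks).normalize()
    true_trees = true_set.trees()
    for j in range(n_control):
        if j < n_contam and n_true > 0:
            src = true_peaks[int(rng.integers(n_true))]
            iv = _jitter(src, cfg, rng, sizes, f"control_{j:04d}",
                         float(rng.uniform(0, cfg.fdr_threshold / 2)))
            control_ivs.append(iv)
        else:
            for _ in range(1000):
                cand = _place_peak(cfg, rng, annotation, False, prom_trees)
                tree = true_trees.get(cand.chrom)
                if tree is None or not tree.overlaps(cand.start, cand.end):
                    control_ivs.append(
                        GenomicInterval(cand.chrom, cand.start, cand.end,
                                        name=f"control_{j:04d}",
                                        score=float(rng.uniform(0, cfg.fdr_threshold / 2)))
                    )
                    break
            else:
                raise RuntimeError("could not place control peak")
    controls = [
        PeakSet(IntervalSet(control_ivs).normalize(), factor="control",
                condition=condition, replicate=1)
    ]
    return replicates, controls, PlantedTruth(peaks=pd.DataFrame(rows))


def simulate_cobound_factor(
    cfg: SyntheticConfig,
    annotation: GenomeAnnotation,
    factor_a: PeakSet,
    factor: str = "factorB",
) -> tuple[PeakSet, PlantedTruth]:
    """A second factor's peak set sharing ``cobinding_fraction`` of factor A's
    peaks (with jitter); the remainder placed independently outside A's peaks."""
    rng = cfg.rng(_STREAM_COBOUND)
    sizes = annotation.chrom_sizes
    prom_trees = annotation.promoters.trees()
    a_ivs = list(factor_a.intervals)
    a_trees = factor_a.intervals.trees()
    n_total = len(a_ivs) if a_ivs else cfg.peaks_per_replicate
    n_cobound = int(round(cfg.cobinding_fraction * n_total))

    ivs, rows = [], []
    order = rng.permutation(len(a_ivs)) if a_ivs else []
    for i in range(n_cobound):
        src = a_ivs[int(order[i % len(a_ivs)])]
        iv = _jitter(src, cfg, rng, sizes, f"{factor}_cb_{i:04d}", 0.0)
        ivs.append(iv)
        rows.append(dict(peak_id=iv.name, chrom=iv.chrom, start=iv.start,
                         end=iv.end, is_true=True, promoter_planted=False, cobound=True))
    for i in range(n_total - n_cobound):
        for _ in range(1000):
            cand = _place_peak(cfg, rng, annotation, rng.random() < cfg.promoter_planting_fraction, prom_trees)
            tree = a_trees.get(cand.chrom)
            if tree is None or not tree.overlaps(cand.start, cand.end):
                iv = GenomicInterval(cand.chrom, cand.start, cand.end,
                                     name=f"{factor}_ind_{i:04d}", score=0.0)
                ivs.append(iv)
                rows.append(dict(peak_id=iv.name, chrom=iv.chrom, start=iv.start,
                                 end=iv.end, is_true=True, promoter_planted=False,
                                 cobound=False))
                break
        else:
            raise RuntimeError("could not place independent peak")
    peaks = PeakSet(IntervalSet(ivs).normalize(), factor=factor,
                    condition=factor_a.condition, replicate="consensus")
    return peaks, PlantedTruth(peaks=pd.DataFrame(rows))


_STREAM_KNOCKDOWN = 5


def simulate_knockdown_arms(
    cfg: SyntheticConfig,
    annotation: GenomeAnnotation,
    dependent_fraction: float = 0.3,
    factor: str = "H3K9ac",
) -> tuple[list[PeakSet], list[PeakSet], PlantedTruth]:
    """Untreated vs knockdown replicate arms for a histone mark.

    A ``dependent_fraction`` of true peaks is knockdown-sensitive: present in
    the untreated arm's true set but omitted from the knockdown arm's.
    Replicates in both arms are drawn at ``replicate_reproducibility`` with
    jitter; FDR scores as for factor peaks. Truth column ``dependent`` flags
    the sensitive peaks.
    """
    if not 0 <= dependent_fraction <= 1:
        raise ValueError("dependent_fraction must be in [0, 1]")
    rng = cfg.rng(_STREAM_KNOCKDOWN)
    sizes = annotation.chrom_sizes
    prom_trees = annotation.promoters.trees()

    true_peaks, rows = [], []
    for i in range(cfg.peaks_per_replicate):
        in_prom = rng.random() < cfg.promoter_planting_fraction
        iv = _place_peak(cfg, rng, annotation, in_prom, prom_trees)
        dependent = rng.random() < dependent_fraction
        iv = GenomicInterval(iv.chrom, iv.start, iv.end, name=f"acetyl_{i:04d}")
        true_peaks.append((iv, dependent))
        rows.append(dict(peak_id=iv.name, chrom=iv.chrom, start=iv.start,
                         end=iv.end, is_true=True, promoter_planted=in_prom,
                         dependent=dependent))

    def _draw_arm(peak_pool: list[GenomicInterval], arm: str) -> list[PeakSet]:
        reps = []
        for r in range(cfg.n_replicates):
            ivs = []
            for iv in peak_pool:
                if rng.random() < cfg.replicate_reproducibility:
                    score = float(rng.uniform(0, 0.1))  # under the 0.2 cutoff
                    ivs.append(_jitter(iv, cfg, rng, sizes, f"{iv.name}_{arm}{r + 1}", score))
            reps.append(PeakSet(IntervalSet(ivs).normalize(), factor=factor,
                                condition=arm, replicate=r + 1))
        return reps

    untreated = _draw_arm([iv for iv, _ in true_peaks], "noDox")
    knockdown = _draw_arm([iv for iv, dep in true_peaks if not dep], "Dox")
    return untreated, knockdown, PlantedTruth(peaks=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(
    cfg: SyntheticConfig, annotation: GenomeAnnotation
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Negative-binomial counts over a four-group tissue panel.

    A ``planted_cns_fraction`` of genes has its expected expression multiplied
    by ``planted_fold`` in embryonic-CNS samples. Returns (counts genes x
    samples, sample metadata with tissue_group and library_size, truth).
    """
    rng = cfg.rng(_STREAM_EXPRESSION)
    genes = [g.gene_id for g in annotation.genes]
    lengths = np.array(
        [sum(len(iv) for iv in g.exons) for g in annotation.genes], dtype=float
    )
    groups = ["ES", "embryonic_CNS", "adult_CNS", "other"]
    samples, tissue = [], []
    for grp in groups:
        for i in range(cfg.n_samples_per_group):
            samples.append(f"{grp}_{i + 1}")
            tissue.append(grp)

    n_genes = len(genes)
    cns_flag = rng.random(n_genes) < cfg.planted_cns_fraction
    base_rpkm = rng.lognormal(mean=np.log(30), sigma=1.0, size=n_genes)
    library_size = rng.uniform(8e6, 12e6, size=len(samples))

    counts = np.zeros((n_genes, len(samples)), dtype=int)
    disp = cfg.nb_dispersion
    for s, grp in enumerate(tissue):
        fold = np.where(cns_flag & (grp == "embryonic_CNS"), cfg.planted_fold, 1.0)
        mu = base_rpkm * fold * (lengths / 1e3) * (library_size[s] / 1e6)
        if disp > 0:
            n_param = 1.0 / disp
            p_param = n_param / (n_param + mu)
            counts[:, s] = rng.negative_binomial(n_param, p_param)
        else:
            counts[:, s] = rng.poisson(mu)

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples)
    meta = pd.DataFrame(
        {"sample_id": samples, "tissue_group": tissue,
         "library_size": library_size.astype(int)}
    )
    tf_flag = rng.random(n_genes) < cfg.tf_fraction
    truth = PlantedTruth(
        genes=pd.DataFrame(
            {"gene_id": genes, "cns_enriched": cns_flag,
             "true_fold": np.where(cns_flag, cfg.planted_fold, 1.0),
             "is_tf": tf_flag}
        )
    )
    return counts_df, meta, truth


# ---------------------------------------------------------------------------
# Motifs
# ---------------------------------------------------------------------------

def plant_motif(
    cfg: SyntheticConfig, sequences: dict[str, str], pwm: MotifPWM
) -> tuple[dict[str, str], PlantedTruth]:
    """Write the PWM consensus site into ``motif_planting_rate`` of the sequences.

    The consensus (column-wise most probable base) overwrites the sequence at
    a uniform position; untouched sequences keep their label.
    """
    rng = cfg.rng(_STREAM_MOTIF)
    L = pwm.length
    site = pwm.consensus()
    out, rows = {}, []
    for seq_id, seq in sequences.items():
        if L > len(seq):
            raise ValueError(f"motif ({L} bp) longer than sequence {seq_id} ({len(seq)} bp)")
        planted = rng.random() < cfg.motif_planting_rate
        if planted:
            pos = int(rng.integers(0, len(seq) - L + 1))
            seq = seq[:pos] + site + seq[pos + L:]
        out[seq_id] = seq
        rows.append(dict(seq_id=seq_id, motif_planted=planted))
    return out, PlantedTruth(sequences=pd.DataFrame(rows))


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    """Write sequences as uncompressed FASTA (wrapped at ``width`` columns)."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
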