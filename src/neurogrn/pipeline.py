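"""End-to-end orchestration: simulate (or ingest), consensus, control
subtraction, knockdown-sensitive acetylation, annotation, feature enrichment,
expression classification, motif enrichment, overlap statistics, and GRN
construction, with a run manifest recording checksums and record counts.

Configuration is a flat TOML file whose keys mirror
:class:`~neurogrn.synth.SyntheticConfig` plus the analysis parameters below;
a rerun with identical config and seed is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotation as ann
from . import expression as expr
from . import grn as grnmod
from . import motifs as motifmod
from . import setstats
from . import synth
from .intervals import IntervalSet, write_bed, write_chrom_sizes
from .peaks import ConsensusParams, PeakSet, consensus_peaks, knockdown_sensitive_peaks, subtract_control

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Analysis parameters plus the synthetic-study configuration."""

    synthetic: synth.SyntheticConfig = field(default_factory=synth.SyntheticConfig)
    fdr_max: float = 0.05
    acetyl_fdr_max: float = 0.2
    min_support: int = 2
    acetyl_dependent_fraction: float = 0.3
    fold_threshold: float = 2.0
    score_fraction: float = 0.8
    n_background_per_peak: int = 2
    require_tf: bool = True
    require_cns_enriched: bool = True
    out_dir: str = "pipeline_out"

    def consensus_params(self, acetyl: bool = False) -> ConsensusParams:
        return ConsensusParams(
            fdr_max=self.acetyl_fdr_max if acetyl else self.fdr_max,
            min_support=self.min_support,
            n_replicates=self.synthetic.n_replicates,
        )


def load_config(path: str | Path, seed: int | None = None) -> PipelineConfig:
    """Read a flat TOML config; unknown keys are errors. ``seed`` overrides."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    synth_fields = {f.name for f in dataclasses.fields(synth.SyntheticConfig)}
    pipe_fields = {f.name for f in dataclasses.fields(PipelineConfig)} - {"synthetic"}
    synth_kwargs, pipe_kwargs = {}, {}
    for key, value in raw.items():
        if key in synth_fields:
            synth_kwargs[key] = value
        elif key in pipe_fields:
            pipe_kwargs[key] = value
        else:
            raise ValueError(f"unknown config key {key!r}")
    if seed is not None:
        synth_kwargs["seed"] = seed
    return PipelineConfig(synthetic=synth.SyntheticConfig(**synth_kwargs), **pipe_kwargs)


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Serialize the effective config as flat TOML (lossless round trip)."""
    lines = []
    for f in dataclasses.fields(synth.SyntheticConfig):
        lines.append(_toml_kv(f.name, getattr(cfg.synthetic, f.name)))
    for f in dataclasses.fields(PipelineConfig):
        if f.name == "synthetic":
            continue
        lines.append(_toml_kv(f.name, getattr(cfg, f.name)))
    Path(path).write_text("\n".join(lines) + "\n")


def _toml_kv(key: str, value) -> str:
    if isinstance(value, bool):
        return f"{key} = {'true' if value else 'false'}"
    if isinstance(value, (int, float)):
        return f"{key} = {value}"
    return f'{key} = "{value}"'


@dataclass
class RunManifest:
    """Per-stage record counts and output checksums for a pipeline run."""

    seed: int
    config_hash: str
    stages: list[str] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)

    def record_file(self, path: Path, n_records: int | None = None) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.checksums[path.name] = digest
        if n_records is not None:
            self.counts[path.name] = n_records

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")


def _write_peaks(ps: PeakSet, path: Path, manifest: RunManifest) -> None:
    write_bed(ps.intervals, path, "bed6+1")
    manifest.record_file(path, len(ps))


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage in dependency order; outputs under ``out_dir``.

    Returns the manifest (also written as ``manifest.json``). Identical config
    and seed give identical checksums.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.synthetic
    config_text = json.dumps(dataclasses.asdict(config), sort_keys=True)
    manifest = RunManifest(
        seed=cfg.seed, config_hash=hashlib.sha256(config_text.encode()).hexdigest()
    )
    write_config(config, out / "effective_config.toml")

    # --- stage: simulate genome -------------------------------------------
    annotation, genome_seq, chrom_sizes = synth.simulate_genome(cfg)
    synth.write_fasta(genome_seq, out / "genome.fa")
    write_chrom_sizes(chrom_sizes, out / "chrom.sizes")
    manifest.record_file(out / "genome.fa")
    manifest.record_file(out / "chrom.sizes", len(chrom_sizes.sizes))
    manifest.stages.append("simulate_genome")

    # --- stage: peak replicates + consensus + control subtraction ---------
    reps_a, controls, truth_a = synth.simulate_peak_replicates(
        cfg, annotation, factor="factorA", condition="NE"
    )
    cons_a = consensus_peaks(reps_a, config.consensus_params())
    peaks_a = subtract_control(cons_a, controls)
    _write_peaks(peaks_a, out / "factorA_peaks.bed", manifest)
    manifest.stages.append("consensus_factorA")

    peaks_b, truth_b = synth.simulate_cobound_factor(cfg, annotation, peaks_a, factor="factorB")
    _write_peaks(peaks_b, out / "factorB_peaks.bed", manifest)
    manifest.stages.append("cobound_factorB")

    # --- stage: knockdown-sensitive acetylation ---------------------------
    nodox, dox, truth_ac = synth.simulate_knockdown_arms(
        cfg, annotation, dependent_fraction=config.acetyl_dependent_fraction
    )
    acetyl = knockdown_sensitive_peaks(nodox, dox, config.consensus_params(acetyl=True))
    _write_peaks(acetyl, out / "acetyl_sensitive_peaks.bed", manifest)
    manifest.stages.append("knockdown_acetylation")

    # --- stage: annotation ------------------------------------------------
    gene_sets: dict[str, set[str]] = {}
    assignment_rows = []
    for name, ps in (("factorA", peaks_a), ("factorB", peaks_b), ("acetyl", acetyl)):
        assignments = ann.nearest_tss(ps.intervals, annotation)
        gene_sets[name] = {a.gene_id for a in assignments if a.gene_id is not None}
        for a in assignments:
            assignment_rows.append(
                dict(factor=name, peak=a.peak.name, chrom=a.peak.chrom,
                     start=a.peak.start, end=a.peak.end,
                     gene=a.gene_id, distance_bp=a.distance_bp)
            )
    pd.DataFrame(assignment_rows).to_csv(out / "peak_gene_assignments.tsv", sep="\t", index=False)
    manifest.record_file(out / "peak_gene_assignments.tsv", len(assignment_rows))
    manifest.stages.append("nearest_tss")

    enrich_rows = []
    for feature in ("promoter", "cpg_island", "enhancer"):
        fe = ann.feature_enrichment(
            peaks_a.intervals, annotation.feature_set(feature), chrom_sizes,
            feature_name=feature,
        )
        enrich_rows.append(dataclasses.asdict(fe))
    pd.DataFrame(enrich_rows).to_csv(out / "feature_enrichment.tsv", sep="\t", index=False)
    manifest.record_file(out / "feature_enrichment.tsv", len(enrich_rows))
    manifest.stages.append("feature_enrichment")

    # --- stage: expression ------------------------------------------------
    counts, meta, truth_expr = synth.simulate_expression(cfg, annotation)
    lengths = pd.Series(
        {g.gene_id: sum(len(iv) for iv in g.exons) for g in annotation.genes}
    )
    rpkm_df = expr.rpkm(counts, lengths, meta.set_index("sample_id")["library_size"].astype(float))
    em = expr.ExpressionMatrix(
        rpkm=rpkm_df,
        tissue_group=meta.set_index("sample_id")["tissue_group"],
        gene_length_bp=lengths,
        library_size=meta.set_index("sample_id")["library_size"],
    )
    expr.zscore_rows(em)
    labels = expr.classify_enrichment(
        em, "embryonic_CNS", "ES", fold_threshold=config.fold_threshold
    )
    label_df = pd.DataFrame(
        [dataclasses.asdict(l) for l in labels]
    )
    label_df.to_csv(out / "cns_enrichment_labels.tsv", sep="\t", index=False)
    manifest.record_file(out / "cns_enrichment_labels.tsv", len(label_df))
    manifest.stages.append("expression")

    # --- stage: motif enrichment -----------------------------------------
    planted_pwm = default_planted_pwm()
    target_seqs = motifmod.extract_peak_sequences(peaks_b.intervals, out / "genome.fa")
    target_seqs, truth_motif = synth.plant_motif(cfg, target_seqs, planted_pwm)
    bg_regions = motifmod.sample_background_regions(
        peaks_b.intervals, chrom_sizes, seed=cfg.seed,
        n_per_peak=config.n_background_per_peak,
    )
    bg_seqs = motifmod.extract_peak_sequences(bg_regions, out / "genome.fa")
    shuffled = planted_pwm.shuffled(cfg.rng(97))
    motif_results = motifmod.rank_motifs(
        target_seqs, bg_seqs, [planted_pwm, shuffled], config.score_fraction
    )
    motif_df = pd.DataFrame([dataclasses.asdict(r) for r in motif_results])
    motif_df.to_csv(out / "motif_enrichment.tsv", sep="\t", index=False)
    manifest.record_file(out / "motif_enrichment.tsv", len(motif_df))
    manifest.stages.append("motif_enrichment")

    # --- stage: overlap statistics ---------------------------------------
    universe = {g.gene_id for g in annotation.genes}
    ov = setstats.overlap_test(gene_sets["factorA"], gene_sets["factorB"], universe)
    stats_payload = {
        "table": dataclasses.asdict(ov.table),
        "chi2_yates": ov.chi2_yates,
        "p_chi2": setstats.format_p(ov.p_chi2),
        "p_hypergeom": setstats.format_p(ov.p_hypergeom),
        "jaccard": ov.jaccard,
    }
    (out / "overlap_stats.json").write_text(json.dumps(stats_payload, indent=2) + "\n")
    manifest.record_file(out / "overlap_stats.json")
    manifest.stages.append("set_statistics")

    # --- stage: GRN -------------------------------------------------------
    catalog = grnmod.GeneSetCatalog()
    for name in ("factorA", "factorB"):
        catalog.add(name, gene_sets[name], provenance="chip")
    tf_list = set(truth_expr.genes.loc[truth_expr.genes.is_tf, "gene_id"])
    enrichment_labels = {l.gene_id: l.label for l in labels}
    cobound_genes, _ = grnmod.cobound_targets(peaks_a, peaks_b, annotation)
    acetyl_genes = gene_sets["acetyl"]
    network = grnmod.build_grn(
        catalog, tf_list, enrichment_labels, acetyl_genes, cobound_genes,
        grnmod.GRNFilters(require_tf=config.require_tf,
                          require_cns_enriched=config.require_cns_enriched),
    )
    grnmod.export_grn(network, out / "grn_edges.tsv", "edge_tsv")
    grnmod.export_grn(network, out / "grn.graphml", "graphml")
    grnmod.export_grn(network, out / "grn.dot", "dot")
    manifest.record_file(out / "grn_edges.tsv", network.number_of_edges())
    manifest.stages.append("grn")

    # --- truth tables -----------------------------------------------------
    truth = synth.PlantedTruth(
        peaks=truth_a.peaks, genes=truth_expr.genes, sequences=truth_motif.sequences
    )
    truth.to_tsv(out / "synthetic")
    manifest.save(out / "manifest.json")
    return manifest


def default_planted_pwm() -> "motifmod.MotifPWM":
    """The 8-bp GC-rich PWM planted by the synthetic motif stage (a
    Zic-family-like consensus, CCCGCTGT-leaning)."""
    import numpy as np

    consensus = "CCCGCTGT"
    base_index = {b: i for i, b in enumerate("ACGT")}
    mat = np.full((4, len(consensus)), 0.04)
    for j, b in enumerate(consensus):
        mat[base_index[b], j] = 0.88
    return motifmod.MotifPWM(name="planted_zic_like", matrix=mat, pseudocount=0.0)
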