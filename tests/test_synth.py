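"""Synthetic-data generator: determinism, planted-parameter structure, and
degenerate configurations."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from neurogrn.intervals import intersect
from neurogrn.peaks import subtract_control
from neurogrn.synth import (
    SyntheticConfig,
    plant_motif,
    simulate_cobound_factor,
    simulate_expression,
    simulate_genome,
    simulate_peak_replicates,
    write_fasta,
)


@pytest.fixture(scope="module")
def small_genome():
    cfg = SyntheticConfig(seed=1, n_genes=100, n_cpg_islands=40, n_enhancers=40,
                          peaks_per_replicate=150)
    annotation, seqs, sizes = simulate_genome(cfg)
    return cfg, annotation, seqs, sizes


class TestGenome:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(seed=1, n_genes=100)
        for run in (1, 2):
            annotation, seqs, sizes = simulate_genome(cfg)
            write_fasta(seqs, tmp_path / f"g{run}.fa")
        assert (tmp_path / "g1.fa").read_bytes() == (tmp_path / "g2.fa").read_bytes()

    def test_different_seeds_differ(self):
        s1 = simulate_genome(SyntheticConfig(seed=1, n_genes=10))[1]
        s2 = simulate_genome(SyntheticConfig(seed=2, n_genes=10))[1]
        assert s1["chr1"] != s2["chr1"]

    def test_zero_genes_valid_empty(self):
        annotation, seqs, sizes = simulate_genome(SyntheticConfig(seed=0, n_genes=0,
                                                                  n_cpg_islands=0,
                                                                  n_enhancers=0))
        assert annotation.genes == []
        assert len(annotation.promoters) == 0
        assert len(seqs) == 3

    def test_capacity_error_when_genes_do_not_fit(self):
        with pytest.raises(ValueError, match="capacity"):
            simulate_genome(SyntheticConfig(seed=0, n_genes=10_000,
                                            chrom_length_bp=100_000))

    def test_all_features_within_bounds(self, small_genome):
        cfg, annotation, seqs, sizes = small_genome
        for collection in (annotation.cpg_islands, annotation.enhancers,
                           annotation.promoters):
            for iv in collection:
                sizes.validate(iv)
        for g in annotation.genes:
            assert 0 <= g.start < g.end <= sizes[g.chrom]
            for iv in g.exons:
                assert g.start <= iv.start < iv.end <= g.end

    def test_genes_do_not_overlap(self, small_genome):
        _, annotation, _, _ = small_genome
        by_chrom = {}
        for g in annotation.genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2


class TestPeakReplicates:
    def test_full_reproducibility_no_noise_identical_counts(self):
        cfg = SyntheticConfig(seed=3, peaks_per_replicate=100,
                              replicate_reproducibility=1.0, noise_peak_rate=0.0,
                              width_jitter_frac=0.0)
        annotation, _, _ = simulate_genome(cfg)
        reps, _, _ = simulate_peak_replicates(cfg, annotation)
        coords = [
            [(iv.chrom, iv.start, iv.end) for iv in r.intervals] for r in reps
        ]
        assert coords[0] == coords[1] == coords[2]

    def test_promoter_fraction_within_binomial_interval(self):
        """Planted promoter fraction 0.5 at n=1,000 true peaks lands in the
        exact 99% binomial interval."""
        cfg = SyntheticConfig(seed=4, peaks_per_replicate=1000,
                              promoter_planting_fraction=0.5,
                              chrom_length_bp=4_000_000)
        annotation, _, _ = simulate_genome(cfg)
        _, _, truth = simulate_peak_replicates(cfg, annotation)
        trees = annotation.promoters.trees()
        observed = 0
        for row in truth.peaks.itertuples():
            mid = (row.start + row.end) // 2
            tree = trees.get(row.chrom)
            if tree is not None and tree.overlaps_point(mid):
                observed += 1
        lo, hi = binom.interval(0.99, 1000, 0.5)
        assert lo <= observed <= hi

    def test_zero_contamination_controls_remove_nothing(self):
        cfg = SyntheticConfig(seed=5, peaks_per_replicate=100,
                              control_contamination=0.0)
        annotation, _, _ = simulate_genome(cfg)
        reps, controls, _ = simulate_peak_replicates(cfg, annotation)
        # controls placed off the true peaks: subtracting them from the pure
        # true set removes nothing
        from neurogrn.intervals import IntervalSet, GenomicInterval
        from neurogrn.peaks import PeakSet

        truth_ivs = reps[0]  # replicate 1 includes jittered true + noise
        before = len(truth_ivs)
        after = len(subtract_control(truth_ivs, controls))
        # only noise peaks may collide by chance; true peaks never do by
        # construction, so removal is limited to the noise complement
        assert before - after <= int(cfg.noise_peak_rate * cfg.peaks_per_replicate)

    def test_fdr_scores_separate_true_from_noise(self):
        cfg = SyntheticConfig(seed=6, peaks_per_replicate=200)
        annotation, _, _ = simulate_genome(cfg)
        reps, _, _ = simulate_peak_replicates(cfg, annotation)
        for r in reps:
            for iv in r.intervals:
                if iv.name.startswith("true"):
                    assert iv.score < cfg.fdr_threshold / 2


class TestCoboundFactor:
    def test_full_cobinding_zero_jitter_identical(self, small_genome):
        cfg0, annotation, _, _ = small_genome
        cfg = SyntheticConfig(seed=7, cobinding_fraction=1.0, width_jitter_frac=0.0)
        _, _, truth = simulate_peak_replicates(cfg, annotation)
        from neurogrn.intervals import GenomicInterval, IntervalSet
        from neurogrn.peaks import PeakSet

        a = PeakSet(
            IntervalSet([
                GenomicInterval(r.chrom, r.start, r.end, name=r.peak_id)
                for r in truth.peaks.itertuples()
            ]).normalize(),
            factor="A", condition="NE",
        )
        b, _ = simulate_cobound_factor(cfg, annotation, a)
        assert {(iv.chrom, iv.start, iv.end) for iv in b.intervals} == {
            (iv.chrom, iv.start, iv.end) for iv in a.intervals
        }

    def test_recovered_cobinding_fraction_in_binomial_interval(self):
        """intersect() recovers the planted co-binding fraction at n=1,000."""
        cfg = SyntheticConfig(seed=8, peaks_per_replicate=1000,
                              cobinding_fraction=0.3, chrom_length_bp=5_000_000)
        annotation, _, _ = simulate_genome(cfg)
        _, _, truth = simulate_peak_replicates(cfg, annotation)
        from neurogrn.intervals import GenomicInterval, IntervalSet
        from neurogrn.peaks import PeakSet

        a = PeakSet(
            IntervalSet([
                GenomicInterval(r.chrom, r.start, r.end, name=r.peak_id)
                for r in truth.peaks.itertuples()
            ]).normalize(),
            factor="A", condition="NE",
        )
        b, truth_b = simulate_cobound_factor(cfg, annotation, a)
        shared = intersect(b.intervals, a.intervals)
        observed = len(shared) / len(b.intervals)
        lo, hi = binom.interval(0.99, len(b.intervals), 0.3)
        # independent peaks are placed off factor A's intervals, so overlap
        # beyond the planted fraction cannot occur
        assert lo / len(b.intervals) <= observed <= hi / len(b.intervals)

    def test_zero_cobinding_no_overlap_by_construction(self, small_genome):
        cfg0, annotation, _, _ = small_genome
        cfg = SyntheticConfig(seed=9, cobinding_fraction=0.0, peaks_per_replicate=100)
        _, _, truth = simulate_peak_replicates(cfg, annotation)
        from neurogrn.intervals import GenomicInterval, IntervalSet
        from neurogrn.peaks import PeakSet

        a = PeakSet(
            IntervalSet([
                GenomicInterval(r.chrom, r.start, r.end, name=r.peak_id)
                for r in truth.peaks.itertuples()
            ]).normalize(),
            factor="A", condition="NE",
        )
        b, _ = simulate_cobound_factor(cfg, annotation, a)
        assert len(intersect(b.intervals, a.intervals)) == 0


class TestExpressionAndMotifs:
    def test_expression_deterministic(self, small_genome):
        cfg, annotation, _, _ = small_genome
        c1, m1, t1 = simulate_expression(cfg, annotation)
        c2, m2, t2 = simulate_expression(cfg, annotation)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(t1.genes, t2.genes)

    def test_sample_layout(self, small_genome):
        cfg, annotation, _, _ = small_genome
        counts, meta, _ = simulate_expression(cfg, annotation)
        assert counts.shape == (100, 4 * cfg.n_samples_per_group)
        assert set(meta.tissue_group) == {"ES", "embryonic_CNS", "adult_CNS", "other"}

    def test_plant_rate_one_every_sequence_hit(self):
        from neurogrn.motifs import scan_pwm
        from neurogrn.pipeline import default_planted_pwm

        cfg = SyntheticConfig(seed=10, motif_planting_rate=1.0)
        rng = np.random.default_rng(0)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 120)) for i in range(50)}
        pwm = default_planted_pwm()
        planted, truth = plant_motif(cfg, seqs, pwm)
        assert truth.sequences.motif_planted.all()
        with_hit = {h.sequence_id for h in scan_pwm(planted, pwm)}
        assert with_hit == set(planted)

    def test_plant_rate_zero_untouched(self):
        from neurogrn.pipeline import default_planted_pwm

        cfg = SyntheticConfig(seed=11, motif_planting_rate=0.0)
        seqs = {"s": "ACGT" * 30}
        planted, truth = plant_motif(cfg, seqs, default_planted_pwm())
        assert planted == seqs
        assert not truth.sequences.motif_planted.any()

    def test_motif_longer_than_sequence_rejected(self):
        from neurogrn.pipeline import default_planted_pwm

        cfg = SyntheticConfig(seed=12, motif_planting_rate=1.0)
        with pytest.raises(ValueError, match="longer"):
            plant_motif(cfg, {"s": "ACG"}, default_planted_pwm())


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs", [dict(replicate_reproducibility=1.5),
                   dict(cobinding_fraction=-0.1), dict(planted_fold=0.0),
                   dict(n_genes=-1)],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)
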