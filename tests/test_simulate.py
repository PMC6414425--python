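"""Synthetic-data generator: determinism, construction rules, planted rates."""

import numpy as np
import pandas as pd
import pytest

from rloopkit.dedup import deduplicate
from rloopkit.intervals import ValidationError
from rloopkit.rloops import classify_rloop, gene_window
from rloopkit.simulate import (
    SimulationConfig,
    SizingError,
    simulate_annotation,
    simulate_chip_reads,
    simulate_groseq,
    simulate_rloop_peaks,
)


def small_cfg(**kw):
    defaults = dict(
        n_genes={"pcg_repressed": 30, "active_top": 30, "inactive_bottom": 30},
        chrom_size=5_000_000,
        seed=7,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestAnnotation:
    def test_deterministic_under_seed(self):
        g1, t1 = simulate_annotation(small_cfg())
        g2, t2 = simulate_annotation(small_cfg())
        assert g1 == g2
        assert t1.equals(t2)

    def test_class_counts_match_config(self):
        genes, _ = simulate_annotation(small_cfg())
        labels = pd.Series([g.class_label for g in genes]).value_counts()
        assert labels["pcg_repressed"] == 30
        assert labels["active_top"] == 30

    def test_no_window_overlap_when_fraction_zero(self):
        genes, truth = simulate_annotation(small_cfg(window_overlap_fraction=0.0))
        assert (truth["pair_id"] == -1).all()
        windows = sorted(
            (gene_window(g).chrom, gene_window(g).start, gene_window(g).end)
            for g in genes
        )
        for (c1, s1, e1), (c2, s2, e2) in zip(windows, windows[1:]):
            assert c1 != c2 or e1 <= s2

    def test_planted_pair_fraction(self):
        cfg = small_cfg(
            n_genes={"pcg_repressed": 34, "active_top": 33, "inactive_bottom": 33},
            window_overlap_fraction=0.2,
        )
        genes, truth = simulate_annotation(cfg)
        paired = (truth["pair_id"] >= 0).sum()
        assert paired == 20  # round(0.2 * 100), pairs of two
        by_id = {g.gene_id: g for g in genes}
        for _, grp in truth[truth["pair_id"] >= 0].groupby("pair_id"):
            a, b = (by_id[i] for i in grp["gene_id"])
            assert gene_window(a).overlaps(gene_window(b))
            assert not a.body.overlaps(b.body)  # close but non-nested bodies

    def test_genome_too_small_errors(self):
        with pytest.raises(SizingError):
            simulate_annotation(small_cfg(chrom_size=50_000))


class TestPeaks:
    def test_degenerate_probabilities(self):
        cfg = small_cfg(p_rloop={k: 1.0 for k in ("pcg_repressed", "active_top", "inactive_bottom")})
        genes, truth = simulate_annotation(cfg)
        peaks, ptruth = simulate_rloop_peaks(genes, cfg, annotation_truth=truth)
        assert ptruth["planted_positive"].all()
        assert len(peaks) == len(genes)
        cfg0 = small_cfg(p_rloop={k: 0.0 for k in ("pcg_repressed", "active_top", "inactive_bottom")})
        peaks0, ptruth0 = simulate_rloop_peaks(genes, cfg0, annotation_truth=truth)
        assert peaks0 == []
        assert not ptruth0["planted_positive"].any()

    def test_planted_fraction_within_three_se(self):
        cfg = SimulationConfig(
            n_genes={"pcg_repressed": 10, "active_top": 1000, "inactive_bottom": 10},
            chrom_size=40_000_000,
            seed=11,
        )
        genes, truth = simulate_annotation(cfg)
        _, ptruth = simulate_rloop_peaks(genes, cfg, annotation_truth=truth)
        merged = truth.merge(ptruth, on="gene_id")
        active = merged[merged["class_label"] == "active_top"]
        frac = active["planted_positive"].mean()
        se = np.sqrt(0.76 * 0.24 / len(active))
        assert abs(frac - 0.76) < 3 * se

    def test_recovery_on_isolated_genes(self):
        cfg = small_cfg()
        genes, truth = simulate_annotation(cfg)
        peaks, ptruth = simulate_rloop_peaks(genes, cfg, annotation_truth=truth)
        calls = {c.gene_id: c.status for c in classify_rloop(genes, peaks)}
        for gid, expected in zip(ptruth["gene_id"], ptruth["expected_status"]):
            assert calls[gid] == expected


class TestGroseq:
    def test_inactive_rate_zero_gives_zero_sense_coverage(self):
        cfg = small_cfg(nascent_rate={"pcg_repressed": 1.0, "active_top": 10.0,
                                      "inactive_bottom": 0.0})
        genes, _ = simulate_annotation(cfg)
        plus, minus, truth = simulate_groseq(genes, cfg)
        counts = dict(zip(truth["gene_id"], truth["sense_reads"]))
        for g in genes:
            if g.class_label == "inactive_bottom":
                assert counts[g.gene_id] == 0

    def test_truth_counts_match_sense_coverage_integral(self):
        cfg = small_cfg()
        genes, _ = simulate_annotation(cfg)
        plus, minus, truth = simulate_groseq(genes, cfg)
        counts = dict(zip(truth["gene_id"], truth["sense_reads"]))
        for g in genes[:40]:
            sense = plus if g.body.strand == "+" else minus
            integral = sense.integral(g.body.chrom, g.body.start, g.body.end)
            assert integral / cfg.read_length_bp == pytest.approx(counts[g.gene_id])

    def test_poisson_mean_recovery(self):
        cfg = small_cfg(nascent_rate={"pcg_repressed": 100.0, "active_top": 100.0,
                                      "inactive_bottom": 100.0})
        totals, expected = [], []
        genes, _ = simulate_annotation(cfg)
        for seed in range(10):
            _, _, truth = simulate_groseq(genes, cfg, rng=np.random.default_rng(seed))
            totals.append(truth["sense_reads"].sum())
        mean_len_kb = np.mean([g.length_bp for g in genes]) / 1000
        mu = 100.0 * mean_len_kb * len(genes)
        se = np.sqrt(mu / len(totals))
        assert abs(np.mean(totals) - mu) < 4 * se

    def test_strand_separation(self):
        cfg = small_cfg(antisense_rate=0.0)
        genes, _ = simulate_annotation(cfg)
        plus, minus, _ = simulate_groseq(genes, cfg)
        for g in genes:
            anti = minus if g.body.strand == "+" else plus
            assert anti.integral(g.body.chrom, g.body.start, g.body.end) == 0.0


class TestChipReads:
    def test_no_duplicates_when_rate_zero(self):
        cfg = small_cfg(duplication_rate=0.0)
        genes, truth = simulate_annotation(cfg)
        _, ptruth = simulate_rloop_peaks(genes, cfg, annotation_truth=truth)
        reads = simulate_chip_reads(genes, cfg, "control", ptruth)
        # distinct generated reads may still collide, but only rarely
        assert (reads.counts() > 1).mean() < 0.02

    def test_spikein_fraction_binomial(self):
        cfg = small_cfg(spikein_fraction=0.1, duplication_rate=0.0)
        genes, truth = simulate_annotation(cfg)
        _, ptruth = simulate_rloop_peaks(genes, cfg, annotation_truth=truth)
        reads = simulate_chip_reads(genes, cfg, "control", ptruth)
        n_spike = reads.n_reads("spikein")
        n_total = reads.n_reads()
        se = np.sqrt(0.1 * 0.9 * n_total)
        assert abs(n_spike - 0.1 * n_total) < 4 * se

    def test_depletion_factor_one_is_identity_in_distribution(self):
        cfg = small_cfg(rnaseh1_depletion=1.0, duplication_rate=0.0)
        genes, truth = simulate_annotation(cfg)
        _, ptruth = simulate_rloop_peaks(genes, cfg, annotation_truth=truth)
        a = simulate_chip_reads(genes, cfg, "control", ptruth,
                                rng=np.random.default_rng(5))
        b = simulate_chip_reads(genes, cfg, "rnaseh1", ptruth,
                                rng=np.random.default_rng(5))
        assert a.df.equals(b.df)  # identical parameters, identical stream

    def test_duplicates_survive_dedup_cap(self):
        cfg = small_cfg(duplication_rate=0.4)
        genes, truth = simulate_annotation(cfg)
        _, ptruth = simulate_rloop_peaks(genes, cfg, annotation_truth=truth)
        reads = simulate_chip_reads(genes, cfg, "control", ptruth)
        res = deduplicate(reads)
        assert res.removed > 0
        assert res.retained.counts().max() <= res.threshold

    def test_unknown_condition_rejected(self, simple_genes):
        with pytest.raises(ValidationError):
            simulate_chip_reads(simple_genes, small_cfg(), "knockout")


class TestConfigValidation:
    def test_probability_bounds(self):
        with pytest.raises(ValidationError):
            SimulationConfig(p_rloop={"pcg_repressed": 1.5, "active_top": 0.5,
                                      "inactive_bottom": 0.0})

    def test_spacing_must_exceed_window(self):
        with pytest.raises(ValidationError):
            simulate_annotation(small_cfg(min_spacing_bp=1500))
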