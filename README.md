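# rloopkit

Analysis toolkit for studying how R-loops (co-transcriptional RNA–DNA
hybrids) relate to Polycomb (PcG) repression in embryonic stem cells. It
re-implements, as a tested and reusable pipeline, the quantitative layer
of that analysis:

- **Duplicate-read thresholding** — read signatures (chrom, start, end,
  strand) occurring more often than the nearest-rank **95th percentile**
  of the per-signature frequency distribution are trimmed.
- **Exogenous spike-in normalization** — ChIP signal is scaled by
  `10^6 / n_spikein`, so the normalized depth is
  `n_target / n_spikein × 10^6`, making samples with different IP
  efficiencies comparable (spike-in chromatin is added in fixed
  proportion to cell number).
- **R-loop gene classification** — a gene is *R-loop positive* when a
  DRIP peak overlaps its window (1 kb before the TSS to 1 kb after the
  TES); positive genes whose windows overlap another positive gene's
  window are *uncertain due to proximity*; all others are negative.
- **Nascent-transcription calls** — sense-strand RPKM from stranded
  run-on (GRO-seq-style) coverage: reads mapped in the sense of the gene,
  TSS to TES, per kb of gene length per million mapped reads; genes with
  RPKM > 0.1 are nascent-positive. Top/bottom 15% expression classes are
  ranked among genes negative for Polycomb marks.
- **Meta-gene profiles and statistics** — average coverage in 10-bp bins
  around TSS/TES; Wilcoxon rank-sum (exact enumeration for small tie-free
  samples, tie- and continuity-corrected normal approximation otherwise)
  and the two-tailed unpaired Student t test with `*`/`**`/`***` at
  0.05/0.01/0.001.
- **qPCR percent input** — dilution-adjusted ΔCt:
  `%input = 100 × 2^((Ct_input − log2(1/input_fraction)) − Ct_IP)`.

A synthetic-data generator plants known gene classes, R-loop statuses,
transcription rates, spike-in fractions, PCR duplicates and qPCR
enrichments, so every stage is verified by parameter recovery.

## Worked example

```python
from rloopkit import (SimulationConfig, simulate_annotation,
                      simulate_rloop_peaks, classify_rloop, group_proportions)

cfg = SimulationConfig(
    n_genes={"pcg_repressed": 400, "active_top": 400, "inactive_bottom": 400},
    chrom_size=20_000_000, window_overlap_fraction=0.1, seed=42)
genes, truth = simulate_annotation(cfg)
peaks, _ = simulate_rloop_peaks(genes, cfg, annotation_truth=truth)
print(group_proportions(classify_rloop(genes, peaks), genes).round(3))
```

prints

```
                 positive  uncertain_proximity  negative  n_genes
active_top          0.728                0.028     0.245      400
inactive_bottom     0.042                0.000     0.958      400
pcg_repressed       0.205                0.012     0.782      400
```

Each row is one gene class; `positive` is the fraction of genes whose
±1 kb window holds a DRIP peak and is not shared with another positive
gene, `uncertain_proximity` the fraction whose window overlaps another
positive gene's window. The positive + uncertain fractions recover the
planted R-loop rates (0.76 / 0.25 / 0.05) to within sampling error.

The `examples/` directory holds one short script per capability
(classification, spike-in normalization, nascent RPKM and intersection,
meta-gene profiles, qPCR); each prints its numbers with a note on what
they mean. A thin CLI exposes the same stages
(`rloopkit run-all --seed 5 --out run/`, plus `simulate`, `dedup`,
`normalize`, `classify-rloops`, `nascent-rpkm`, `intersect`, `profile`,
`boxplot-stats`, `qpcr`).

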