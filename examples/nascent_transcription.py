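"""Sense-strand nascent-RNA RPKM and the R-loop x nascent-RNA intersection.

Simulates stranded run-on coverage, computes per-gene RPKM (reads mapped in
the sense of the gene, TSS to TES, per kb per million mapped), calls
positivity at RPKM > 0.1, and crosses the calls with R-loop status among
Polycomb-repressed genes.
"""

from rloopkit import (
    SimulationConfig,
    classify_rloop,
    expression_table,
    intersection_counts,
    simulate_annotation,
    simulate_groseq,
    simulate_rloop_peaks,
    wilcoxon_rank_sum,
)

cfg = SimulationConfig(seed=11)
genes, truth = simulate_annotation(cfg)
peaks, _ = simulate_rloop_peaks(genes, cfg, annotation_truth=truth)
plus, minus, _ = simulate_groseq(genes, cfg)

calls = classify_rloop(genes, peaks)
expr = expression_table(plus, minus, genes, read_length_bp=cfg.read_length_bp)
counts = intersection_counts(calls, expr, genes, "pcg_repressed")
print(counts.round(2).to_string())

status = {c.gene_id: c.status for c in calls}
rpkm = {e.gene_id: e.rpkm for e in expr}
pcg = [g for g in genes if g.class_label == "pcg_repressed"]
pos = [rpkm[g.gene_id] for g in pcg if status[g.gene_id] == "positive"]
neg = [rpkm[g.gene_id] for g in pcg if status[g.gene_id] == "negative"]
_, p = wilcoxon_rank_sum(pos, neg)
print(f"\nWilcoxon rank-sum p (R-loop+ vs R-loop- PcG RPKM): {p:.3f}")
# Only part of the Polycomb class shows detectable nascent RNA, and of those
# genes a minority carries an R-loop; the non-significant p-value reflects
# that both R-loop groups were simulated at the same transcription rate.
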