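"""End-to-end orchestration: simulate -> dedup -> normalize -> classify ->
RPKM -> intersect -> profiles -> statistics, with a JSON summary.

Every stage is a pure function of its inputs, the analysis parameters
and the seed; re-running with the same configuration reproduces the
summary byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import io as gio
from .dedup import deduplicate, normalization_factors, window_signal
from .expression import expression_table, intersection_counts
from .intervals import ValidationError
from .rloops import calls_to_frame, classify_rloop, group_proportions
from .simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_chip_reads,
    simulate_groseq,
    simulate_rloop_peaks,
)
from .stats import wilcoxon_rank_sum

log = logging.getLogger("rloopkit")


@dataclass
class AnalysisParams:
    """Tunable constants of the analysis, with their standard defaults."""

    flank_bp: int = 1000  # gene window flank for R-loop classification
    tss_window_bp: int = 1000  # window for normalized ChIP signal
    profile_bin_bp: int = 10
    rpkm_threshold: float = 0.1  # nascent positivity cutoff
    rank_fraction: float = 0.15  # top/bottom expression class size
    dedup_percentile: float = 95.0
    alpha_levels: tuple = (0.05, 0.01, 0.001)
    seed: int = 0


def run_pipeline(
    out_dir,
    params: Optional[AnalysisParams] = None,
    sim: Optional[SimulationConfig] = None,
) -> Dict:
    """Run the full synthetic analysis and write all stage outputs.

    With ``sim`` given (the usual mode) the inputs are generated; the run
    directory receives the gene table, peaks, truth sidecars, stranded
    bedGraphs, per-gene classification/expression/signal tables and a
    ``summary.json`` with the headline statistics.
    """
    params = params or AnalysisParams()
    sim = sim or SimulationConfig(seed=params.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(sim.seed)

    log.info("stage simulate: %d genes", sum(sim.n_genes.values()))
    genes, ann_truth = simulate_annotation(sim, rng)
    peaks, rloop_truth = simulate_rloop_peaks(genes, sim, rng, ann_truth)
    plus, minus, gro_truth = simulate_groseq(genes, sim, rng)
    reads_ctrl = simulate_chip_reads(genes, sim, "control", rloop_truth, rng)
    reads_rh = simulate_chip_reads(genes, sim, "rnaseh1", rloop_truth, rng)

    gio.write_gene_table(genes, out / "genes.tsv")
    gio.write_bed(peaks, out / "rloop_peaks.bed")
    ann_truth.merge(rloop_truth, on="gene_id").to_csv(
        out / "truth_rloops.tsv", sep="\t", index=False
    )
    gro_truth.to_csv(out / "truth_groseq.tsv", sep="\t", index=False)
    gio.write_bedgraph(plus, out / "groseq_plus.bedgraph")
    gio.write_bedgraph(minus, out / "groseq_minus.bedgraph")

    log.info("stage classify: %d peaks", len(peaks))
    calls = classify_rloop(genes, peaks, params.flank_bp)
    calls_to_frame(calls).to_csv(out / "rloop_calls.tsv", sep="\t", index=False)
    proportions = group_proportions(calls, genes)
    proportions.to_csv(out / "rloop_proportions.tsv", sep="\t")

    log.info("stage expression")
    expr = expression_table(
        plus, minus, genes, sim.read_length_bp, params.rpkm_threshold
    )
    pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in expr],
            "rpkm": [e.rpkm for e in expr],
            "nascent_positive": [e.nascent_positive for e in expr],
        }
    ).to_csv(out / "nascent_rpkm.tsv", sep="\t", index=False)
    counts = intersection_counts(calls, expr, genes)

    status = {c.gene_id: c.status for c in calls}
    rpkm_by_id = {e.gene_id: e.rpkm for e in expr}
    pcg = [g for g in genes if g.class_label == "pcg_repressed"]
    rpos = [rpkm_by_id[g.gene_id] for g in pcg if status[g.gene_id] == "positive"]
    rneg = [rpkm_by_id[g.gene_id] for g in pcg if status[g.gene_id] == "negative"]
    if rpos and rneg:
        _, wilcoxon_p = wilcoxon_rank_sum(rpos, rneg)
    else:
        wilcoxon_p = float("nan")

    log.info("stage dedup+normalize: %d / %d reads", len(reads_ctrl), len(reads_rh))
    medians = {}
    for name, coll in (("control", reads_ctrl), ("rnaseh1", reads_rh)):
        ded = deduplicate(coll, params.dedup_percentile)
        factors = normalization_factors(ded.retained)
        sig = window_signal(ded.retained, genes, factors, params.tss_window_bp)
        sig.to_csv(out / f"tss_signal_{name}.tsv", sep="\t", header=True)
        with open(out / f"factors_{name}.json", "w") as fh:
            json.dump(
                {
                    "n_target": factors.n_target,
                    "n_spikein": factors.n_spikein,
                    "per_read_weight": factors.per_read_weight,
                    "normalized_depth": factors.normalized_depth,
                    "dedup_threshold": ded.threshold,
                    "dedup_removed": ded.removed,
                },
                fh,
                indent=2,
            )
        medians[name] = {
            "rloop_pos_pcg": float(
                np.median([sig[g.gene_id] for g in pcg if status[g.gene_id] == "positive"])
            ),
            "active": float(
                np.median(
                    [sig[g.gene_id] for g in genes if g.class_label == "active_top"]
                )
            ),
        }

    summary = {
        "n_genes": len(genes),
        "rloop_proportions": proportions.to_dict(orient="index"),
        "intersection_counts": {k: float(v) for k, v in counts.items()},
        "wilcoxon_p_rloop_pos_vs_neg_pcg_rpkm": wilcoxon_p,
        "median_tss_signal": medians,
        "seed": sim.seed,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", out / "summary.json")
    return summary
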