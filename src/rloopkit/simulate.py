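"""Synthetic data with planted ground truth for parameter-recovery tests.

The generator emulates the structure of the real inputs: a gene
annotation with three classes (Polycomb-repressed, highly active,
inactive), DRIP-style R-loop peaks planted on a controlled fraction of
each class, stranded nascent-RNA coverage with class-dependent intensity,
ChIP read collections mixed with exogenous spike-in reads and PCR
duplicates, and qPCR Ct tables with known enrichment.  Every generator is
deterministic under a fixed seed and emits a machine-readable truth table
so downstream calls can be checked against what was planted.

Spike-in reads live on chromosomes named ``spike_*``, mirroring a
combined-genome (mouse + fly) alignment without modelling alignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dedup import SPIKEIN_PREFIX, ReadCollection
from .intervals import (
    GeneRecord,
    GenomicInterval,
    SignalTrack,
    ValidationError,
    coverage_from_reads,
)
from .qpcr import QpcrSample

SIM_CLASSES = ("pcg_repressed", "active_top", "inactive_bottom")


class SizingError(ValueError):
    """Raised when the configured genome cannot hold the requested genes."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic genome.

    Defaults mirror the class structure of the real analysis: R-loops at
    76% of active genes, 25% of Polycomb-repressed genes and 5% of
    inactive genes; nascent transcription high at active genes, low but
    non-zero at Polycomb-repressed genes (identical for R-loop-positive
    and -negative members of the class) and near-absent at inactive genes.
    """

    n_genes: Dict[str, int] = field(
        default_factory=lambda: {
            "pcg_repressed": 300,
            "active_top": 300,
            "inactive_bottom": 300,
        }
    )
    chrom_size: int = 30_000_000
    n_chromosomes: int = 2
    gene_length_range: Tuple[int, int] = (3000, 10000)
    min_spacing_bp: int = 3000  # > 2 * flank_bp: isolated windows never touch
    window_overlap_fraction: float = 0.0  # fraction of genes in planted close pairs
    flank_bp: int = 1000
    p_rloop: Dict[str, float] = field(
        default_factory=lambda: {
            "pcg_repressed": 0.25,
            "active_top": 0.76,
            "inactive_bottom": 0.05,
        }
    )
    peak_width_bp: int = 300
    nascent_rate: Dict[str, float] = field(
        default_factory=lambda: {
            # reads/kb; PcG rate is low enough that only part of the class
            # has detectable nascent RNA, as run-on data show
            "pcg_repressed": 0.1,
            "active_top": 50.0,
            "inactive_bottom": 0.01,
        }
    )
    antisense_rate: float = 0.2  # reads/kb background on the opposite strand
    read_length_bp: int = 50
    chip_enrichment: Dict[str, float] = field(
        default_factory=lambda: {
            "pcg_repressed": 8.0,  # fold over background, EZH2-like antibody
            "active_top": 2.0,
            "inactive_bottom": 1.0,
        }
    )
    chip_background_per_window: float = 20.0  # mean background reads per TSS window
    chip_genome_background_per_kb: float = 0.02
    chip_fragment_range: Tuple[int, int] = (150, 350)  # sonicated fragment lengths
    rnaseh1_depletion: float = 0.5  # enrichment multiplier at R-loop+ PcG genes
    spikein_fraction: float = 0.1
    spikein_chrom_size: int = 1_000_000
    duplication_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in self.p_rloop.items():
            if not 0 <= p <= 1:
                raise ValidationError(f"p_rloop[{name}] must be in [0,1]")
        if not 0 <= self.spikein_fraction < 1:
            raise ValidationError("spikein_fraction must be in [0,1)")
        if not 0 <= self.duplication_rate < 1:
            raise ValidationError("duplication_rate must be in [0,1)")
        if not 0 <= self.window_overlap_fraction <= 1:
            raise ValidationError("window_overlap_fraction must be in [0,1]")
        if any(r < 0 for r in self.nascent_rate.values()):
            raise ValidationError("nascent rates must be >= 0")


def simulate_annotation(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[List[GeneRecord], pd.DataFrame]:
    """Place non-nested genes of three classes on the synthetic genome.

    A ``window_overlap_fraction`` of genes is laid out in close pairs
    whose +/-1 kb windows overlap (inter-body gap < 2 * flank_bp),
    exercising the proximity rule; all other genes are spaced at least
    ``min_spacing_bp`` apart so their windows are isolated.

    Returns the genes plus a truth table with columns ``gene_id``,
    ``class_label`` and ``pair_id`` (-1 for isolated genes).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if cfg.min_spacing_bp <= 2 * cfg.flank_bp:
        raise ValidationError("min_spacing_bp must exceed 2 * flank_bp")
    labels = [c for c in SIM_CLASSES for _ in range(cfg.n_genes.get(c, 0))]
    n_total = len(labels)
    order = rng.permutation(n_total)
    labels = [labels[i] for i in order]

    n_paired = int(round(cfg.window_overlap_fraction * n_total))
    n_pairs = n_paired // 2

    # layout units: first n_pairs units hold two genes each, rest are singles
    units: List[List[int]] = []
    idx = 0
    for _ in range(n_pairs):
        units.append([idx, idx + 1])
        idx += 2
    while idx < n_total:
        units.append([idx])
        idx += 1

    lo, hi = cfg.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n_total)
    genes: List[Optional[GeneRecord]] = [None] * n_total
    pair_ids = np.full(n_total, -1, dtype=int)
    cursors = [cfg.flank_bp] * cfg.n_chromosomes
    for u, unit in enumerate(units):
        chrom_i = u % cfg.n_chromosomes
        chrom = f"chr{chrom_i + 1}"
        pos = cursors[chrom_i] + int(rng.integers(0, cfg.min_spacing_bp))
        for j, gi in enumerate(unit):
            if j > 0:
                # gap small enough that the two +/-1 kb windows overlap
                gap = int(rng.integers(1, 2 * cfg.flank_bp - 1))
                pos = genes[unit[j - 1]].body.end + gap
                pair_ids[unit[0]] = u
                pair_ids[gi] = u
            strand = "+" if rng.random() < 0.5 else "-"
            body = GenomicInterval(chrom, pos, pos + int(lengths[gi]), strand)
            genes[gi] = GeneRecord(f"g{gi:05d}", body, labels[gi])
            pos = body.end
        cursors[chrom_i] = pos + cfg.min_spacing_bp
        if cursors[chrom_i] > cfg.chrom_size:
            raise SizingError(
                f"genome too small: chromosome {chrom} needs {cursors[chrom_i]} bp "
                f"but chrom_size is {cfg.chrom_size}"
            )
    gene_list = [g for g in genes if g is not None]
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in gene_list],
            "class_label": [g.class_label for g in gene_list],
            "pair_id": pair_ids,
        }
    )
    return gene_list, truth


def simulate_rloop_peaks(
    genes: Sequence[GeneRecord],
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    annotation_truth: Optional[pd.DataFrame] = None,
) -> Tuple[List[GenomicInterval], pd.DataFrame]:
    """Plant one DRIP peak inside the body of each gene drawn R-loop positive.

    For genes in planted close pairs the peak is confined to the part of
    the body outside the partner's window, so a peak never makes the
    partner positive by itself.  The truth table records, per gene, the
    planted positivity and the expected classification outcome
    (``uncertain_proximity`` when both members of a close pair are
    positive, since their windows overlap by construction).
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    pair_of: Dict[str, int] = {}
    if annotation_truth is not None:
        pair_of = dict(zip(annotation_truth["gene_id"], annotation_truth["pair_id"]))
    partners: Dict[str, GeneRecord] = {}
    by_pair: Dict[int, List[GeneRecord]] = {}
    for g in genes:
        pid = pair_of.get(g.gene_id, -1)
        if pid >= 0:
            by_pair.setdefault(pid, []).append(g)
    for members in by_pair.values():
        if len(members) == 2:
            partners[members[0].gene_id] = members[1]
            partners[members[1].gene_id] = members[0]

    planted = {g.gene_id: bool(rng.random() < cfg.p_rloop[g.class_label]) for g in genes}
    peaks: List[GenomicInterval] = []
    for g in genes:
        if not planted[g.gene_id]:
            continue
        span0, span1 = g.body.start, g.body.end
        partner = partners.get(g.gene_id)
        if partner is not None:
            pw0 = max(0, partner.body.start - cfg.flank_bp)
            pw1 = partner.body.end + cfg.flank_bp
            if pw0 > span0:  # partner to the right: keep the left part of the body
                span1 = min(span1, pw0)
            else:  # partner to the left
                span0 = max(span0, pw1)
        if span1 <= span0:
            raise SizingError(
                f"gene {g.gene_id}: no room for a peak outside the partner window; "
                "increase gene_length_range"
            )
        width = min(cfg.peak_width_bp, span1 - span0)
        start = int(rng.integers(span0, span1 - width + 1))
        peaks.append(GenomicInterval(g.body.chrom, start, start + width))

    expected = []
    for g in genes:
        if not planted[g.gene_id]:
            expected.append("negative")
            continue
        partner = partners.get(g.gene_id)
        if partner is not None and planted[partner.gene_id]:
            expected.append("uncertain_proximity")
        else:
            expected.append("positive")
    truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "planted_positive": [planted[g.gene_id] for g in genes],
            "expected_status": expected,
        }
    )
    return peaks, truth


def simulate_groseq(
    genes: Sequence[GeneRecord],
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[SignalTrack, SignalTrack, pd.DataFrame]:
    """Stranded nascent-RNA coverage with class-dependent intensity.

    Sense reads per gene are Poisson(nascent_rate * length_kb), placed
    uniformly over the gene body on the gene's strand; a low antisense
    background is placed on the opposite strand.  Reads are kept entirely
    within the body, so the sense coverage integral over the body equals
    (read count) * read_length exactly.  Returns plus track, minus track
    and a truth table of per-gene sense read counts.
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    per_strand: Dict[str, Dict[str, List[np.ndarray]]] = {"+": {}, "-": {}}
    totals = {"+": 0, "-": 0}
    truth_counts = []
    rl = cfg.read_length_bp
    for g in genes:
        length_kb = g.length_bp / 1000.0
        n_sense = int(rng.poisson(cfg.nascent_rate[g.class_label] * length_kb))
        n_anti = int(rng.poisson(cfg.antisense_rate * length_kb))
        truth_counts.append(n_sense)
        hi = g.body.end - rl
        for strand, n in ((g.body.strand, n_sense), ("-" if g.body.strand == "+" else "+", n_anti)):
            if n == 0 or hi <= g.body.start:
                continue
            starts = rng.integers(g.body.start, hi + 1, size=n)
            per_strand[strand].setdefault(g.body.chrom, []).append(starts)
            totals[strand] += n
    tracks = {}
    for strand in ("+", "-"):
        data = {}
        for chrom, chunks in per_strand[strand].items():
            starts = np.concatenate(chunks)
            s, e, v = coverage_from_reads(starts, starts + rl)
            data[chrom] = (s, e, v)
        tracks[strand] = SignalTrack(data, strand=strand, total_mapped=totals[strand])
    truth = pd.DataFrame(
        {"gene_id": [g.gene_id for g in genes], "sense_reads": truth_counts}
    )
    return tracks["+"], tracks["-"], truth


def simulate_chip_reads(
    genes: Sequence[GeneRecord],
    cfg: SimulationConfig,
    condition: str = "control",
    rloop_truth: Optional[pd.DataFrame] = None,
    rng: Optional[np.random.Generator] = None,
) -> ReadCollection:
    """ChIP read collection with spike-in reads and PCR duplicates.

    Each gene's 1-kb TSS window receives Poisson(background * enrichment)
    reads; under ``condition='rnaseh1'`` the enrichment of R-loop-positive
    Polycomb-repressed genes (per ``rloop_truth``) is multiplied by the
    depletion factor.  Uniform genome-wide background is added, spike-in
    reads are appended so they make up ``spikein_fraction`` of the
    collection in expectation, and every read receives
    1 + Geometric(duplication_rate) copies (failure-count convention:
    zero extra copies with probability 1 - duplication_rate).
    """
    if condition not in ("control", "rnaseh1"):
        raise ValidationError("condition must be 'control' or 'rnaseh1'")
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    frag_lo, frag_hi = cfg.chip_fragment_range
    rloop_pos = set()
    if rloop_truth is not None:
        mask = rloop_truth["planted_positive"].astype(bool)
        rloop_pos = set(rloop_truth.loc[mask, "gene_id"])

    chroms: List[str] = []
    starts: List[np.ndarray] = []
    for g in genes:
        lam = cfg.chip_background_per_window * cfg.chip_enrichment[g.class_label]
        if (
            condition == "rnaseh1"
            and g.class_label == "pcg_repressed"
            and g.gene_id in rloop_pos
        ):
            lam *= cfg.rnaseh1_depletion
        n = int(rng.poisson(lam))
        if n == 0:
            continue
        w0 = max(0, g.tss - 500)
        w1 = max(w0 + 1, g.tss + 500 - frag_lo)
        chroms.extend([g.body.chrom] * n)
        starts.append(rng.integers(w0, w1, size=n))
    # flat genome-wide background
    for ci in range(cfg.n_chromosomes):
        n_bg = int(rng.poisson(cfg.chip_genome_background_per_kb * cfg.chrom_size / 1000.0))
        if n_bg:
            chroms.extend([f"chr{ci + 1}"] * n_bg)
            starts.append(rng.integers(0, cfg.chrom_size - frag_hi, size=n_bg))
    start_arr = np.concatenate(starts) if starts else np.empty(0, dtype=np.int64)
    n_target = len(start_arr)

    f = cfg.spikein_fraction
    if f > 0 and n_target > 0:
        # spike-in chromatin is added in fixed proportion to cell number,
        # so its expected read count does not depend on the condition
        expected_target = sum(
            cfg.chip_background_per_window * cfg.chip_enrichment[g.class_label]
            for g in genes
        ) + cfg.n_chromosomes * cfg.chip_genome_background_per_kb * cfg.chrom_size / 1000.0
        n_planned = int(round(expected_target / (1 - f)))
        n_spike = int(rng.binomial(n_planned, f))
        spike_starts = rng.integers(0, cfg.spikein_chrom_size - frag_hi, size=n_spike)
        chroms.extend([f"{SPIKEIN_PREFIX}chr1"] * n_spike)
        start_arr = np.concatenate([start_arr, spike_starts])

    frag_lens = rng.integers(frag_lo, frag_hi + 1, size=len(start_arr))
    strands = np.where(rng.random(len(start_arr)) < 0.5, "+", "-")
    # PCR duplicates: geometric number of extra copies per original read
    copies = 1 + (rng.geometric(1 - cfg.duplication_rate, size=len(start_arr)) - 1)
    chrom_arr = np.asarray(chroms)
    rep = np.repeat(np.arange(len(start_arr)), copies)
    return ReadCollection.from_reads(
        chrom_arr[rep], start_arr[rep], start_arr[rep] + frag_lens[rep], strands[rep]
    )


def simulate_qpcr(
    true_percent_input: float,
    ct_noise_sd: float = 0.0,
    input_dilution: float = 1.0,
    n_replicates: int = 3,
    seed: int = 0,
    target_id: str = "amplicon",
    condition: str = "mock",
    base_input_ct: float = 20.0,
    rng: Optional[np.random.Generator] = None,
) -> List[QpcrSample]:
    """Ct tables with known percent-input enrichment.

    The measured input Ct reflects the diluted input aliquot
    (``base_input_ct + log2(1/dilution)``); the IP Ct is the
    dilution-adjusted input Ct minus log2(true%/100), plus Gaussian
    noise on both measurements.  At zero noise ``percent_input`` inverts
    this construction exactly for any dilution.
    """
    if true_percent_input <= 0:
        raise ValidationError("true_percent_input must be > 0")
    if not (0 < input_dilution <= 1):
        raise ValidationError("input_dilution must be in (0, 1]")
    rng = np.random.default_rng(seed) if rng is None else rng
    samples = []
    for rep in range(n_replicates):
        ct_input = base_input_ct + math.log2(1.0 / input_dilution) + rng.normal(0, ct_noise_sd)
        adjusted = ct_input - math.log2(1.0 / input_dilution)
        ct_ip = adjusted - math.log2(true_percent_input / 100.0) + rng.normal(0, ct_noise_sd)
        samples.append(
            QpcrSample(
                target_id=target_id,
                condition=condition,
                ct_ip=ct_ip,
                ct_input=ct_input,
                input_fraction=input_dilution,
                replicate=rep,
            )
        )
    return samples
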