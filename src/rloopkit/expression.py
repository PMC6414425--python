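"""Nascent-transcription RPKM from stranded run-on coverage.

RPKM is the number of reads mapped in the sense of the gene, from TSS to
TES, per kilobase of gene length per million mapped reads.  Genes with
RPKM strictly above 0.1 are called nascent-positive.  The library size is
the total mapped reads on both strands (sense plus antisense tracks).
Because bedGraph coverage has no read boundaries, reads are counted as
the coverage integral divided by the read length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GeneRecord, SignalTrack, ValidationError
from .rloops import RloopCall

RPKM_THRESHOLD = 0.1


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    sense_reads: float
    length_kb: float
    library_millions: float
    rpkm: float
    nascent_positive: bool


def nascent_rpkm(
    track_plus: SignalTrack,
    track_minus: SignalTrack,
    gene: GeneRecord,
    read_length_bp: float = 1.0,
    rpkm_threshold: float = RPKM_THRESHOLD,
) -> ExpressionRecord:
    """Sense-strand RPKM for one gene from a pair of stranded tracks.

    The sense track is chosen by gene strand; positivity is strict
    (``rpkm > rpkm_threshold``).
    """
    sense = track_plus if gene.body.strand == "+" else track_minus
    library = track_plus.total_mapped + track_minus.total_mapped
    if library <= 0:
        raise ValidationError("zero library size")
    lo, hi = min(gene.tss, gene.tes), max(gene.tss, gene.tes)
    sense_reads = sense.integral(gene.body.chrom, lo, hi) / read_length_bp
    length_kb = gene.length_bp / 1000.0
    rpkm = sense_reads / (length_kb * library / 1e6)
    return ExpressionRecord(
        gene_id=gene.gene_id,
        sense_reads=sense_reads,
        length_kb=length_kb,
        library_millions=library / 1e6,
        rpkm=rpkm,
        nascent_positive=bool(rpkm > rpkm_threshold),
    )


def expression_table(
    track_plus: SignalTrack,
    track_minus: SignalTrack,
    genes: Sequence[GeneRecord],
    read_length_bp: float = 1.0,
    rpkm_threshold: float = RPKM_THRESHOLD,
) -> List[ExpressionRecord]:
    return [
        nascent_rpkm(track_plus, track_minus, g, read_length_bp, rpkm_threshold)
        for g in genes
    ]


def expression_rank_classes(
    fpkm: Dict[str, float], eligible: Sequence[str], fraction: float = 0.15
) -> Tuple[List[str], List[str]]:
    """Top/bottom expression classes among an eligible gene subset.

    ``eligible`` is the set of genes negative for Polycomb marks; each
    returned set has ``floor(fraction * len(eligible))`` genes.  Ties are
    broken by ascending gene_id so the split is deterministic.
    """
    if not (0 < fraction < 0.5):
        raise ValidationError("fraction must be in (0, 0.5)")
    if not eligible:
        raise ValidationError("eligible gene set is empty")
    k = int(np.floor(fraction * len(eligible)))
    ordered = sorted(eligible, key=lambda gid: (fpkm[gid], gid))
    bottom = sorted(ordered[:k])
    top = sorted(ordered[len(ordered) - k:])
    return top, bottom


def intersection_counts(
    calls: Sequence[RloopCall],
    expr: Sequence[ExpressionRecord],
    genes: Sequence[GeneRecord],
    gene_class: str = "pcg_repressed",
    exclude_uncertain: bool = True,
) -> pd.Series:
    """Joint nascent-RNA x R-loop counts among one gene class.

    Returns counts for the four cells of the 2x2 table plus two derived
    percentages: nascent-positive genes as a fraction of the class, and
    R-loop-positive among the nascent-positive.  Genes called
    ``uncertain_proximity`` are dropped from the table by default.
    """
    status = {c.gene_id: c.status for c in calls}
    nascent = {e.gene_id: e.nascent_positive for e in expr}
    ids = [g.gene_id for g in genes if g.class_label == gene_class]
    if exclude_uncertain:
        ids = [i for i in ids if status.get(i) != "uncertain_proximity"]
    both = sum(1 for i in ids if nascent[i] and status[i] == "positive")
    nascent_only = sum(1 for i in ids if nascent[i] and status[i] != "positive")
    rloop_only = sum(1 for i in ids if not nascent[i] and status[i] == "positive")
    neither = len(ids) - both - nascent_only - rloop_only
    n_nascent = both + nascent_only
    pct_nascent = 100.0 * n_nascent / len(ids) if ids else float("nan")
    if n_nascent == 0:
        warnings.warn("no nascent-positive genes; R-loop fraction undefined")
        pct_rloop_of_nascent = float("nan")
    else:
        pct_rloop_of_nascent = 100.0 * both / n_nascent
    return pd.Series(
        {
            "nascent_and_rloop": both,
            "nascent_only": nascent_only,
            "rloop_only": rloop_only,
            "neither": neither,
            "n_genes": len(ids),
            "pct_nascent_positive": pct_nascent,
            "pct_rloop_among_nascent": pct_rloop_of_nascent,
        }
    )
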