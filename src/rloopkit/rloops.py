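"""Classify genes as R-loop positive, negative or uncertain-due-to-proximity.

A gene is R-loop positive when at least one DRIP peak overlaps its window,
defined as the region from 1 kb before the TSS to 1 kb after the TES
(equivalently the gene body extended by 1 kb on both sides, for either
strand).  A positive gene whose window overlaps another positive gene's
window cannot be unambiguously attributed the shared peak signal and is
reassigned ``uncertain_proximity``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .intervals import GeneRecord, GenomicInterval, ValidationError

STATUSES = ("positive", "negative", "uncertain_proximity")


@dataclass(frozen=True)
class RloopCall:
    gene_id: str
    window: GenomicInterval
    status: str
    n_overlapping_peaks: int

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValidationError(f"unknown status {self.status!r}")
        if self.status == "negative" and self.n_overlapping_peaks != 0:
            raise ValidationError("negative call with overlapping peaks")
        if self.status != "negative" and self.n_overlapping_peaks < 1:
            raise ValidationError(f"{self.status} call without overlapping peaks")


def gene_window(gene: GeneRecord, flank_bp: int = 1000) -> GenomicInterval:
    """Gene body extended ``flank_bp`` both sides, clipped at 0 (strand-free span)."""
    if flank_bp < 0:
        raise ValidationError("flank_bp must be >= 0")
    return GenomicInterval(
        gene.body.chrom,
        max(0, gene.body.start - flank_bp),
        gene.body.end + flank_bp,
        gene.body.strand,
    )


def classify_rloop(
    genes: Sequence[GeneRecord],
    peaks: Sequence[GenomicInterval],
    flank_bp: int = 1000,
    proximity_basis: str = "gene",
) -> List[RloopCall]:
    """Assign each gene an R-loop status from DRIP peak overlaps.

    Peaks on either strand count (DRIP peaks carry no strand).  With
    ``proximity_basis='gene'`` (default) a positive gene becomes
    ``uncertain_proximity`` when its window overlaps another *positive
    gene's* window; with ``'peak'`` it becomes uncertain when a peak in its
    window also overlaps another positive gene's window.  The two readings
    coincide whenever every shared peak lies in the window intersection.
    Output order matches input order.
    """
    if proximity_basis not in ("gene", "peak"):
        raise ValidationError("proximity_basis must be 'gene' or 'peak'")
    windows = [gene_window(g, flank_bp) for g in genes]
    peak_trees: Dict[str, IntervalTree] = {}
    for p in peaks:
        peak_trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)

    n_peaks = []
    for w in windows:
        tree = peak_trees.get(w.chrom)
        n_peaks.append(len(tree.overlap(w.start, w.end)) if tree else 0)

    positive = [n > 0 for n in n_peaks]

    # windows of the initial positive set; reassignment is one pass -- it
    # cannot create new overlaps
    pos_tree: Dict[str, IntervalTree] = {}
    for i, w in enumerate(windows):
        if positive[i]:
            pos_tree.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end, i)

    calls: List[RloopCall] = []
    for i, (g, w) in enumerate(zip(genes, windows)):
        if not positive[i]:
            calls.append(RloopCall(g.gene_id, w, "negative", 0))
            continue
        tree = pos_tree.get(w.chrom)
        if proximity_basis == "gene":
            others = {hit.data for hit in tree.overlap(w.start, w.end)} - {i}
            uncertain = bool(others)
        else:
            uncertain = False
            for hit in peak_trees.get(w.chrom, IntervalTree()).overlap(w.start, w.end):
                p = hit.data
                shared = {h.data for h in tree.overlap(p.start, p.end)} - {i}
                if shared:
                    uncertain = True
                    break
        status = "uncertain_proximity" if uncertain else "positive"
        calls.append(RloopCall(g.gene_id, w, status, n_peaks[i]))
    return calls


def group_proportions(
    calls: Sequence[RloopCall],
    genes: Sequence[GeneRecord],
    classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-class fractions of positive / uncertain_proximity / negative calls.

    Rows sum to 1; an empty class raises rather than dividing by zero.
    ``classes`` restricts/fixes the reported classes (default: all labels
    present among ``genes``).
    """
    status_by_id = {c.gene_id: c.status for c in calls}
    rows = {}
    labels = list(classes) if classes is not None else sorted({g.class_label for g in genes})
    for label in labels:
        ids = [g.gene_id for g in genes if g.class_label == label]
        if not ids:
            raise ValidationError(f"empty gene class {label!r}")
        statuses = [status_by_id[i] for i in ids]
        n = len(statuses)
        rows[label] = {
            "positive": statuses.count("positive") / n,
            "uncertain_proximity": statuses.count("uncertain_proximity") / n,
            "negative": statuses.count("negative") / n,
            "n_genes": n,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def calls_to_frame(calls: Sequence[RloopCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in calls],
            "status": [c.status for c in calls],
            "n_peaks": [c.n_overlapping_peaks for c in calls],
        }
    )
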