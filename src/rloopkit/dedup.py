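"""PCR-duplicate thresholding and exogenous spike-in normalization.

Duplicated reads are identical read signatures (chrom, start, end, strand)
aligned to the same location.  Signatures occurring more often than a
per-dataset threshold -- the nearest-rank 95th percentile of the
frequency distribution of signature counts -- are trimmed.  Signal is then
made comparable across samples by dividing the target-genome read count by
the spike-in (exogenous genome) read count and multiplying by 1e6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .intervals import GeneRecord, GenomicInterval, ValidationError

SPIKEIN_PREFIX = "spike_"

_SIG_COLS = ["chrom", "start", "end", "strand"]


class NormalizationError(ValueError):
    """Raised when spike-in reads are absent and no scale factor exists."""


class ReadCollection:
    """Multiset of aligned read signatures tagged by genome of origin.

    Backed by a DataFrame with one row per unique signature and a
    ``count`` column; ``genome_tag`` is ``target`` or ``spikein``.
    Spike-in reads live on chromosomes named ``spike_*``, mirroring a
    combined-genome alignment.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        required = _SIG_COLS + ["genome_tag", "count"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"ReadCollection missing columns {missing}")
        if len(df) and (df["count"] < 1).any():
            raise ValidationError("signature counts must be >= 1")
        bad = set(df["genome_tag"].unique()) - {"target", "spikein"}
        if bad:
            raise ValidationError(f"unknown genome_tag values {bad}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_reads(
        cls,
        chroms: Iterable[str],
        starts: Iterable[int],
        ends: Iterable[int],
        strands: Iterable[str],
    ) -> "ReadCollection":
        """Build from one row per read; genome_tag inferred from chromosome name."""
        df = pd.DataFrame(
            {"chrom": list(chroms), "start": list(starts), "end": list(ends), "strand": list(strands)}
        )
        grouped = df.groupby(_SIG_COLS, sort=True).size().reset_index(name="count")
        grouped["genome_tag"] = np.where(
            grouped["chrom"].str.startswith(SPIKEIN_PREFIX), "spikein", "target"
        )
        return cls(grouped)

    @classmethod
    def from_bed(cls, path) -> "ReadCollection":
        from .io import read_bed

        ivs = read_bed(path)
        return cls.from_reads(
            [iv.chrom for iv in ivs],
            [iv.start for iv in ivs],
            [iv.end for iv in ivs],
            [iv.strand for iv in ivs],
        )

    def to_bed(self, path) -> None:
        from .io import write_bed

        ivs, names = [], []
        cols = zip(
            self.df["chrom"], self.df["start"], self.df["end"], self.df["strand"], self.df["count"]
        )
        for chrom, start, end, strand, count in cols:
            for _ in range(int(count)):
                ivs.append(GenomicInterval(chrom, int(start), int(end), strand))
                names.append("read")
        write_bed(ivs, path, names)

    def n_reads(self, genome_tag: Optional[str] = None) -> int:
        df = self.df if genome_tag is None else self.df[self.df["genome_tag"] == genome_tag]
        return int(df["count"].sum())

    def counts(self) -> np.ndarray:
        """Per-signature occurrence counts (the frequency distribution of reads)."""
        return self.df["count"].to_numpy()

    def __len__(self) -> int:
        return self.n_reads()


@dataclass(frozen=True)
class DedupResult:
    threshold: int
    removed: int
    retained: ReadCollection


@dataclass(frozen=True)
class NormalizationFactors:
    """Spike-in scale factors: weight 1e6 / n_spikein per target read."""

    n_target: int
    n_spikein: int

    def __post_init__(self) -> None:
        if self.n_spikein <= 0:
            raise NormalizationError(
                "no spike-in reads in dataset; spike-in normalization impossible"
            )

    @property
    def per_read_weight(self) -> float:
        return 1e6 / self.n_spikein

    @property
    def normalized_depth(self) -> float:
        return self.n_target / self.n_spikein * 1e6


def nearest_rank_percentile(values: np.ndarray, percentile: float = 95.0) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th order statistic."""
    values = np.sort(np.asarray(values))
    if len(values) == 0:
        raise ValidationError("cannot take percentile of empty collection")
    rank = max(1, math.ceil(percentile / 100.0 * len(values)))
    return float(values[rank - 1])


def dedup_threshold(reads: ReadCollection, percentile: float = 95.0) -> int:
    """Duplicate cap: nearest-rank percentile of per-signature counts, min 1.

    Computed on the full dataset (target plus spike-in signatures
    together), one threshold per dataset.
    """
    if len(reads.df) == 0:
        raise ValidationError("empty read collection")
    return max(1, int(nearest_rank_percentile(reads.counts(), percentile)))


def deduplicate(
    reads: ReadCollection,
    percentile: float = 95.0,
    mode: str = "cap",
    threshold: Optional[int] = None,
) -> DedupResult:
    """Trim signatures occurring more often than the duplicate threshold.

    ``mode='cap'`` (default) keeps ``threshold`` copies of an
    over-threshold signature and removes only the excess; ``mode='drop'``
    removes the entire signature group.  The threshold is computed once on
    the whole collection and applied to every signature regardless of
    genome tag.
    """
    if mode not in ("cap", "drop"):
        raise ValidationError("mode must be 'cap' or 'drop'")
    thr = threshold if threshold is not None else dedup_threshold(reads, percentile)
    df = reads.df.copy()
    over = df["count"] > thr
    if mode == "cap":
        removed = int((df.loc[over, "count"] - thr).sum())
        df.loc[over, "count"] = thr
    else:
        removed = int(df.loc[over, "count"].sum())
        df = df[~over]
    return DedupResult(threshold=thr, removed=removed, retained=ReadCollection(df))


def normalization_factors(reads: ReadCollection) -> NormalizationFactors:
    """Spike-in scale factors from a (deduplicated) read collection."""
    return NormalizationFactors(
        n_target=reads.n_reads("target"), n_spikein=reads.n_reads("spikein")
    )


def window_signal(
    reads: ReadCollection,
    genes: List[GeneRecord],
    factors: NormalizationFactors,
    window_bp: int = 1000,
) -> pd.Series:
    """Spike-in-normalized read count in a window centered on each TSS.

    The window is ``[tss - window_bp/2, tss + window_bp/2)`` clipped at 0;
    a read counts if it overlaps the window by >= 1 base.  Each target read
    contributes ``per_read_weight``.
    """
    if window_bp % 2:
        raise ValidationError("window_bp must be even")
    half = window_bp // 2
    target = reads.df[reads.df["genome_tag"] == "target"]
    by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in target.groupby("chrom"):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cnts = sub["count"].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts, ends, cnts = starts[order], ends[order], cnts[order]
        # cumulative counts indexed alongside start-sorted reads; ends sorted
        # separately for the complementary searchsorted
        end_order = np.argsort(ends, kind="stable")
        by_chrom[chrom] = (starts, np.sort(ends), cnts, cnts[end_order])
    out = {}
    for g in genes:
        w0 = max(0, g.tss - half)
        w1 = g.tss + half
        rec = by_chrom.get(g.body.chrom)
        if rec is None:
            out[g.gene_id] = 0.0
            continue
        starts, ends_sorted, cnts_by_start, cnts_by_end = rec
        # reads overlapping [w0, w1): start < w1 and end > w0
        n_start_before = np.searchsorted(starts, w1, side="left")
        total_start_before = cnts_by_start[:n_start_before].sum()
        n_end_before = np.searchsorted(ends_sorted, w0, side="right")
        total_end_before = cnts_by_end[:n_end_before].sum()
        # all reads with end <= w0 also have start < w1 (start < end)
        n_overlap = total_start_before - total_end_before
        out[g.gene_id] = float(n_overlap) * factors.per_read_weight
    return pd.Series(out, name="normalized_signal")
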