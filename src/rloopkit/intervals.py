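"""Core genomic primitives shared by every pipeline stage.

Coordinates are 0-based, half-open everywhere (`[start, end)`), the BED
convention.  GTF input (1-based, inclusive) is converted on read.  A
minus-strand gene's TSS is the *end* coordinate of its body interval --
the biological 5' end under this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np

STRANDS = ("+", "-", ".")

GENE_CLASSES = ("pcg_repressed", "active_top", "inactive_bottom", "other")


class ValidationError(ValueError):
    """Raised when an input record violates a format or domain invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A strand-aware half-open interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneRecord:
    """A gene with its body interval, strand-derived TSS/TES and class label.

    ``class_label`` is one of ``pcg_repressed`` (Polycomb-repressed),
    ``active_top`` (most active genes), ``inactive_bottom`` (least active)
    or ``other``.
    """

    gene_id: str
    body: GenomicInterval
    class_label: str

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if self.class_label not in GENE_CLASSES:
            raise ValidationError(
                f"gene {self.gene_id}: unknown class_label {self.class_label!r}; "
                f"allowed: {', '.join(GENE_CLASSES)}"
            )

    @property
    def tss(self) -> int:
        """Transcription start site: 5' end of the body."""
        return self.body.start if self.body.strand == "+" else self.body.end

    @property
    def tes(self) -> int:
        """Transcription end site: 3' end of the body."""
        return self.body.end if self.body.strand == "+" else self.body.start

    @property
    def length_bp(self) -> int:
        return len(self.body)


def check_unique_gene_ids(genes: Iterable[GeneRecord]) -> None:
    seen = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {g.gene_id!r}")
        seen.add(g.gene_id)


class SignalTrack:
    """Piecewise-constant, non-negative coverage over one or more chromosomes.

    Internally each chromosome holds three parallel arrays (starts, ends,
    values) with sorted, non-overlapping intervals.  ``total_mapped`` is
    the number of reads the track derives from and is the denominator for
    per-million normalisation.
    """

    def __init__(
        self,
        data: Optional[Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]]] = None,
        strand: str = ".",
        total_mapped: float = 0.0,
    ) -> None:
        if strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}")
        self.strand = strand
        self.total_mapped = float(total_mapped)
        self._data: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if data:
            for chrom, (s, e, v) in data.items():
                self._set_chrom(chrom, np.asarray(s), np.asarray(e), np.asarray(v))

    def _set_chrom(self, chrom: str, s: np.ndarray, e: np.ndarray, v: np.ndarray) -> None:
        s = np.asarray(s, dtype=np.int64)
        e = np.asarray(e, dtype=np.int64)
        v = np.asarray(v, dtype=np.float64)
        if not (len(s) == len(e) == len(v)):
            raise ValidationError("starts, ends, values must have equal length")
        if np.any(v < 0):
            raise ValidationError(f"negative coverage value on {chrom}")
        if np.any(s >= e):
            raise ValidationError(f"empty or inverted interval on {chrom}")
        order = np.argsort(s, kind="stable")
        s, e, v = s[order], e[order], v[order]
        if len(s) > 1 and np.any(e[:-1] > s[1:]):
            raise ValidationError(f"overlapping intervals on {chrom}")
        self._data[chrom] = (s, e, v)

    @property
    def chroms(self) -> Tuple[str, ...]:
        return tuple(sorted(self._data))

    def intervals(self, chrom: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        if chrom not in self._data:
            z = np.empty(0, dtype=np.int64)
            return z, z, np.empty(0, dtype=np.float64)
        return self._data[chrom]

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Integral of coverage over [start, end): sum of value * overlap_bp."""
        if end <= start:
            return 0.0
        s, e, v = self.intervals(chrom)
        if len(s) == 0:
            return 0.0
        ov = np.minimum(e, end) - np.maximum(s, start)
        ov = np.clip(ov, 0, None)
        return float(np.sum(ov * v))

    def total_integral(self) -> float:
        return float(
            sum(np.sum((e - s) * v) for s, e, v in self._data.values())
        )

    def binned_means(self, chrom: str, start: int, n_bins: int, bin_bp: int) -> np.ndarray:
        """Mean coverage in ``n_bins`` consecutive bins of ``bin_bp`` from ``start``.

        Bins extending below position 0 contribute zero; the caller masks
        out-of-bounds bins separately.
        """
        out = np.zeros(n_bins, dtype=np.float64)
        s, e, v = self.intervals(chrom)
        if len(s) == 0:
            return out
        edges = start + bin_bp * np.arange(n_bins + 1, dtype=np.int64)
        # restrict to intervals overlapping the window
        lo = np.searchsorted(e, edges[0], side="right")
        hi = np.searchsorted(s, edges[-1], side="left")
        for i in range(lo, hi):
            b0 = np.searchsorted(edges, s[i], side="right") - 1
            b1 = np.searchsorted(edges, e[i], side="left")
            b0 = max(b0, 0)
            for b in range(b0, min(b1, n_bins)):
                ov = min(e[i], edges[b + 1]) - max(s[i], edges[b])
                if ov > 0:
                    out[b] += ov * v[i]
        return out / bin_bp


def coverage_from_reads(
    read_starts: np.ndarray, read_ends: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse a pile of read intervals into piecewise-constant coverage.

    Returns (starts, ends, values) with values >= 1, sorted and
    non-overlapping; zero-coverage gaps are omitted.
    """
    read_starts = np.asarray(read_starts, dtype=np.int64)
    read_ends = np.asarray(read_ends, dtype=np.int64)
    if len(read_starts) == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z.copy(), np.empty(0, dtype=np.float64)
    points = np.concatenate([read_starts, read_ends])
    deltas = np.concatenate(
        [np.ones(len(read_starts)), -np.ones(len(read_ends))]
    )
    order = np.argsort(points, kind="stable")
    points, deltas = points[order], deltas[order]
    uniq, idx = np.unique(points, return_index=True)
    # net delta at each unique breakpoint
    net = np.add.reduceat(deltas, idx)
    depth = np.cumsum(net)[:-1]
    starts = uniq[:-1]
    ends = uniq[1:]
    keep = depth > 0
    return starts[keep], ends[keep], depth[keep].astype(np.float64)
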