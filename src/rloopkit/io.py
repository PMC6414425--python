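"""Readers and writers for the plain-text formats the pipeline consumes.

BED and bedGraph are 0-based half-open.  GTF gene features (1-based,
inclusive) are converted to the internal convention on read.  All readers
skip blank lines and lines starting with ``#`` or ``track``.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from .intervals import (
    GENE_CLASSES,
    GeneRecord,
    GenomicInterval,
    SignalTrack,
    ValidationError,
    check_unique_gene_ids,
)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Raised for malformed lines; message names the file and line number."""


def _data_lines(path: PathLike):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#") or line.startswith("track"):
                continue
            yield lineno, line


def read_bed(path: PathLike) -> List[GenomicInterval]:
    """Parse a BED3/BED6 file into intervals.

    Strand is taken from column 6 when present, otherwise unstranded.
    """
    out: List[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
        try:
            out.append(GenomicInterval(fields[0], start, end, strand))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: List[GenomicInterval], path: PathLike, names: Optional[List[str]] = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"iv{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand if iv.strand != '.' else '.'}\n")


_GENE_TABLE_COLS = ["gene_id", "chrom", "start", "end", "strand", "class_label"]


def read_gene_table(path: PathLike) -> List[GeneRecord]:
    """Read a TSV gene table with columns gene_id, chrom, start, end, strand, class_label."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str, "chrom": str})
    missing = [c for c in _GENE_TABLE_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    genes = []
    for row in df.itertuples(index=False):
        label = row.class_label
        if label not in GENE_CLASSES:
            raise ValidationError(
                f"{path}: gene {row.gene_id}: unknown class_label {label!r}; "
                f"allowed: {', '.join(GENE_CLASSES)}"
            )
        genes.append(
            GeneRecord(
                gene_id=str(row.gene_id),
                body=GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                class_label=label,
            )
        )
    check_unique_gene_ids(genes)
    return genes


def write_gene_table(genes: List[GeneRecord], path: PathLike) -> None:
    rows = [
        (g.gene_id, g.body.chrom, g.body.start, g.body.end, g.body.strand, g.class_label)
        for g in genes
    ]
    pd.DataFrame(rows, columns=_GENE_TABLE_COLS).to_csv(path, sep="\t", index=False)


_GTF_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


def read_gtf_genes(path: PathLike, class_table: Optional[PathLike] = None) -> List[GeneRecord]:
    """Read gene features from a GTF file (1-based inclusive -> half-open).

    ``class_table`` is an optional two-column TSV (gene_id, class_label);
    genes absent from it get label ``other``.
    """
    labels: Dict[str, str] = {}
    if class_table is not None:
        tbl = pd.read_csv(class_table, sep="\t", comment="#", dtype=str)
        labels = dict(zip(tbl.iloc[:, 0], tbl.iloc[:, 1]))
    genes: List[GeneRecord] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 9:
            raise ParseError(f"{path}:{lineno}: expected 9 GTF columns")
        if fields[2] != "gene":
            continue
        m = _GTF_GENE_ID_RE.search(fields[8])
        if not m:
            raise ParseError(f"{path}:{lineno}: gene feature without gene_id attribute")
        gene_id = m.group(1)
        start = int(fields[3]) - 1  # GTF is 1-based inclusive
        end = int(fields[4])
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                body=GenomicInterval(fields[0], start, end, fields[6]),
                class_label=labels.get(gene_id, "other"),
            )
        )
    check_unique_gene_ids(genes)
    return genes


def read_bedgraph(
    path: PathLike,
    strand: str = ".",
    total_mapped: Optional[float] = None,
    read_length_bp: float = 1.0,
) -> SignalTrack:
    """Parse a 4-column bedGraph into a :class:`SignalTrack`.

    Overlapping intervals or negative values raise a validation error.
    If ``total_mapped`` is not given it is estimated as the coverage
    integral divided by ``read_length_bp``.
    """
    per_chrom: Dict[str, List[List[float]]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
        chrom = fields[0]
        try:
            start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed numeric field") from exc
        if value < 0:
            raise ValidationError(f"{path}:{lineno}: negative coverage value {value}")
        per_chrom.setdefault(chrom, []).append([start, end, value])
    data = {}
    for chrom, rows in per_chrom.items():
        arr = np.asarray(rows)
        data[chrom] = (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
    track = SignalTrack(data, strand=strand)
    if total_mapped is None:
        total_mapped = track.total_integral() / read_length_bp
    track.total_mapped = float(total_mapped)
    return track


def write_bedgraph(track: SignalTrack, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            s, e, v = track.intervals(chrom)
            for i in range(len(s)):
                fh.write(f"{chrom}\t{s[i]}\t{e[i]}\t{v[i]:g}\n")
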