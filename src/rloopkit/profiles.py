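"""Meta-gene profiles: average coverage in 10-bp bins around TSS or TES.

Each gene contributes one row of per-bin mean coverage over a window
centered on its anchor; minus-strand rows are flipped so columns always
run 5' to 3'.  Bins falling outside chromosome bounds are zero and masked
out of column averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneRecord, SignalTrack, ValidationError


@dataclass
class ProfileMatrix:
    values: np.ndarray  # genes x bins, 5'->3'
    mask: np.ndarray  # True where the bin lies inside chromosome bounds
    gene_ids: Sequence[str]
    anchor: str  # "TSS" or "TES"
    flank_bp: int
    bin_bp: int

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        offsets = -self.flank_bp + self.bin_bp * np.arange(self.n_bins)
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=offsets)


def profile_matrix(
    track: SignalTrack,
    genes: Sequence[GeneRecord],
    anchor: str = "TSS",
    flank_bp: int = 2000,
    bin_bp: int = 10,
    chrom_sizes: Optional[Dict[str, int]] = None,
) -> ProfileMatrix:
    """Per-gene binned coverage around TSS or TES.

    The window spans ``[anchor - flank_bp, anchor + flank_bp)`` in genomic
    coordinates before orientation; with ``bin_bp`` = 10 this yields
    ``2 * flank_bp / 10`` columns.  ``chrom_sizes`` enables masking at the
    right chromosome edge; the left edge (position 0) is always masked.
    """
    if anchor not in ("TSS", "TES"):
        raise ValidationError("anchor must be 'TSS' or 'TES'")
    if flank_bp % bin_bp:
        raise ValidationError("flank_bp must be a multiple of bin_bp")
    n_bins = 2 * flank_bp // bin_bp
    values = np.zeros((len(genes), n_bins))
    mask = np.ones((len(genes), n_bins), dtype=bool)
    for r, g in enumerate(genes):
        pos = g.tss if anchor == "TSS" else g.tes
        w0 = pos - flank_bp
        row = track.binned_means(g.body.chrom, w0, n_bins, bin_bp)
        edges = w0 + bin_bp * np.arange(n_bins)
        row_mask = edges >= 0
        if chrom_sizes is not None and g.body.chrom in chrom_sizes:
            row_mask &= (edges + bin_bp) <= chrom_sizes[g.body.chrom]
        row[~row_mask] = 0.0
        if g.body.strand == "-":
            row = row[::-1]
            row_mask = row_mask[::-1]
        values[r] = row
        mask[r] = row_mask
    return ProfileMatrix(values, mask, [g.gene_id for g in genes], anchor, flank_bp, bin_bp)


def average_profile(m: ProfileMatrix) -> np.ndarray:
    """Column means over unmasked entries (the meta-gene average)."""
    counts = m.mask.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, (m.values * m.mask).sum(axis=0) / counts, np.nan)
    return means
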