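"""Percent-of-input quantification for DRIP-qPCR and ChIP-qPCR.

Enrichment is expressed as the immunoprecipitated fraction of the input
chromatin.  Because only a fraction of the chromatin is kept as input,
the input Ct is first adjusted down by log2(1 / input_fraction); the
percent input is then 100 * 2^(adjusted_input_ct - ip_ct).  Amplification
efficiency is fixed at 2.0 per cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import ValidationError
from .stats import stars, t_test_two_tailed


@dataclass(frozen=True)
class QpcrSample:
    """One qPCR replicate: IP and input Ct values plus dilution metadata."""

    target_id: str
    condition: str
    ct_ip: float
    ct_input: float
    input_fraction: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.input_fraction <= 1):
            raise ValidationError("input_fraction must be in (0, 1]")
        if not (math.isfinite(self.ct_ip) and math.isfinite(self.ct_input)):
            raise ValidationError("Ct values must be finite")


def percent_input(s: QpcrSample) -> float:
    """Percent of input: 100 * 2^(dilution-adjusted input Ct - IP Ct)."""
    adjusted = s.ct_input - math.log2(1.0 / s.input_fraction)
    return 100.0 * 2.0 ** (adjusted - s.ct_ip)


def samples_to_frame(samples: Sequence[QpcrSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "target_id": [s.target_id for s in samples],
            "condition": [s.condition for s in samples],
            "replicate": [s.replicate for s in samples],
            "percent_input": [percent_input(s) for s in samples],
        }
    )


def read_qpcr_table(path) -> list[QpcrSample]:
    """Read a TSV with columns target_id, condition, ct_ip, ct_input, input_fraction[, replicate]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["target_id", "condition", "ct_ip", "ct_input", "input_fraction"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if "replicate" not in df.columns:
        df["replicate"] = range(len(df))
    return [
        QpcrSample(
            target_id=str(r.target_id),
            condition=str(r.condition),
            ct_ip=float(r.ct_ip),
            ct_input=float(r.ct_input),
            input_fraction=float(r.input_fraction),
            replicate=int(r.replicate),
        )
        for r in df.itertuples(index=False)
    ]


def condition_summary(samples: Sequence[QpcrSample]) -> pd.DataFrame:
    """Mean percent input, sample SD (n-1) and n per (target, condition) group."""
    df = samples_to_frame(samples)
    out = (
        df.groupby(["target_id", "condition"])["percent_input"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="size")
        .reset_index()
    )
    return out


def condition_compare(
    group_a: Sequence[float], group_b: Sequence[float]
) -> Tuple[float, float, float, str]:
    """Fold change (b over a), t statistic, two-sided p and star annotation."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs n >= 2 replicates")
    fold = float(np.mean(b) / np.mean(a))
    t, p = t_test_two_tailed(a, b)
    return fold, t, p, stars(p)


def compare_conditions_table(
    samples: Sequence[QpcrSample], reference_condition: str
) -> pd.DataFrame:
    """Compare every (target, condition) group against the reference condition."""
    df = samples_to_frame(samples)
    rows = []
    for target, sub in df.groupby("target_id"):
        ref = sub[sub["condition"] == reference_condition]["percent_input"].to_numpy()
        if len(ref) < 2:
            continue
        for cond, grp in sub.groupby("condition"):
            if cond == reference_condition:
                continue
            vals = grp["percent_input"].to_numpy()
            if len(vals) < 2:
                continue
            fold, t, p, star = condition_compare(ref, vals)
            rows.append((target, reference_condition, cond, fold, t, p, star))
    return pd.DataFrame(
        rows,
        columns=["target_id", "reference", "condition", "fold_change", "t", "p", "stars"],
    )
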