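"""Duplicate thresholding and spike-in normalization."""

import math

import numpy as np
import pandas as pd
import pytest

from rloopkit.dedup import (
    NormalizationError,
    ReadCollection,
    dedup_threshold,
    deduplicate,
    nearest_rank_percentile,
    normalization_factors,
    window_signal,
)
from rloopkit.intervals import GeneRecord, GenomicInterval, ValidationError


def collection_from_counts(counts, tag="target"):
    rows = []
    for i, c in enumerate(counts):
        rows.append(
            {
                "chrom": "spike_chr1" if tag == "spikein" else "chr1",
                "start": i * 100,
                "end": i * 100 + 50,
                "strand": "+",
                "genome_tag": tag,
                "count": c,
            }
        )
    return ReadCollection(pd.DataFrame(rows))


def brute_force_threshold(counts, percentile=95.0):
    """Independent nearest-rank percentile: walk the sorted multiset."""
    ordered = sorted(counts)
    rank = max(1, math.ceil(percentile / 100.0 * len(ordered)))
    return max(1, ordered[rank - 1])


class TestThreshold:
    def test_all_unique_gives_one(self):
        assert dedup_threshold(collection_from_counts([1] * 20)) == 1

    @pytest.mark.parametrize(
        "counts, expected",
        [
            ([1] * 95 + [10] * 5, 1),  # 95th nearest rank sits in the 1-block
            ([1] * 50 + [2] * 50, 2),
            ([3] * 10, 3),
        ],
    )
    def test_known_multisets(self, counts, expected):
        assert dedup_threshold(collection_from_counts(counts)) == expected
        assert brute_force_threshold(counts) == expected

    def test_matches_brute_force_on_random_multisets(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 60))
            counts = list(rng.integers(1, 12, size=n))
            got = dedup_threshold(collection_from_counts(counts))
            assert got == brute_force_threshold(counts)

    def test_empty_collection_errors(self):
        with pytest.raises(ValidationError):
            dedup_threshold(ReadCollection(pd.DataFrame(
                columns=["chrom", "start", "end", "strand", "genome_tag", "count"]
            )))


class TestDeduplicate:
    def test_no_duplicates_is_identity(self):
        coll = collection_from_counts([1] * 30)
        res = deduplicate(coll)
        assert res.removed == 0
        assert res.retained.n_reads() == 30

    def test_single_jackpot_capped(self):
        coll = collection_from_counts([1] * 99 + [100])
        res = deduplicate(coll)
        assert res.threshold == 1
        assert res.removed == 99
        assert res.retained.counts().max() == 1

    def test_idempotent(self, rng):
        for _ in range(20):
            counts = list(rng.integers(1, 20, size=int(rng.integers(5, 50))))
            res = deduplicate(collection_from_counts(counts))
            again = deduplicate(res.retained)
            assert again.removed == 0

    def test_cap_invariant_random(self, rng):
        for _ in range(50):
            counts = list(rng.integers(1, 30, size=int(rng.integers(2, 80))))
            res = deduplicate(collection_from_counts(counts))
            assert res.retained.counts().max() <= res.threshold
            assert res.removed == sum(counts) - res.retained.n_reads()

    def test_drop_mode_removes_whole_groups(self):
        coll = collection_from_counts([1] * 99 + [100])
        res = deduplicate(coll, mode="drop")
        assert res.removed == 100
        assert res.retained.n_reads() == 99

    def test_threshold_computed_on_combined_tags(self):
        # identical count structure split across genomes: one threshold
        df = pd.concat(
            [collection_from_counts([1] * 10 + [5]).df,
             collection_from_counts([1] * 10 + [5], tag="spikein").df]
        )
        res = deduplicate(ReadCollection(df))
        assert res.threshold == brute_force_threshold([1] * 20 + [5, 5])


class TestNormalization:
    def test_stated_formula(self):
        df = pd.concat(
            [collection_from_counts([1] * 4).df, collection_from_counts([1] * 2, "spikein").df]
        )
        f = normalization_factors(ReadCollection(df))
        assert f.normalized_depth == pytest.approx(4 / 2 * 1e6)
        assert f.per_read_weight == pytest.approx(1e6 / 2)

    def test_doubling_spikein_halves_weight(self):
        a = normalization_factors(ReadCollection(pd.concat(
            [collection_from_counts([1] * 10).df, collection_from_counts([1] * 5, "spikein").df]
        )))
        b = normalization_factors(ReadCollection(pd.concat(
            [collection_from_counts([1] * 10).df, collection_from_counts([2] * 5, "spikein").df]
        )))
        assert a.per_read_weight == pytest.approx(2 * b.per_read_weight)

    def test_zero_spikein_errors(self):
        with pytest.raises(NormalizationError):
            normalization_factors(collection_from_counts([1] * 10))


def brute_force_window_counts(reads_df, genes, window_bp, weight):
    out = {}
    half = window_bp // 2
    for g in genes:
        w0, w1 = max(0, g.tss - half), g.tss + half
        n = 0
        for row in reads_df.to_dict("records"):
            if row["genome_tag"] != "target":
                continue
            if row["chrom"] == g.body.chrom and row["start"] < w1 and row["end"] > w0:
                n += row["count"]
        out[g.gene_id] = n * weight
    return out


class TestWindowSignal:
    def make_genes(self, rng, n=20):
        genes = []
        for i in range(n):
            start = int(rng.integers(1000, 100_000))
            genes.append(
                GeneRecord(
                    f"g{i}",
                    GenomicInterval(f"chr{rng.integers(1, 3)}", start, start + 2000,
                                    "+" if rng.random() < 0.5 else "-"),
                    "other",
                )
            )
        return genes

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            genes = self.make_genes(rng)
            rows = []
            for j in range(300):
                s = int(rng.integers(0, 110_000))
                rows.append({"chrom": f"chr{rng.integers(1, 3)}", "start": s,
                             "end": s + int(rng.integers(1, 200)), "strand": "+",
                             "genome_tag": "target", "count": int(rng.integers(1, 4))})
            rows.append({"chrom": "spike_chr1", "start": 0, "end": 50, "strand": "+",
                         "genome_tag": "spikein", "count": 10})
            coll = ReadCollection(pd.DataFrame(rows))
            factors = normalization_factors(coll)
            sig = window_signal(coll, genes, factors, 1000)
            expected = brute_force_window_counts(coll.df, genes, 1000, factors.per_read_weight)
            for g in genes:
                assert sig[g.gene_id] == pytest.approx(expected[g.gene_id])

    def test_spikein_scale_equivariance(self, rng):
        genes = self.make_genes(rng, 10)
        base_rows = [{"chrom": "chr1", "start": genes[0].tss, "end": genes[0].tss + 50,
                      "strand": "+", "genome_tag": "target", "count": 10}]
        for k in (1, 3):
            rows = base_rows + [{"chrom": "spike_chr1", "start": 0, "end": 50,
                                 "strand": "+", "genome_tag": "spikein", "count": 100 * k}]
            coll = ReadCollection(pd.DataFrame(rows))
            sig = window_signal(coll, genes, normalization_factors(coll))
            if k == 1:
                ref = sig
        assert np.allclose(ref.to_numpy(), sig.to_numpy() * 3)

    def test_odd_window_rejected(self, simple_genes):
        coll = ReadCollection(pd.DataFrame([
            {"chrom": "chr1", "start": 0, "end": 50, "strand": "+",
             "genome_tag": "spikein", "count": 1}]))
        coll.df.loc[0, "chrom"] = "spike_chr1"
        with pytest.raises(ValidationError):
            window_signal(coll, simple_genes, normalization_factors(coll), window_bp=999)
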