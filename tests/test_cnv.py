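"""Sliding-window fold change, amplicon merging, sizes and gene annotation."""

import numpy as np
import pytest

from conftest import counts_from_array, synthetic_tagdb
from digikaryo.cnv import (
    AmpliconCall,
    Window,
    amplicon_size,
    annotate_genes,
    call_amplicons,
    qualifying_runs,
    read_bed,
    scan_windows,
    sliding_window_sums,
)


class TestScanWindows:
    def test_uniform_counts_give_fold_exactly_one(self):
        db = synthetic_tagdb(60)
        tc = counts_from_array(db, np.full(60, 7))
        windows = scan_windows(tc, db, window=20)
        assert len(windows) == 41
        assert all(w.fold == 1.0 for w in windows)

    def test_zero_count_chromosome_has_fold_zero(self):
        db = synthetic_tagdb(40, chrom="chrA") + synthetic_tagdb(40, chrom="chrB", seed=1)
        arr = np.concatenate([np.zeros(40), np.full(40, 5)])
        tc = counts_from_array(db, arr)
        windows = scan_windows(tc, db, window=20)
        assert all(w.fold == 0.0 for w in windows if w.chrom == "chrA")
        assert all(w.fold == 2.0 for w in windows if w.chrom == "chrB")

    def test_chromosome_shorter_than_window_yields_no_windows(self):
        db = synthetic_tagdb(10)
        tc = counts_from_array(db, np.full(10, 3))
        assert scan_windows(tc, db, window=20) == []

    def test_window_sums_match_direct_recount(self):
        rng = np.random.default_rng(5)
        arr = rng.integers(0, 50, 200)
        db = synthetic_tagdb(200)
        tc = counts_from_array(db, arr)
        windows = scan_windows(tc, db, window=20)
        for w in windows:  # brute-force recount
            assert w.observed == arr[w.first_index : w.first_index + 20].sum()

    def test_tenfold_spike_reaches_amplification_threshold(self):
        rng = np.random.default_rng(11)
        db = synthetic_tagdb(1000)
        weights = np.ones(1000)
        weights[480:520] = 10.0  # spike spanning 40 virtual tags
        counts = rng.multinomial(100_000, weights / weights.sum())
        tc = counts_from_array(db, counts)
        windows = scan_windows(tc, db, window=20)
        assert max(w.fold for w in windows) >= 3.0

    def test_nonunique_tags_excluded_from_windows(self):
        db = synthetic_tagdb(30)
        db[5] = db[5].__class__(db[5].chrom, db[5].pos, "+", db[5].seq, False)
        tc = counts_from_array(db, np.full(30, 4))
        tc.counts.pop(db[5].key)
        tc.mapped_tags -= 4
        tc.total_tags -= 4
        windows = scan_windows(tc, db, window=20)
        assert len(windows) == 10  # 29 unique tags -> 10 windows
        assert all(w.fold == 1.0 for w in windows)


class TestCallAmplicons:
    def make_windows(self, folds, spacing=1000, width=21):
        return [
            Window("c", i, i * spacing, i * spacing + (19 * spacing) + width, f * 100.0, 100.0)
            for i, f in enumerate(folds)
        ]

    def test_no_qualifying_window_gives_no_calls(self):
        assert call_amplicons(self.make_windows([1.0] * 10)) == []

    def test_interrupted_runs_become_two_calls(self):
        calls = call_amplicons(self.make_windows([1, 4, 1, 5, 1]))
        assert len(calls) == 2
        assert all(c.direction == "amplification" for c in calls)

    def test_adjacent_qualifying_windows_merge(self):
        calls = call_amplicons(self.make_windows([1, 4, 5, 4, 1]))
        assert len(calls) == 1
        assert calls[0].n_windows == 3
        assert calls[0].mean_fold == pytest.approx(13 / 3)

    def test_deletion_and_amplification_do_not_merge(self):
        calls = call_amplicons(self.make_windows([4, 0.05, 4]))
        assert [c.direction for c in calls] == [
            "amplification",
            "deletion",
            "amplification",
        ]

    def test_call_size_follows_end_minus_start(self):
        calls = call_amplicons(self.make_windows([5.0] * 3))
        (c,) = calls
        assert c.size == c.end - c.start

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            call_amplicons([], amp_threshold=3, del_threshold=2)

    def test_qualifying_runs_direction_and_maximality(self):
        runs = qualifying_runs(np.array([5, 5, 1, 0.05, 0.05, 1, 5]))
        assert runs == [(0, 1, "amplification"), (3, 4, "deletion"), (6, 6, "amplification")]


class TestAmpliconSize:
    @pytest.mark.parametrize(
        "start,end,size",
        [
            (94_187_248, 94_227_832, 40_584),
            (116_359_697, 116_359_984, 287),
            (96_223_512, 96_436_326, 212_814),
        ],
    )
    def test_published_interval_arithmetic(self, start, end, size):
        assert amplicon_size(start, end) == size

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            amplicon_size(100, 100)


class TestAnnotateGenes:
    CALL = AmpliconCall("chr7", 94_187_248, 94_227_832, "amplification", 3.1, 12)

    def test_contained_gene_annotated(self):
        (c,) = annotate_genes([self.CALL], [("chr7", 94_190_000, 94_220_000, "SGCE")])
        assert c.genes == ("SGCE",)

    def test_gene_straddling_boundary_included(self):
        (c,) = annotate_genes([self.CALL], [("chr7", 94_100_000, 94_190_000, "EDGE")])
        assert c.genes == ("EDGE",)

    def test_no_overlap_gives_empty_genes(self):
        (c,) = annotate_genes([self.CALL], [("chr7", 95_000_000, 95_010_000, "FAR")])
        assert c.genes == ()

    def test_bed_round_trip_and_validation(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr7\t94190000\t94220000\tSGCE\n")
        assert read_bed(bed) == [("chr7", 94_190_000, 94_220_000, "SGCE")]
        bed.write_text("chr7\t94190000\tend\tSGCE\n")
        with pytest.raises(ValueError, match="line 1"):
            read_bed(bed)

    def test_window_sums_kernel_edge_cases(self):
        assert sliding_window_sums(np.array([1, 2, 3]), 5).size == 0
        assert list(sliding_window_sums(np.array([1, 2, 3, 4]), 2)) == [3, 5, 7]
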