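"""Synthetic data generator: determinism, planted geometry, sampling model."""

import numpy as np
import pytest

from digikaryo._util import find_all
from digikaryo.extract import extract_tags
from digikaryo.mapping import map_tags
from digikaryo.simulate import (
    CnvSegment,
    SimConfig,
    locus_weights,
    make_genome,
    simulate_ct_table,
    simulate_tag_reads,
)
from digikaryo.tagdb import build_virtual_tags


class TestMakeGenome:
    def test_byte_identical_under_fixed_seed(self):
        cfg = SimConfig(genome_length=50_000, seed=1)
        g1, t1 = make_genome(cfg)
        g2, t2 = make_genome(SimConfig(genome_length=50_000, seed=1))
        assert g1 == g2 and t1.mapping_sites == t2.mapping_sites

    def test_different_seed_changes_sequence(self):
        g1, _ = make_genome(SimConfig(genome_length=50_000, seed=1))
        g2, _ = make_genome(SimConfig(genome_length=50_000, seed=2))
        assert g1 != g2

    def test_planted_sites_occur_exactly_where_reported(self):
        cfg = SimConfig(genome_length=60_000, mapping_spacing=3000, seed=4)
        genome, truth = make_genome(cfg)
        seq = genome["chr1"]
        assert find_all(seq, "GAGCTC") == truth.mapping_sites["chr1"]
        assert find_all(seq, "CATG") == truth.frag_sites["chr1"]

    def test_each_mapping_site_yields_two_flanking_tags(self):
        cfg = SimConfig(genome_length=60_000, mapping_spacing=5000, seed=4)
        genome, truth = make_genome(cfg)
        tagdb = build_virtual_tags(genome)
        n_sites = len(truth.mapping_sites["chr1"])
        assert n_sites >= 10
        assert len(tagdb) >= n_sites  # at least one tag per planted site

    def test_zero_mapping_sites_give_empty_tag_set(self):
        cfg = SimConfig(genome_length=20_000, mapping_sites_per_chrom=0, seed=1)
        genome, truth = make_genome(cfg)
        assert truth.mapping_sites["chr1"] == []
        assert build_virtual_tags(genome) == []

    def test_short_genome_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(genome_length=500)


class TestSimulateReads:
    def test_reads_deterministic_under_seed(self, small_genome):
        genome, _t, tagdb, cfg = small_genome
        r1, _ = simulate_tag_reads(genome, cfg, tagdb)
        r2, _ = simulate_tag_reads(genome, cfg, tagdb)
        assert r1 == r2

    def test_zero_depth_gives_zero_reads(self, small_genome):
        genome, _t, tagdb, cfg = small_genome
        cfg0 = SimConfig(**{**cfg.__dict__, "depth": 0})
        reads, _ = simulate_tag_reads(genome, cfg0, tagdb)
        assert reads == []

    def test_empty_tag_set_rejected(self):
        cfg = SimConfig(genome_length=20_000, mapping_sites_per_chrom=0, seed=1)
        genome, _ = make_genome(cfg)
        with pytest.raises(ValueError):
            simulate_tag_reads(genome, cfg)

    def test_flat_profile_counts_uniform_within_multinomial_noise(self, small_genome):
        from scipy import stats

        genome, _t, tagdb, cfg = small_genome
        cfg = SimConfig(**{**cfg.__dict__, "depth": 100_000, "cnv_profile": []})
        reads, _ = simulate_tag_reads(genome, cfg, tagdb)
        counts, _rep = extract_tags(reads, dedup=False)
        tc = map_tags(counts, tagdb)
        observed = np.array(list(tc.counts.values()))
        _chi, p = stats.chisquare(observed)
        assert p > 0.001

    def test_spiked_segment_counts_scale_with_fold(self, small_genome):
        genome, _t, tagdb, cfg = small_genome
        lo, hi = 40_000, 80_000
        seg = CnvSegment("chr1", lo, hi, 10.0)
        cfg = SimConfig(**{**cfg.__dict__, "depth": 100_000, "cnv_profile": [seg]})
        reads, _ = simulate_tag_reads(genome, cfg, tagdb)
        counts, _rep = extract_tags(reads, dedup=False)
        tc = map_tags(counts, tagdb)
        inside = [tc.counts[t.key] for t in tagdb if t.unique and lo <= t.footprint()[0] < hi]
        outside = [tc.counts[t.key] for t in tagdb if t.unique and not lo <= t.footprint()[0] < hi]
        assert len(inside) >= 30
        ratio = np.mean(inside) / np.mean(outside)
        assert 8.0 <= ratio <= 12.0  # within 20% of the planted fold

    def test_locus_weight_ratio_converges_to_fold_at_high_depth(self, small_genome):
        _g, _t, tagdb, _cfg = small_genome
        lo, hi = 40_000, 80_000
        w = locus_weights(tagdb, [CnvSegment("chr1", lo, hi, 10.0)])
        rng = np.random.default_rng(9)
        counts = rng.multinomial(1_000_000, w / w.sum())
        in_mask = np.array([lo <= t.footprint()[0] < hi for t in tagdb])
        ratio = counts[in_mask].mean() / counts[~in_mask].mean()
        assert abs(ratio - 10.0) / 10.0 < 0.05

    def test_overlapping_profile_segments_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(
                genome_length=50_000,
                cnv_profile=[CnvSegment("chr1", 0, 100, 3.0), CnvSegment("chr1", 50, 200, 0.1)],
            )


class TestSimulateCtTable:
    def test_tables_deterministic_under_seed(self):
        t1 = simulate_ct_table(5, 5, 3.0, 0.2, seed=3)
        t2 = simulate_ct_table(5, 5, 3.0, 0.2, seed=3)
        assert t1.equals(t2)

    def test_per_gene_folds_respected_at_zero_noise(self):
        table = simulate_ct_table(2, 2, {"A": 2.0, "B": 8.0}, 0.0, seed=1)
        from digikaryo.qpcr import relative_levels

        levels = relative_levels(table)
        tum = levels[levels.group == "tumor"].set_index(["gene", "sample_id"])["level"]
        assert set(tum.loc["A"]) == {2.0}
        assert set(tum.loc["B"]) == {8.0}

    def test_cohort_recovers_fold_within_15_percent(self):
        from digikaryo.qpcr import relative_levels

        table = simulate_ct_table(52, 52, 3.0, 0.2, seed=7)
        levels = relative_levels(table)
        mean_tumor = levels.loc[levels.group == "tumor", "level"].mean()
        assert 2.5 <= mean_tumor <= 3.6
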