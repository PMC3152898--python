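"""Shared fixtures: small deterministic synthetic inputs."""

import numpy as np
import pytest

from digikaryo.mapping import TagCounts
from digikaryo.simulate import SimConfig, make_genome
from digikaryo.tagdb import VirtualTag, build_virtual_tags


@pytest.fixture(scope="session")
def small_genome():
    """A ~120 kb planted genome with its truth and virtual-tag database."""
    cfg = SimConfig(genome_length=120_000, mapping_spacing=2000, site_spacing=400, seed=42)
    genome, truth = make_genome(cfg)
    tagdb = build_virtual_tags(genome)
    return genome, truth, tagdb, cfg


def synthetic_tagdb(n_tags: int, spacing: int = 4000, chrom: str = "chr1", seed: int = 0):
    """A uniformly spaced all-unique tag database (no genome behind it)."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    tags = []
    for i in range(n_tags):
        seq = "CATG" + "".join(rng.choice(bases, 17))
        tags.append(VirtualTag(chrom, 100 + i * spacing, "+", seq, True))
    return tags


def counts_from_array(tagdb, arr) -> TagCounts:
    counts = {t.key: int(c) for t, c in zip(tagdb, arr)}
    total = int(sum(counts.values()))
    return TagCounts(counts=counts, total_tags=total, mapped_tags=total)
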