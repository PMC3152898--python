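"""Synthetic genomes, tag libraries and Ct tables with known ground truth.

No real digital-karyotyping data accompany the study system this package
models, so every pipeline input is generated here with exact ground truth:

* **Genomes** — i.i.d. uniform ACGT background from which every chance
  GAGCTC/CATG occurrence is scrubbed, then mapping-enzyme sites (GAGCTC)
  and fragmenting-enzyme sites (CATG) are planted explicitly.  Each mapping
  site receives one flanking CATG on either side at a distance guaranteeing
  a valid 21-bp tag, plus background CATGs at the configured spacing (kept
  clear of mapping sites so the flank geometry survives).  Planted
  coordinates are returned for oracle tests.
* **Tag libraries** — tags are drawn multinomially over the genome's virtual
  tag loci, each locus weighted by the fold of any copy-number segment
  covering it (1.0 outside segments), paired into ditags and emitted as
  shared-anchor concatemer reads: CATG + k x (34 bp + CATG).  Reads are
  error-free by default; ``error_rate`` adds uniform substitutions.
* **Ct tables** — triplicate threshold cycles for a normal and a tumor
  cohort.  A tumor carrying fold f has Ct(target) = Ct(ref) - log2(f) plus
  Gaussian replicate noise, so the downstream 2^dCt estimator recovers f
  exactly at zero noise.

Fixing the seed fixes every emitted byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import find_all, revcomp, write_fasta
from .qpcr import CT_COLUMNS
from .tagdb import FRAGMENTING_SITE, MAPPING_SITE, VirtualTag, build_virtual_tags

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CYCLE = {ord("A"): ord("C"), ord("C"): ord("G"), ord("G"): ord("T"), ord("T"): ord("A")}


@dataclass(frozen=True)
class CnvSegment:
    """One copy-number segment: fold multiplier relative to diploid."""

    chrom: str
    start: int  # 0-based, half-open
    end: int
    fold: float

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("segment start must precede end")
        if self.fold <= 0:
            raise ValueError("segment fold must be positive")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def validate_profile(segments: Sequence[CnvSegment]) -> None:
    by_chrom: dict[str, list[CnvSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping segments on {chrom}: {a} / {b}")


@dataclass
class SimConfig:
    """Study conditions for one synthetic run.

    ``site_spacing`` is the mean distance between background fragmenting-
    enzyme sites; ``mapping_spacing`` between mapping-enzyme sites (so the
    virtual-tag spacing is about half of it, two tags per site).  ``depth``
    is the expected total number of extracted tags.
    """

    genome_length: int = 500_000
    n_chroms: int = 1
    site_spacing: float = 500.0
    mapping_spacing: float = 4000.0
    depth: int = 100_000
    seed: int = 0
    cnv_profile: list[CnvSegment] = field(default_factory=list)
    mapping_sites_per_chrom: int | None = None  # override the spacing-derived count
    ditags_per_read: int = 8
    error_rate: float = 0.0
    ref_ct: float = 20.0

    def __post_init__(self):
        if self.genome_length < 1000:
            raise ValueError("genome_length must be >= 1000")
        if self.n_chroms < 1:
            raise ValueError("n_chroms must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")
        validate_profile(self.cnv_profile)


@dataclass
class SimTruth:
    """Planted coordinates: ground truth for oracle tests."""

    mapping_sites: dict[str, list[int]]
    frag_sites: dict[str, list[int]]


def _scrub(seq: bytearray, motifs: Iterable[bytes], keep: set[int] | None = None) -> None:
    """Mutate bases until no motif occurs outside planted positions.

    ``keep`` holds genome offsets covered by planted motifs; mutation always
    picks a base outside it (every stray motif has at least one such base).
    """
    keep = keep or set()
    s = bytes(seq)
    for _ in range(50):
        dirty = False
        for motif in motifs:
            for p in find_all(s.decode(), motif.decode()):
                span = range(p, p + len(motif))
                if all(i in keep for i in span):
                    continue  # the planted motif itself
                target = next(i for i in span if i not in keep)
                seq[target] = _CYCLE[seq[target]]
                dirty = True
        if not dirty:
            return
        s = bytes(seq)
    raise RuntimeError("motif scrubbing did not converge")


def make_genome(config: SimConfig) -> tuple[dict[str, str], SimTruth]:
    """Generate chromosomes with planted enzyme sites; deterministic per seed.

    Returns (genome, truth) where truth carries the planted GAGCTC and CATG
    coordinates per chromosome.
    """
    rng = np.random.default_rng([config.seed, 0])
    genome: dict[str, str] = {}
    truth = SimTruth({}, {})
    margin = 100
    site, frag = MAPPING_SITE.encode(), FRAGMENTING_SITE.encode()
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        n = config.genome_length
        seq = bytearray(_BASES[rng.integers(0, 4, n)].tobytes())
        _scrub(seq, (site, frag))
        # plant mapping sites on a jittered grid
        if config.mapping_sites_per_chrom is not None:
            n_sites = config.mapping_sites_per_chrom
        else:
            n_sites = int((n - 2 * margin) // config.mapping_spacing)
        g_sites: list[int] = []
        prev = -(10**9)
        for k in range(n_sites):
            g = margin + int(k * config.mapping_spacing) + int(rng.integers(0, max(1, int(config.mapping_spacing / 8))))
            if g - prev < 160 or g + len(site) + margin > n:
                continue
            seq[g : g + len(site)] = site
            g_sites.append(g)
            prev = g
        # flank every mapping site with a CATG on each side, far enough for a tag
        c_sites: list[int] = []
        for g in g_sites:
            up = g - 21 - int(rng.integers(0, 30))
            down = g + len(site) + 17 + int(rng.integers(0, 30))
            for p in (up, down):
                if 0 <= p and p + len(frag) <= n:
                    seq[p : p + len(frag)] = frag
                    c_sites.append(p)
        # background fragmenting sites, kept clear of mapping-site geometry
        occupied = sorted(g_sites)
        k, pos = 0, margin
        while pos + len(frag) + margin <= n:
            p = pos + int(rng.integers(0, max(1, int(config.site_spacing / 4))))
            near_site = any(abs(p - g) < 90 for g in occupied)
            near_flank = any(abs(p - c) < 25 for c in c_sites)
            if not near_site and not near_flank and p + len(frag) + margin <= n:
                seq[p : p + len(frag)] = frag
                c_sites.append(p)
            k += 1
            pos = margin + int(k * config.site_spacing)
        # remove stray motifs created at planting boundaries
        keep = {i for g in g_sites for i in range(g, g + len(site))}
        keep |= {i for c in c_sites for i in range(c, c + len(frag))}
        _scrub(seq, (site, frag), keep)
        genome[chrom] = seq.decode()
        truth.mapping_sites[chrom] = sorted(g_sites)
        truth.frag_sites[chrom] = sorted(c_sites)
    for seg in config.cnv_profile:
        if seg.chrom not in genome:
            raise ValueError(f"profile references unknown chromosome {seg.chrom!r}")
    return genome, truth


def locus_weights(tagdb: Sequence[VirtualTag], profile: Sequence[CnvSegment]) -> np.ndarray:
    """Sampling weight per virtual tag: segment fold at its anchor, else 1."""
    w = np.ones(len(tagdb))
    for i, t in enumerate(tagdb):
        start, _ = t.footprint()
        for seg in profile:
            if seg.contains(t.chrom, start):
                w[i] = seg.fold
                break
    return w


def simulate_tag_reads(
    genome: Mapping[str, str],
    config: SimConfig,
    tagdb: Sequence[VirtualTag] | None = None,
) -> tuple[list[tuple[str, str]], list[VirtualTag]]:
    """Sample ``depth`` tags multinomially and emit ditag-concatemer reads.

    Tags are paired into ditags (CATG + 17 + 17rc + CATG) and concatenated
    ``ditags_per_read`` at a time with shared punctuating anchors.  Returns
    (reads, tagdb); the expected number of extractable tags equals depth.
    """
    if tagdb is None:
        tagdb = build_virtual_tags(genome)
    if not tagdb:
        raise ValueError("virtual-tag set of the genome is empty")
    rng = np.random.default_rng([config.seed, 1])
    n_ditags = config.depth // 2
    if n_ditags == 0:
        return [], list(tagdb)
    w = locus_weights(tagdb, config.cnv_profile)
    p = w / w.sum()
    idx = rng.choice(len(tagdb), size=2 * n_ditags, p=p)
    seqs = [t.seq for t in tagdb]
    reads: list[tuple[str, str]] = []
    per_read = max(1, config.ditags_per_read)
    for r0 in range(0, n_ditags, per_read):
        parts = [FRAGMENTING_SITE]
        for d in range(r0, min(r0 + per_read, n_ditags)):
            a, b = seqs[idx[2 * d]], seqs[idx[2 * d + 1]]
            parts.append(a[4:] + revcomp(b))
        read = "".join(parts)
        if config.error_rate > 0.0:
            read = _add_errors(read, config.error_rate, rng)
        reads.append((f"read{r0 // per_read}", read))
    return reads, list(tagdb)


def _add_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = bytearray(seq.encode())
    n_err = rng.binomial(len(arr), rate)
    for pos in rng.choice(len(arr), size=n_err, replace=False):
        arr[pos] = _CYCLE[arr[pos]]
    return arr.decode()


def simulate_ct_table(
    n_normals: int,
    n_tumors: int,
    true_fold: float | Mapping[str, float],
    noise_sd: float,
    seed: int,
    genes: Sequence[str] | None = None,
    n_amplified_tumors: int | None = None,
    ref_ct: float = 20.0,
    n_reps: int = 3,
) -> pd.DataFrame:
    """Triplicate Ct tables for a normal cohort and a tumor cohort.

    ``true_fold`` is a per-gene multiplier (scalar applies to every gene).
    With ``n_amplified_tumors`` only the first k tumors carry the fold, the
    rest stay at 1.0 — the mixed-cohort design of real validation panels.
    """
    if n_normals <= 0 or n_tumors <= 0:
        raise ValueError("cohort sizes must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if isinstance(true_fold, Mapping):
        folds = dict(true_fold)
        genes = list(genes) if genes is not None else sorted(folds)
    else:
        genes = list(genes) if genes is not None else ["GENE1"]
        folds = {g: float(true_fold) for g in genes}
    if any(f <= 0 for f in folds.values()):
        raise ValueError("true_fold must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    samples = [(f"N{i + 1:03d}", "normal", False) for i in range(n_normals)]
    samples += [
        (f"T{i + 1:03d}", "tumor", n_amplified_tumors is None or i < n_amplified_tumors)
        for i in range(n_tumors)
    ]
    for sample_id, group, carries in samples:
        for gene in genes:
            fold = folds[gene] if (group == "tumor" and carries) else 1.0
            ref = ref_ct + rng.normal(0.0, noise_sd, n_reps)
            target = ref_ct - math.log2(fold) + rng.normal(0.0, noise_sd, n_reps)
            rows.append([sample_id, group, gene, *target, *ref])
    return pd.DataFrame(rows, columns=CT_COLUMNS)


def segments_to_bed(segments: Sequence[CnvSegment], path: str | Path) -> None:
    """Ground-truth copy-number segments as BED (name=direction, score=fold)."""
    with open(path, "w") as fh:
        for s in sorted(segments, key=lambda s: (s.chrom, s.start)):
            name = "amplification" if s.fold > 1 else "deletion"
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{name}\t{s.fold:g}\n")


def write_reads_fasta(reads: Iterable[tuple[str, str]], path: str | Path) -> None:
    write_fasta(reads, path)
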