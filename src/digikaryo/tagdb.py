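"""Virtual-tag database construction.

Digital karyotyping counts short sequence tags released at a fixed geometry:
the genome is cut at every *mapping-enzyme* site (SacI, ``GAGCTC``) and each
fragment end is trimmed back to the nearest *fragmenting-enzyme* site (NlaIII,
``CATG``), from which a type-IIS enzyme releases a 21-bp tag.  The in-silico
twin of that protocol is the **virtual tag database**: for every mapping site,
and for each side of it, the nearest CATG anchor on that side defines one
21-bp tag read from the anchor toward the mapping site.  Observed sequencing
tags are later matched exactly against this database, so tag density along
the chromosome becomes a direct, digital readout of copy number.

Conventions (any consistent choice works as long as the extractor agrees):

* A tag is the 21 bases starting at the C of its CATG anchor, read toward
  the mapping site; minus-strand tags are stored reverse-complemented so
  every stored sequence begins ``CATG``.
* ``pos`` is the 0-based coordinate of the anchor C on the forward strand.
  A ``+`` tag occupies ``[pos, pos+21)``; a ``-`` tag occupies
  ``[pos-20, pos+1)``.
* The nearest anchor on a side is chosen by anchor start.  If its 21-bp
  footprint would overlap the mapping site (touching is fine) the side is
  skipped — no fallback to a farther anchor.  Tags containing N are dropped.
* ``unique`` is True when the 21-mer occurs at exactly one locus genome-wide,
  counting both strands.
* Internally all coordinates are 0-based half-open; emitted files are 1-based.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._util import find_all, revcomp

log = logging.getLogger(__name__)

TAG_LENGTH = 21
MAPPING_SITE = "GAGCTC"  # SacI
FRAGMENTING_SITE = "CATG"  # NlaIII


@dataclass(frozen=True)
class VirtualTag:
    """One genome-derived tag locus.

    ``seq`` is the 21-base tag beginning with its CATG anchor; ``pos`` the
    0-based forward-strand coordinate of the anchor C; ``unique`` whether the
    sequence occurs at exactly one locus genome-wide.
    """

    chrom: str
    pos: int
    strand: str
    seq: str
    unique: bool = True

    def footprint(self, tag_length: int = TAG_LENGTH) -> tuple[int, int]:
        """Forward-strand 0-based half-open interval the tag occupies."""
        if self.strand == "+":
            return self.pos, self.pos + tag_length
        return self.pos - tag_length + 1, self.pos + 1

    @property
    def key(self) -> tuple[str, int, str]:
        return self.chrom, self.pos, self.strand


def _tags_for_chrom(
    chrom: str,
    seq: str,
    mapping_site: str,
    fragmenting_site: str,
    tag_length: int,
) -> list[VirtualTag]:
    site_len = len(mapping_site)
    g_positions = find_all(seq, mapping_site)
    if not g_positions:
        return []
    c_positions = find_all(seq, fragmenting_site)
    tags: dict[tuple[str, int, str], VirtualTag] = {}
    for g in g_positions:
        # upstream side: nearest anchor starting before the site, tag reads
        # rightward toward the site on the forward strand
        i = bisect_left(c_positions, g) - 1
        if i >= 0:
            p = c_positions[i]
            if p + tag_length <= g:
                t = seq[p : p + tag_length]
                if "N" not in t:
                    tags.setdefault((chrom, p, "+"), VirtualTag(chrom, p, "+", t))
            else:
                log.debug("%s: anchor %d too close to site %d, skipped", chrom, p, g)
        # downstream side: nearest anchor starting after the site start, tag
        # reads leftward toward the site, i.e. lives on the reverse strand
        i = bisect_right(c_positions, g)
        if i < len(c_positions):
            p = c_positions[i]
            start = p + len(fragmenting_site) - tag_length
            if start >= g + site_len:
                t = revcomp(seq[start : p + len(fragmenting_site)])
                if "N" not in t:
                    pos = p + len(fragmenting_site) - 1
                    tags.setdefault((chrom, pos, "-"), VirtualTag(chrom, pos, "-", t))
            else:
                log.debug("%s: anchor %d too close to site %d, skipped", chrom, p, g)
    return sorted(tags.values(), key=lambda t: (t.pos, t.strand))


def _occurrence_counts(genome: Mapping[str, str], queries: set[str], k: int) -> dict[str, int]:
    """Count forward-strand occurrences of each query k-mer across the genome."""
    counts = {q: 0 for q in queries}
    for seq in genome.values():
        n = len(seq)
        for i in range(n - k + 1):
            w = seq[i : i + k]
            if w in counts:
                counts[w] += 1
    return counts


def build_virtual_tags(
    genome: Mapping[str, str],
    mapping_site: str = MAPPING_SITE,
    fragmenting_site: str = FRAGMENTING_SITE,
    tag_length: int = TAG_LENGTH,
) -> list[VirtualTag]:
    """Build the ordered virtual-tag database for ``genome``.

    ``genome`` maps chromosome name to sequence; chromosome order follows the
    mapping's insertion order and tags are sorted by position within each
    chromosome.  Uniqueness is computed by exact genome-wide occurrence
    counting of each tag sequence on both strands.
    """
    if not genome:
        raise ValueError("genome is empty")
    tags: list[VirtualTag] = []
    for chrom, seq in genome.items():
        tags.extend(
            _tags_for_chrom(chrom, seq.upper(), mapping_site, fragmenting_site, tag_length)
        )
    if not tags:
        return []
    queries = {t.seq for t in tags} | {revcomp(t.seq) for t in tags}
    counts = _occurrence_counts({c: s.upper() for c, s in genome.items()}, queries, tag_length)
    out = []
    for t in tags:
        occ = counts[t.seq] + counts[revcomp(t.seq)]
        out.append(replace(t, unique=occ == 1))
    return out


TAGDB_HEADER = ["chrom", "pos", "strand", "seq", "unique"]


def write_tagdb(tags: Iterable[VirtualTag], path: str | Path) -> None:
    """Write tags as a tab-delimited file with 1-based anchor positions."""
    with open(path, "w") as fh:
        fh.write("\t".join(TAGDB_HEADER) + "\n")
        for t in tags:
            fh.write(f"{t.chrom}\t{t.pos + 1}\t{t.strand}\t{t.seq}\t{int(t.unique)}\n")


def read_tagdb(path: str | Path) -> list[VirtualTag]:
    """Read a tag database written by :func:`write_tagdb` (lossless round trip)."""
    tags: list[VirtualTag] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != TAGDB_HEADER:
            raise ValueError(f"line 1: bad header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ValueError(f"line {lineno}: expected 5 fields, got {len(fields)}")
            chrom, pos_s, strand, seq, uniq_s = fields
            try:
                pos = int(pos_s) - 1
                uniq = bool(int(uniq_s))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            if strand not in "+-":
                raise ValueError(f"line {lineno}: bad strand {strand!r}")
            if not seq or set(seq) - set("ACGTN"):
                raise ValueError(f"line {lineno}: bad tag sequence {seq!r}")
            tags.append(VirtualTag(chrom, pos, strand, seq, uniq))
    return tags


def verify_tags(tags: Sequence[VirtualTag], genome: Mapping[str, str]) -> bool:
    """Check every stored sequence occurs verbatim at its locus (strand-aware)."""
    for t in tags:
        start, end = t.footprint()
        window = genome[t.chrom][start:end].upper()
        observed = window if t.strand == "+" else revcomp(window)
        if observed != t.seq:
            return False
    return True
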