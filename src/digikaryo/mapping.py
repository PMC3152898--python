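"""Joining observed tags to virtual-tag loci.

An observed tag is assigned to a locus only when its sequence matches exactly
one virtual tag whose sequence is unique genome-wide; everything else
(sequences absent from the database, or matching a non-unique virtual tag)
is tallied but carries no positional information.  The mapped fraction F/T
is the library's headline quality figure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from ._util import percent_nearest, revcomp
from .tagdb import VirtualTag

_MULTI = object()  # sentinel: sequence present at >1 database locus


@dataclass
class TagCounts:
    """Per-locus observed counts plus library totals.

    ``counts`` is keyed by (chrom, pos, strand) over the unique virtual-tag
    loci (zero entries included); invariant: sum(counts) == mapped_tags and
    mapped + unmapped + nonunique == total.
    """

    counts: dict[tuple[str, int, str], int]
    total_tags: int = 0
    mapped_tags: int = 0
    unmapped_tags: int = 0
    nonunique_tags: int = 0

    def report(self) -> dict:
        return mapping_report(self.total_tags, self.mapped_tags) | {
            "unmapped_tags": self.unmapped_tags,
            "nonunique_tags": self.nonunique_tags,
        }


def map_tags(
    observed: Mapping[str, int],
    tagdb: Sequence[VirtualTag],
    match_revcomp: bool = False,
) -> TagCounts:
    """Assign observed tag counts to unique virtual-tag loci by exact match.

    ``observed`` maps tag sequence to count (e.g. the Counter from
    :func:`digikaryo.extract.extract_tags`).  With ``match_revcomp`` a tag
    failing the forward lookup is retried as its reverse complement.
    """
    index: dict[str, object] = {}
    for t in tagdb:
        index[t.seq] = _MULTI if t.seq in index else t
    tc = TagCounts(counts={t.key: 0 for t in tagdb if t.unique})
    for seq, n in observed.items():
        if n < 0:
            raise ValueError(f"negative count for {seq!r}")
        tc.total_tags += n
        hit = index.get(seq)
        if hit is None and match_revcomp:
            hit = index.get(revcomp(seq))
        if hit is None:
            tc.unmapped_tags += n
        elif hit is _MULTI or not hit.unique:
            tc.nonunique_tags += n
        else:
            tc.counts[hit.key] += n
            tc.mapped_tags += n
    return tc


def mapping_report(total_tags: int, mapped_tags: int) -> dict:
    """Summary of a mapping run: totals and mapped percentage (nearest int)."""
    if total_tags <= 0:
        raise ValueError("total_tags must be positive")
    if mapped_tags > total_tags:
        raise ValueError("mapped_tags cannot exceed total_tags")
    return {
        "total_tags": total_tags,
        "mapped_tags": mapped_tags,
        "percent_mapped": percent_nearest(mapped_tags, total_tags),
    }


def write_locus_counts(tc: TagCounts, path: str | Path) -> None:
    """Per-locus counts as TSV (1-based anchor positions)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tstrand\tcount\n")
        for (chrom, pos, strand), n in sorted(tc.counts.items()):
            fh.write(f"{chrom}\t{pos + 1}\t{strand}\t{n}\n")


def read_locus_counts(path: str | Path) -> dict[tuple[str, int, str], int]:
    out: dict[tuple[str, int, str], int] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != "chrom\tpos\tstrand\tcount":
            raise ValueError(f"line 1: bad header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"line {lineno}: expected 4 fields")
            try:
                out[(fields[0], int(fields[1]) - 1, fields[2])] = int(fields[3])
            except ValueError:
                raise ValueError(f"line {lineno}: bad integer field") from None
    return out


def write_report(tc: TagCounts, path: str | Path) -> None:
    Path(path).write_text(json.dumps(tc.report(), indent=2, sort_keys=True) + "\n")
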