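"""Extraction of 21-bp tags from ditag-concatemer sequencing reads.

The sequencing library consists of concatemers of *ditags*: two 21-bp tags
ligated tail-to-tail, so each ditag reads CATG + 17 nt + 17 nt + CATG and
adjacent ditags in a concatemer share their punctuating CATG anchor.  A read
is therefore scanned greedily left to right: from the current anchor, the
next anchor whose internal span (bases strictly between the two CATGs) falls
within the accepted ditag window yields one ditag, and scanning resumes at
that shared anchor.  Anchors giving too-short spans (e.g. a CATG that happens
to occur inside a tag) are passed over; an overlong span abandons the current
anchor and moves to the next one.

The two tags of a ditag are recovered as:

* ``tag_a`` — the first CATG plus the following 17 bases;
* ``tag_b`` — the reverse complement of (last 17 internal bases + terminal
  CATG), so both tags are reported CATG-first in database orientation.

Ditag deduplication (on by default) counts each distinct ditag sequence once,
the conventional guard against PCR duplicates in tag libraries; a ditag and
its reverse complement are treated as the same molecule.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from ._util import find_all, iter_reads, revcomp

TAG_LENGTH = 21
ANCHOR = "CATG"
# internal span bounds bracket the canonical 2*(21-4) = 34 with +/-2 slack
MIN_INTERNAL = 32
MAX_INTERNAL = 36


@dataclass(frozen=True)
class Ditag:
    """A CATG...CATG span and the two CATG-first tags derived from its ends."""

    seq: str

    @property
    def internal_length(self) -> int:
        return len(self.seq) - 2 * len(ANCHOR)

    @property
    def tag_a(self) -> str:
        return self.seq[:TAG_LENGTH]

    @property
    def tag_b(self) -> str:
        return revcomp(self.seq[-TAG_LENGTH:])

    def canonical(self) -> str:
        rc = revcomp(self.seq)
        return self.seq if self.seq <= rc else rc


@dataclass
class ExtractionReport:
    total_reads: int = 0
    skipped_reads: int = 0
    ditags_found: int = 0
    duplicate_ditags: int = 0
    tags_emitted: int = 0
    dedup: bool = True
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def find_ditags(
    seq: str,
    min_internal: int = MIN_INTERNAL,
    max_internal: int = MAX_INTERNAL,
) -> list[Ditag]:
    """Greedy left-to-right ditag segmentation of one read."""
    anchors = find_all(seq, ANCHOR)
    out: list[Ditag] = []
    i = 0
    n = len(anchors)
    while i < n:
        a = anchors[i]
        placed = False
        j = i + 1
        while j < n:
            internal = anchors[j] - (a + len(ANCHOR))
            if internal < min_internal:
                j += 1
                continue
            if internal <= max_internal:
                out.append(Ditag(seq[a : anchors[j] + len(ANCHOR)]))
                i = j
                placed = True
            break
        if not placed:
            i += 1
    return out


def extract_tags(
    reads,
    dedup: bool = True,
    min_internal: int = MIN_INTERNAL,
    max_internal: int = MAX_INTERNAL,
) -> tuple[Counter, ExtractionReport]:
    """Extract the tag multiset from reads.

    ``reads`` may be a FASTA/FASTQ path (plain or gzipped) or an iterable of
    sequences / (id, sequence) pairs.  Returns (tag counts, report); a
    zero-tag outcome is a valid result, not an error.
    """
    if min_internal > max_internal or min_internal < TAG_LENGTH - len(ANCHOR):
        raise ValueError("invalid ditag internal-length window")
    counts: Counter = Counter()
    report = ExtractionReport(
        dedup=dedup, params={"min_internal": min_internal, "max_internal": max_internal}
    )
    seen: set[str] = set()
    for _rid, seq in iter_reads(reads):
        report.total_reads += 1
        if not seq or set(seq) - set("ACGTN"):
            report.skipped_reads += 1
            continue
        for dt in find_ditags(seq, min_internal, max_internal):
            report.ditags_found += 1
            if dedup:
                key = dt.canonical()
                if key in seen:
                    report.duplicate_ditags += 1
                    continue
                seen.add(key)
            counts[dt.tag_a] += 1
            counts[dt.tag_b] += 1
            report.tags_emitted += 2
    return counts, report


def write_tag_counts(counts: Counter, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq\tcount\n")
        for seq in sorted(counts):
            fh.write(f"{seq}\t{counts[seq]}\n")


def read_tag_counts(path: str | Path) -> Counter:
    counts: Counter = Counter()
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != "seq\tcount":
            raise ValueError(f"line 1: bad header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"line {lineno}: expected 2 fields")
            try:
                counts[fields[0]] += int(fields[1])
            except ValueError:
                raise ValueError(f"line {lineno}: bad count {fields[1]!r}") from None
    return counts
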