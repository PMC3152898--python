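"""Small shared helpers: sequence arithmetic, rounding, FASTA I/O."""

from __future__ import annotations

import gzip
import math
from pathlib import Path
from typing import Iterable, Iterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN alphabet, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def percent_nearest(numerator: int, denominator: int) -> int:
    """100*n/d rounded to the nearest integer, halves rounding up.

    Matches report-style percentages (23/52 -> 44, 11/52 -> 21).
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0 or numerator > denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) start positions of ``needle`` in ``haystack``."""
    out: list[int] = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercase sequence mapping."""
    from Bio import SeqIO

    with open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 80) -> None:
    with open_text(path, "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_reads(source, fmt: str | None = None) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) pairs from a FASTA/FASTQ path or an in-memory iterable.

    ``source`` may be a path (format sniffed from the extension unless ``fmt``
    is given), an iterable of raw sequence strings, or of (id, seq) pairs.
    """
    from Bio import SeqIO

    if isinstance(source, (str, Path)):
        path = Path(source)
        if fmt is None:
            stem = path.name[:-3] if path.name.endswith(".gz") else path.name
            fmt = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
        with open_text(path) as fh:
            for rec in SeqIO.parse(fh, fmt):
                yield rec.id, str(rec.seq).upper()
        return
    for i, item in enumerate(source):
        if isinstance(item, str):
            yield f"read{i}", item.upper()
        elif isinstance(item, tuple):
            yield item[0], item[1].upper()
        else:  # SeqRecord-like
            yield item.id, str(item.seq).upper()
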