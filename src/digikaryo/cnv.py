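"""Sliding-window copy-number detection from per-locus tag counts.

The core computation: order the unique virtual tags along each chromosome,
slide a window of W consecutive tags (step 1), and compare the observed tag
count O in the window with its genome-wide expectation E = W * F / U, where
F is the number of mapped tags and U the number of unique virtual-tag loci.
The ratio FC = O/E is the window's fold change; windows with FC >= 3 call
amplification and FC <= 0.1 call deletion (defaults).  Maximal runs of
consecutive qualifying windows of one direction merge into a single amplicon
whose boundaries are the footprint of its constituent tags; reported
coordinates are 1-based and size = end - start, matching the interval
arithmetic of published amplicon tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .mapping import TagCounts
from .tagdb import VirtualTag

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 20
DEFAULT_AMP_THRESHOLD = 3.0
DEFAULT_DEL_THRESHOLD = 0.1


@dataclass(frozen=True)
class Window:
    """One W-tag window: observed count, expectation and fold change."""

    chrom: str
    first_index: int  # index of the first constituent tag on its chromosome
    start: int  # 0-based footprint start of the first tag
    end: int  # 0-based footprint end of the last tag
    observed: float
    expected: float

    @property
    def fold(self) -> float:
        return self.observed / self.expected


@dataclass(frozen=True)
class AmpliconCall:
    """A merged amplified/deleted interval (1-based start/end, size = end-start)."""

    chrom: str
    start: int
    end: int
    direction: str  # "amplification" | "deletion"
    mean_fold: float
    n_windows: int
    genes: tuple[str, ...] = ()

    @property
    def size(self) -> int:
        return amplicon_size(self.start, self.end)


def amplicon_size(start: int, end: int) -> int:
    """Interval size in bp as printed in amplicon tables: end - start."""
    if end <= start:
        raise ValueError(f"end ({end}) must exceed start ({start})")
    return end - start


def sliding_window_sums(counts: np.ndarray, window: int) -> np.ndarray:
    """Sums over every length-``window`` run of ``counts`` (step 1)."""
    c = np.asarray(counts, dtype=float)
    if window <= 0:
        raise ValueError("window must be positive")
    if c.size < window:
        return np.empty(0)
    cs = np.concatenate(([0.0], np.cumsum(c)))
    return cs[window:] - cs[:-window]


def qualifying_runs(
    folds: np.ndarray,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
    del_threshold: float = DEFAULT_DEL_THRESHOLD,
) -> list[tuple[int, int, str]]:
    """Maximal runs of consecutive qualifying window indices.

    Returns (first_window_index, last_window_index, direction) triples.
    Two qualifying windows separated by a non-qualifying one are two runs.
    """
    folds = np.asarray(folds, dtype=float)
    state = np.where(folds >= amp_threshold, 1, np.where(folds <= del_threshold, -1, 0))
    runs: list[tuple[int, int, str]] = []
    i = 0
    n = state.size
    while i < n:
        if state[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and state[j + 1] == state[i]:
            j += 1
        runs.append((i, j, "amplification" if state[i] == 1 else "deletion"))
        i = j + 1
    return runs


def scan_windows(
    counts: TagCounts,
    tagdb: Sequence[VirtualTag],
    window: int = DEFAULT_WINDOW,
    per_chrom_expected: bool = False,
) -> list[Window]:
    """Slide a ``window``-tag window over the unique tags of each chromosome.

    The expectation per window is E = W * F / U genome-wide (the default) or
    per chromosome with ``per_chrom_expected``.  Chromosomes with fewer than
    W unique tags yield no windows (logged).
    """
    unique = [t for t in tagdb if t.unique]
    if not unique:
        raise ValueError("tag database has no unique tags")
    if counts.mapped_tags <= 0:
        raise ValueError("no mapped tags to scan")
    by_chrom: dict[str, list[VirtualTag]] = {}
    for t in unique:
        by_chrom.setdefault(t.chrom, []).append(t)
    u_total = len(unique)
    out: list[Window] = []
    for chrom, tags in by_chrom.items():
        tags.sort(key=lambda t: (t.pos, t.strand))
        if len(tags) < window:
            log.info("%s: %d unique tags < window %d, skipped", chrom, len(tags), window)
            continue
        c = np.array([counts.counts.get(t.key, 0) for t in tags], dtype=float)
        if per_chrom_expected:
            expected = window * float(c.sum()) / len(tags) if c.sum() > 0 else np.nan
        else:
            expected = window * counts.mapped_tags / u_total
        if not np.isfinite(expected) or expected <= 0:
            log.info("%s: zero expectation, skipped", chrom)
            continue
        sums = sliding_window_sums(c, window)
        starts = [t.footprint()[0] for t in tags]
        ends = [t.footprint()[1] for t in tags]
        for i, o in enumerate(sums):
            out.append(
                Window(chrom, i, starts[i], ends[i + window - 1], float(o), expected)
            )
    return out


def call_amplicons(
    windows: Sequence[Window],
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
    del_threshold: float = DEFAULT_DEL_THRESHOLD,
    min_windows: int = 1,
) -> list[AmpliconCall]:
    """Merge maximal runs of qualifying windows into amplicon/deletion calls.

    Reported start is the 1-based first base of the run's first tag and end
    the last base of its last tag, so size = end - start is the span between
    the outer tag boundaries.
    """
    if not (del_threshold < 1.0 < amp_threshold):
        raise ValueError("thresholds must satisfy del < 1 < amp")
    calls: list[AmpliconCall] = []
    by_chrom: dict[str, list[Window]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)
    for chrom, ws in by_chrom.items():
        ws.sort(key=lambda w: w.first_index)
        folds = np.array([w.fold for w in ws])
        for i, j, direction in qualifying_runs(folds, amp_threshold, del_threshold):
            if j - i + 1 < min_windows:
                continue
            start0 = ws[i].start
            end0 = ws[j].end
            mean_fold = float(folds[i : j + 1].mean())
            calls.append(
                AmpliconCall(chrom, start0 + 1, end0, direction, mean_fold, j - i + 1)
            )
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


# --- gene annotation -------------------------------------------------------


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read a >=4-column BED file as (chrom, start0, end, name) records."""
    out: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"line {lineno}: expected >=4 BED fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer coordinates") from None
            if start < 0 or end <= start:
                raise ValueError(f"line {lineno}: invalid interval [{start}, {end})")
            out.append((fields[0], start, end, fields[3]))
    return out


def annotate_genes(
    calls: Sequence[AmpliconCall],
    annotation: str | Path | Iterable[tuple[str, int, int, str]],
) -> list[AmpliconCall]:
    """Attach the names of annotation intervals intersecting each call.

    ``annotation`` is a BED path or an iterable of (chrom, start0, end, name).
    A gene straddling a call boundary is included; calls without overlap get
    an empty gene tuple.
    """
    from intervaltree import IntervalTree

    if isinstance(annotation, (str, Path)):
        annotation = read_bed(annotation)
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, name in annotation:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
    out = []
    for c in calls:
        tree = trees.get(c.chrom)
        hits = tree.overlap(c.start - 1, c.end) if tree is not None else ()
        genes = tuple(sorted({iv.data for iv in hits}))
        out.append(replace(c, genes=genes))
    return out


# --- output ----------------------------------------------------------------


def write_windows(windows: Sequence[Window], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tobserved\texpected\tfold\n")
        for w in windows:
            fh.write(
                f"{w.chrom}\t{w.start + 1}\t{w.end}\t{w.observed:.0f}"
                f"\t{w.expected:.4f}\t{w.fold:.4f}\n"
            )


def write_calls_bed(calls: Sequence[AmpliconCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.direction}\t{c.mean_fold:.3f}\n")


def write_calls_table(calls: Sequence[AmpliconCall], path: str | Path) -> None:
    """Amplicon-table style TSV: 1-based start/end, size, mean fold, genes."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tsize\tdirection\tmean_fold\tn_windows\tgenes\n")
        for c in calls:
            genes = ",".join(c.genes) if c.genes else "--"
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.size}\t{c.direction}"
                f"\t{c.mean_fold:.3f}\t{c.n_windows}\t{genes}\n"
            )
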