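"""Bundled reference tables.

``chr7_amplicons`` is the published table of fifty amplicons detected on the
q arm of chromosome 7 of an HCC genome by digital karyotyping: 1-based start
and end positions (GRCh37), printed size in bp, and the known genes each
amplicon contains ("--" for none).  It serves as the ground truth for the
interval-arithmetic convention size = end - start used throughout.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def chr7_amplicons() -> pd.DataFrame:
    """The 50-row chromosome-7 amplicon table (start, end, size, genes)."""
    with resources.files("digikaryo.data").joinpath("chr7_amplicons.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["genes"] = df["genes"].map(lambda g: () if g == "--" else tuple(g.split(",")))
    return df
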