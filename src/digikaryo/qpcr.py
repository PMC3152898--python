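"""Relative quantification and amplification calling from qPCR Ct tables.

Each sample x gene measurement is a set of replicate threshold cycles for a
target gene and for a reference assay run on the same material (LINE-1 for
genomic DNA, whose copy number is assumed equal in tumor and normal genomes;
GAPDH for mRNA).  Replicates are averaged per channel and the relative level
is 2^(mean Ct_ref - mean Ct_target): one PCR cycle equals one doubling, so a
level of 4 means four times the reference-normalized template.

A tumor is scored *amplified* for a gene when its relative DNA level strictly
exceeds the normal cohort's mean plus two sample standard deviations
(n-1 denominator).  Cohort comparisons use Student's pooled-variance t test
(Welch and paired variants available) with Bonferroni correction over the m
genes tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._util import percent_nearest


@dataclass(frozen=True)
class CtRecord:
    """Replicate Ct measurements for one sample x gene."""

    sample_id: str
    group: str  # e.g. normal|tumor, or tumor|adjacent for expression
    gene: str
    ct_target: tuple[float, ...]
    ct_ref: tuple[float, ...]

    def __post_init__(self):
        for name, reps in (("ct_target", self.ct_target), ("ct_ref", self.ct_ref)):
            if len(reps) == 0:
                raise ValueError(f"{name}: at least one replicate required")
            if not all(np.isfinite(v) and v > 0 for v in reps):
                raise ValueError(f"{name}: Ct values must be finite and positive")


@dataclass(frozen=True)
class RelativeLevel:
    sample_id: str
    group: str
    gene: str
    level: float


@dataclass(frozen=True)
class CnvQpcrCall:
    """Cohort-threshold amplification call for one gene."""

    gene: str
    threshold: float  # normal-cohort mean + 2 SD
    n_amplified: int
    n_tumors: int
    amplified: tuple[bool, ...]  # per tumor, in input order

    @property
    def frequency(self) -> int:
        return frequency_percent(self.n_amplified, self.n_tumors)


def relative_level(rec: CtRecord) -> RelativeLevel:
    """Reference-normalized level 2^(mean Ct_ref - mean Ct_target)."""
    dct = float(np.mean(rec.ct_ref)) - float(np.mean(rec.ct_target))
    return RelativeLevel(rec.sample_id, rec.group, rec.gene, 2.0**dct)


def relative_levels(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample levels from a Ct table (schema of :func:`read_ct_table`)."""
    recs = table_to_records(table)
    rows = [relative_level(r) for r in recs]
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "group": [r.group for r in rows],
            "gene": [r.gene for r in rows],
            "level": [r.level for r in rows],
        }
    )


def call_amplification(
    normal_levels: Sequence[float],
    tumor_levels: Sequence[float],
    gene: str = "",
) -> CnvQpcrCall:
    """Score each tumor against the normal cohort's mean + 2 SD threshold.

    The inequality is strict: a tumor exactly at the threshold is not called.
    Requires >= 2 normals for the SD to be defined.
    """
    normals = np.asarray(normal_levels, dtype=float)
    tumors = np.asarray(tumor_levels, dtype=float)
    if normals.size < 2:
        raise ValueError("need >= 2 normal samples to define the SD")
    tau = float(normals.mean() + 2.0 * normals.std(ddof=1))
    flags = tuple(bool(v > tau) for v in tumors)
    return CnvQpcrCall(gene, tau, sum(flags), tumors.size, flags)


def call_amplification_table(
    levels: pd.DataFrame,
    normal_group: str = "normal",
    tumor_group: str = "tumor",
) -> list[CnvQpcrCall]:
    """Per-gene mean+2SD calls from a levels table (sample_id, group, gene, level)."""
    out = []
    for gene, sub in levels.groupby("gene", sort=True):
        out.append(
            call_amplification(
                sub.loc[sub["group"] == normal_group, "level"].to_numpy(),
                sub.loc[sub["group"] == tumor_group, "level"].to_numpy(),
                gene=str(gene),
            )
        )
    return out


def frequency_percent(n_amplified: int, n_total: int) -> int:
    """Amplification frequency as a nearest-integer percent (23/52 -> 44)."""
    return percent_nearest(n_amplified, n_total)


def bonferroni(p_raw: float, n_genes: int) -> float:
    """Bonferroni-adjusted p value: min(1, m * p_raw)."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError("p_raw must lie in [0, 1]")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return min(1.0, n_genes * p_raw)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_raw: float
    p_adjusted: float
    n_genes: int
    test: str


def group_test(
    levels_a: Sequence[float],
    levels_b: Sequence[float],
    n_genes: int = 1,
    paired: bool = False,
    welch: bool = False,
) -> TestResult:
    """Two-sided t test between two level groups, Bonferroni-adjusted.

    Default is Student's pooled-variance unpaired test (appropriate for
    unrelated DNA cohorts); ``paired`` switches to the paired test used for
    tumor/adjacent expression comparisons, ``welch`` drops the equal-variance
    assumption.
    """
    a = np.asarray(levels_a, dtype=float)
    b = np.asarray(levels_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    if a.std() == 0.0 and b.std() == 0.0 and not paired:
        raise ValueError("zero variance in both groups; t test undefined")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal group sizes")
        stat, p = stats.ttest_rel(a, b)
        name = "paired t"
    else:
        stat, p = stats.ttest_ind(a, b, equal_var=not welch)
        name = "Welch t" if welch else "Student t"
    stat, p = float(stat), float(p)
    if np.isnan(p):  # identical constant groups in the paired branch etc.
        stat, p = 0.0, 1.0
    return TestResult(stat, p, bonferroni(p, n_genes), n_genes, name)


# --- Ct table I/O ----------------------------------------------------------

CT_COLUMNS = [
    "sample_id",
    "group",
    "gene",
    "ct_rep1",
    "ct_rep2",
    "ct_rep3",
    "ref_ct_rep1",
    "ref_ct_rep2",
    "ref_ct_rep3",
]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    return table


def write_ct_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.4f")


def table_to_records(table: pd.DataFrame) -> list[CtRecord]:
    recs = []
    for row in table.itertuples(index=False):
        recs.append(
            CtRecord(
                sample_id=str(row.sample_id),
                group=str(row.group),
                gene=str(row.gene),
                ct_target=(row.ct_rep1, row.ct_rep2, row.ct_rep3),
                ct_ref=(row.ref_ct_rep1, row.ref_ct_rep2, row.ref_ct_rep3),
            )
        )
    return recs
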