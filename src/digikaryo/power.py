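"""Monte-Carlo power and positive predictive value for lesion detection.

How deep must a tag library be sequenced before a lesion of a given fold and
size is reliably seen?  This module answers by direct simulation rather than
a closed form: a background genome of uniformly spaced unique virtual tags is
laid out, one lesion is planted, T tags are drawn multinomially with the
lesion's loci upweighted by its fold, and the sliding-window caller from
:mod:`digikaryo.cnv` is run on each replicate.

* **power** — fraction of replicates in which at least one call of the
  lesion's direction overlaps the lesion;
* **ppv_region** — true calls / all calls of that direction, pooled over
  replicates (region-level PPV);
* **ppv_window** — same tally at the level of individual qualifying windows.

Both PPV tallies are reported because "PPV" is ambiguous between the two.
Monte-Carlo standard errors use the binomial approximation.  The default tag
spacing of 4 kb reflects the ~0.004 Mb theoretical resolution of the assay.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .cnv import (
    DEFAULT_AMP_THRESHOLD,
    DEFAULT_DEL_THRESHOLD,
    DEFAULT_WINDOW,
    qualifying_runs,
    sliding_window_sums,
)

log = logging.getLogger(__name__)


@dataclass
class PowerQuery:
    """One power/PPV question: lesion fold and size, depth, assay geometry."""

    fold: float
    lesion_bp: float
    depth: int
    tag_spacing_bp: float = 4000.0
    window: int = DEFAULT_WINDOW
    amp_threshold: float = DEFAULT_AMP_THRESHOLD
    del_threshold: float = DEFAULT_DEL_THRESHOLD
    n_sims: int = 200
    seed: int = 0
    genome_tags: int = 5000  # background unique virtual tags simulated

    def __post_init__(self):
        if min(self.fold, self.lesion_bp, self.depth, self.tag_spacing_bp) <= 0:
            raise ValueError("fold, lesion_bp, depth and tag_spacing_bp must be positive")
        if self.n_sims < 100:
            raise ValueError("n_sims must be >= 100")
        if self.genome_tags < self.window:
            raise ValueError("genome_tags must be >= window")

    @property
    def lesion_tags(self) -> int:
        return int(round(self.lesion_bp / self.tag_spacing_bp))


@dataclass
class PowerResult:
    power: float
    ppv_region: float
    ppv_window: float
    power_se: float
    ppv_region_se: float
    ppv_window_se: float
    n_sims: int
    lesion_tags: int
    calls_total: int = 0
    calls_true: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _binom_se(p: float, n: int) -> float:
    return math.sqrt(p * (1.0 - p) / n) if n > 0 else float("nan")


def estimate_power_ppv(q: PowerQuery) -> PowerResult:
    """Estimate detection power and PPV for ``q`` by multinomial simulation.

    Deterministic for a fixed ``q.seed``.  A lesion spanning zero virtual
    tags returns power 0 with a warning.
    """
    rng = np.random.default_rng(q.seed)
    m = q.genome_tags
    lesion = min(q.lesion_tags, m)
    direction = "deletion" if q.fold < 1.0 else "amplification"
    if lesion == 0:
        log.warning(
            "lesion of %.0f bp spans 0 tags at %.0f bp spacing; power is 0",
            q.lesion_bp,
            q.tag_spacing_bp,
        )
        return PowerResult(0.0, 0.0, 0.0, 0.0, float("nan"), float("nan"), q.n_sims, 0)
    a = (m - lesion) // 2  # lesion placed centrally; background is exchangeable
    weights = np.ones(m)
    weights[a : a + lesion] = q.fold
    p = weights / weights.sum()
    expected = q.window * q.depth / m

    hits = 0
    calls_total = calls_true = 0
    win_total = win_true = 0
    w = q.window
    lesion_first_win = max(0, a - w + 1)  # windows overlapping >=1 lesion tag
    lesion_last_win = min(m - w, a + lesion - 1)
    for _ in range(q.n_sims):
        counts = rng.multinomial(q.depth, p)
        folds = sliding_window_sums(counts, w) / expected
        runs = [r for r in qualifying_runs(folds, q.amp_threshold, q.del_threshold) if r[2] == direction]
        sim_hit = False
        for i, j, _dir in runs:
            true = i <= lesion_last_win and j >= lesion_first_win
            calls_total += 1
            calls_true += true
            win_total += j - i + 1
            if true:
                lo, hi = max(i, lesion_first_win), min(j, lesion_last_win)
                win_true += hi - lo + 1
                sim_hit = True
        hits += sim_hit
    power = hits / q.n_sims
    ppv_region = calls_true / calls_total if calls_total else 0.0
    ppv_window = win_true / win_total if win_total else 0.0
    return PowerResult(
        power=power,
        ppv_region=ppv_region,
        ppv_window=ppv_window,
        power_se=_binom_se(power, q.n_sims),
        ppv_region_se=_binom_se(ppv_region, calls_total),
        ppv_window_se=_binom_se(ppv_window, win_total),
        n_sims=q.n_sims,
        lesion_tags=lesion,
        calls_total=calls_total,
        calls_true=calls_true,
    )


def solve_depth(
    q: PowerQuery,
    target_ppv: float = 0.95,
    max_depth: int = 20_000_000,
) -> tuple[int, PowerResult]:
    """Smallest depth (by doubling then bisection) whose region PPV meets target.

    The answer is a property of this simulation's null model and need not
    equal depth figures derived from closed-form PPV calculations elsewhere.
    """
    from dataclasses import replace

    lo, hi = None, None
    depth = max(q.depth, 1000)
    res = None
    while depth <= max_depth:
        res = estimate_power_ppv(replace(q, depth=depth))
        if res.ppv_region >= target_ppv and res.calls_total > 0:
            hi = depth
            break
        lo = depth
        depth *= 2
    if hi is None:
        raise RuntimeError(f"target PPV {target_ppv} not reached by depth {max_depth}")
    while lo is not None and hi - lo > max(1000, hi // 20):
        mid = (lo + hi) // 2
        res_mid = estimate_power_ppv(replace(q, depth=mid))
        if res_mid.ppv_region >= target_ppv and res_mid.calls_total > 0:
            hi, res = mid, res_mid
        else:
            lo = mid
    return hi, res
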