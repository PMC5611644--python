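"""Differentially methylated region (DMR) calling between two methylomes.

The genome is tiled into 100-bp bins; within each bin the pooled
methylated/unmethylated read counts of the two samples form a 2x2 table
tested with Fisher's exact test, p-values are Benjamini-Hochberg
adjusted genome-wide per context, and bins passing both the FDR cut
(q < 0.01) and a context-specific absolute-difference threshold
(CG 0.40, CHG 0.20, CHH 0.20) are merged — tolerating a gap of one
bin — into directional DMRs.  Sites enter a bin only when covered by
10-100 reads in both samples, and bins with fewer than four such sites
are discarded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import GenomicInterval, StageMethylome, ValidationError

logger = logging.getLogger(__name__)

#: Below this grand total the two-sided p is computed in exact integer
#: arithmetic; above it, by log-space hypergeometric summation.
_EXACT_LIMIT = 300

#: Log-space tie tolerance matching the standard "sum of small p" rule.
_LOG_TIE_EPS = 1e-7


@dataclass(frozen=True)
class DmrThresholds:
    """Filters and cutoffs for DMR calling (defaults are the standard ones)."""

    diff: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.40, "CHG": 0.20, "CHH": 0.20}
    )
    fdr: float = 0.01
    min_sites: int = 4
    min_cov: int = 10
    max_cov: int = 100
    merge_gap_windows: int = 1
    bin_size: int = 100

    def __post_init__(self):
        if self.min_cov > self.max_cov:
            raise ValidationError("min_cov must not exceed max_cov")
        for c, t in self.diff.items():
            if not 0 < t <= 1:
                raise ValidationError(f"diff threshold for {c} outside (0,1]")


@dataclass(frozen=True)
class BinComparison:
    """One 100-bp bin's pooled counts and test results for two samples."""

    chrom: str
    start: int
    end: int
    context: str
    a_meth: int
    a_unmeth: int
    b_meth: int
    b_unmeth: int
    n_sites_passing: int
    p_value: float = float("nan")
    q_value: float = float("nan")

    @property
    def level_a(self) -> float:
        t = self.a_meth + self.a_unmeth
        return self.a_meth / t if t else float("nan")

    @property
    def level_b(self) -> float:
        t = self.b_meth + self.b_unmeth
        return self.b_meth / t if t else float("nan")

    @property
    def diff(self) -> float:
        return self.level_a - self.level_b


@dataclass(frozen=True)
class DMR:
    chrom: str
    start: int
    end: int
    context: str
    direction: str           # hyper/hypo with respect to sample A
    mean_diff: float         # site-count-weighted mean of member-bin diffs
    n_bins: int
    annotations: tuple = ()  # overlapping annotation ids; empty = intergenic

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def intergenic(self) -> bool:
        return not self.annotations

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


# ---------------------------------------------------------------------------
# statistics primitives
# ---------------------------------------------------------------------------

def fisher_exact_2x2(a_meth: int, a_unmeth: int, b_meth: int, b_unmeth: int) -> float:
    """Two-sided Fisher exact p for one 2x2 count table.

    Sums hypergeometric point probabilities no larger than that of the
    observed table.  Small tables (grand total <= 300) use exact integer
    arithmetic — point probabilities share the denominator C(N, K), so
    the tie comparison is exact on integer numerators; larger tables use
    log-space summation with a relative tie tolerance.
    """
    if min(a_meth, a_unmeth, b_meth, b_unmeth) < 0:
        raise ValidationError("negative count in 2x2 table")
    r1, r2 = a_meth + a_unmeth, b_meth + b_unmeth
    if r1 == 0 or r2 == 0:
        warnings.warn("empty row in 2x2 table; p = 1 by convention")
        return 1.0
    n = r1 + r2
    k = a_meth + b_meth  # methylated-column margin
    lo, hi = max(0, k - r2), min(r1, k)
    if n <= _EXACT_LIMIT:
        nums = [comb(r1, i) * comb(r2, k - i) for i in range(lo, hi + 1)]
        obs = nums[a_meth - lo]
        return min(1.0, sum(v for v in nums if v <= obs) / comb(n, k))
    support = np.arange(lo, hi + 1)
    lp = hypergeom.logpmf(support, n, k, r1)
    mask = lp <= lp[a_meth - lo] + _LOG_TIE_EPS
    return float(min(1.0, np.exp(logsumexp(lp[mask]))))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# bin building and calling
# ---------------------------------------------------------------------------

def build_bins(
    meth_a: StageMethylome,
    meth_b: StageMethylome,
    context: str,
    thresholds: DmrThresholds = DmrThresholds(),
) -> list[BinComparison]:
    """Pool per-site counts into bins and attach Fisher p / BH q values.

    A cytosine contributes only when its coverage lies within
    [min_cov, max_cov] in *both* samples; bins with fewer than
    ``min_sites`` passing cytosines are dropped.  BH adjustment spans all
    retained bins genome-wide for this context.
    """
    if set(meth_a.chromosomes()) != set(meth_b.chromosomes()):
        raise ValidationError(
            "samples cover different chromosome sets: "
            f"{meth_a.chromosomes()} vs {meth_b.chromosomes()}"
        )
    a = meth_a.subset_context(context)
    b = meth_b.subset_context(context)
    merged = a.merge(
        b, on=["chrom", "pos", "strand"], suffixes=("_a", "_b"), how="inner"
    )
    cov_a = merged["n_meth_a"] + merged["n_unmeth_a"]
    cov_b = merged["n_meth_b"] + merged["n_unmeth_b"]
    ok = (
        cov_a.between(thresholds.min_cov, thresholds.max_cov)
        & cov_b.between(thresholds.min_cov, thresholds.max_cov)
    )
    merged = merged[ok]
    if merged.empty:
        return []
    bin_idx = merged["pos"] // thresholds.bin_size
    grouped = merged.groupby(["chrom", bin_idx], sort=True).agg(
        a_meth=("n_meth_a", "sum"), a_unmeth=("n_unmeth_a", "sum"),
        b_meth=("n_meth_b", "sum"), b_unmeth=("n_unmeth_b", "sum"),
        n_sites=("pos", "size"),
    )
    grouped = grouped[grouped["n_sites"] >= thresholds.min_sites]
    if grouped.empty:
        return []
    p = np.array([
        fisher_exact_2x2(int(r.a_meth), int(r.a_unmeth),
                         int(r.b_meth), int(r.b_unmeth))
        for r in grouped.itertuples()
    ])
    q = bh_adjust(p)
    bins = []
    bs = thresholds.bin_size
    for (chrom, widx), row, pv, qv in zip(grouped.index, grouped.itertuples(), p, q):
        bins.append(BinComparison(
            chrom, int(widx) * bs, (int(widx) + 1) * bs, context,
            int(row.a_meth), int(row.a_unmeth), int(row.b_meth), int(row.b_unmeth),
            int(row.n_sites), float(pv), float(qv),
        ))
    logger.info("built %d %s bins (%d sites merged)", len(bins), context, len(merged))
    return bins


def call_dmr_bins(
    bins: Sequence[BinComparison],
    thresholds: DmrThresholds = DmrThresholds(),
    apply_diff_filter: bool = True,
) -> list[BinComparison]:
    """Select significant bins: q < fdr and |diff| >= the context threshold."""
    out = []
    for b in bins:
        if b.q_value >= thresholds.fdr:
            continue
        if apply_diff_filter and abs(b.diff) < thresholds.diff[b.context]:
            continue
        out.append(b)
    return out


def merge_dmrs(
    significant_bins: Sequence[BinComparison],
    merge_gap_windows: int = 1,
    bin_size: int = 100,
) -> list[DMR]:
    """Merge same-direction significant bins separated by <= the gap budget.

    The gap is counted in bins (one vacant 100-bp window by default);
    hyper and hypo bins never join.  The DMR mean difference is the
    site-count-weighted mean over member bins.
    """
    keyed: dict[tuple[str, str, str], list[BinComparison]] = {}
    for b in significant_bins:
        direction = "hyper" if b.diff >= 0 else "hypo"
        keyed.setdefault((b.chrom, b.context, direction), []).append(b)
    dmrs: list[DMR] = []
    for (chrom, context, direction), bs in sorted(keyed.items()):
        bs = sorted(bs, key=lambda b: b.start)
        run = [bs[0]]
        for b in bs[1:]:
            gap_bins = (b.start - run[-1].end) // bin_size
            if gap_bins <= merge_gap_windows:
                run.append(b)
            else:
                dmrs.append(_finish_dmr(run, chrom, context, direction))
                run = [b]
        dmrs.append(_finish_dmr(run, chrom, context, direction))
    dmrs.sort(key=lambda d: (d.chrom, d.start))
    return dmrs


def _finish_dmr(run, chrom, context, direction) -> DMR:
    w = np.array([b.n_sites_passing for b in run], dtype=float)
    diffs = np.array([b.diff for b in run])
    return DMR(
        chrom, run[0].start, run[-1].end, context, direction,
        float(np.average(diffs, weights=w)), len(run),
    )


def associate_annotations(
    dmrs: Sequence[DMR], annotations: Sequence[GenomicInterval]
) -> list[DMR]:
    """Attach ids of every annotation a DMR overlaps by >= 1 bp.

    DMRs overlapping nothing keep an empty tuple (intergenic).
    """
    trees: dict[str, IntervalTree] = {}
    for iv in annotations:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.id)
    out = []
    for d in dmrs:
        tree = trees.get(d.chrom)
        hits = sorted({h.data for h in tree.overlap(d.start, d.end)}) if tree else []
        out.append(replace(d, annotations=tuple(hits)))
    return out


def call_dmrs(
    meth_a: StageMethylome,
    meth_b: StageMethylome,
    context: str,
    thresholds: DmrThresholds = DmrThresholds(),
    annotations: Sequence[GenomicInterval] | None = None,
) -> list[DMR]:
    """Full pipeline: bins -> significance -> merge -> (optional) annotation."""
    bins = build_bins(meth_a, meth_b, context, thresholds)
    sig = call_dmr_bins(bins, thresholds)
    if not sig:
        return []
    dmrs = merge_dmrs(sig, thresholds.merge_gap_windows, thresholds.bin_size)
    if annotations is not None:
        dmrs = associate_annotations(dmrs, annotations)
    return dmrs


def consensus_bins(
    comparisons: Sequence[Sequence[BinComparison]],
) -> list[BinComparison]:
    """Bins significant in every supplied comparison (consensus mode).

    Intersects on (chrom, start, end, context); the returned bins are
    those of the first comparison.
    """
    if not comparisons:
        return []
    keysets = [
        {(b.chrom, b.start, b.end, b.context) for b in comp}
        for comp in comparisons
    ]
    common = set.intersection(*keysets)
    return [
        b for b in comparisons[0]
        if (b.chrom, b.start, b.end, b.context) in common
    ]


def bins_to_frame(bins: Sequence[BinComparison]) -> pd.DataFrame:
    """Bin-level results as a tidy table (for TSV export)."""
    return pd.DataFrame([
        {
            "chrom": b.chrom, "start": b.start, "end": b.end,
            "context": b.context, "n_sites": b.n_sites_passing,
            "level_a": b.level_a, "level_b": b.level_b, "diff": b.diff,
            "p_value": b.p_value, "q_value": b.q_value,
        }
        for b in bins
    ])
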