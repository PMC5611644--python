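"""Small-RNA size-class selection and normalized abundance over regions.

Reads of the 21-22-nt or 24-nt class are counted over region sets (DMRs
or genome-wide windows) and normalized to reads per million (RPM)
against the *total* mapped library size, not the size-class subtotal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import SmallRNARead, ValidationError

SIZE_CLASSES: Mapping[str, tuple[int, int]] = {
    "21-22": (21, 22),
    "24": (24, 24),
}


@dataclass(frozen=True)
class RegionAbundance:
    chrom: str
    start: int
    end: int
    size_class: str
    raw: int      # reads overlapping the region by >= 1 bp, once each
    rpm: float    # raw * 1e6 / total mapped library reads


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample t-test summary for box-plot-style RPM reporting."""

    t: float
    p_value: float
    median_a: float
    median_b: float
    quartiles_a: tuple
    quartiles_b: tuple
    n_a: int
    n_b: int


def select_size_class(
    reads: Sequence[SmallRNARead], size_class: str
) -> list[SmallRNARead]:
    """Keep reads whose length falls in the named class (21-22 or 24 nt)."""
    if size_class not in SIZE_CLASSES:
        raise ValidationError(
            f"unknown size class {size_class!r}; choose from {list(SIZE_CLASSES)}"
        )
    lo, hi = SIZE_CLASSES[size_class]
    return [r for r in reads if lo <= r.length <= hi]


def quantify_regions(
    reads: Sequence[SmallRNARead],
    regions: Sequence,
    library_total: int,
    size_class: str = "",
) -> list[RegionAbundance]:
    """Count reads over each region and convert to RPM.

    A read overlapping a region by at least 1 bp counts once for that
    region (and again for any other region it overlaps).  The RPM
    denominator is the total mapped library size.
    """
    if library_total <= 0:
        raise ValidationError("library_total must be positive")
    if not regions:
        return []
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    for chrom in {r.chrom for r in reads}:
        rs = [r for r in reads if r.chrom == chrom]
        starts[chrom] = np.sort(np.array([r.start for r in rs]))
        ends[chrom] = np.sort(np.array([r.end for r in rs]))
    out = []
    for reg in regions:
        chrom = reg.chrom
        if chrom in starts:
            # overlap <=> read.start < reg.end and read.end > reg.start
            n = int(
                np.searchsorted(starts[chrom], reg.end, side="left")
                - np.searchsorted(ends[chrom], reg.start, side="right")
            )
        else:
            n = 0
        out.append(RegionAbundance(
            reg.chrom, reg.start, reg.end, size_class,
            n, n * 1e6 / library_total,
        ))
    return out


def compare_groups(
    abundances_a: Sequence[RegionAbundance],
    abundances_b: Sequence[RegionAbundance],
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sided t-test on RPM values (pooled variance; Welch via flag)."""
    a = np.array([x.rpm for x in abundances_a], dtype=float)
    b = np.array([x.rpm for x in abundances_b], dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs >= 2 regions for a t-test")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    q = lambda v: tuple(float(np.quantile(v, x)) for x in (0.25, 0.5, 0.75))
    return GroupComparison(
        float(t), float(p),
        float(np.median(a)), float(np.median(b)),
        q(a), q(b), len(a), len(b),
    )
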