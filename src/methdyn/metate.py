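"""End-aligned meta-TE methylation profiles and relative-position histograms.

TEs are grouped into length classes; within a class both TE borders are
aligned and methylation is pooled in 10-nt bins covering 4 kb of flank
on each side plus an interior stretch fixed so the shortest TE of the
class is fully covered without overlapping bins.  Minus-strand TEs are
mirrored so bins always run 5' to 3'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .io import GenomicInterval, StageMethylome, ValidationError

DEFAULT_CLASS_BOUNDARIES = (1000, 2000)
SEGMENTS = ("upstream", "interior_5p", "interior_3p", "downstream")


@dataclass
class MetaProfile:
    """Pooled methylation per aligned bin for one TE length class.

    ``upstream`` runs farthest-to-nearest toward the 5' border,
    ``interior_5p`` from the 5' border inward, ``interior_3p`` from the
    3' border inward, ``downstream`` nearest-to-farthest from the 3'
    border.  Bins with no contributing site are NaN, not zero.
    """

    length_class: str
    context: str
    bin_size: int
    flank: int
    interior_budget: int  # bins per side
    levels: dict = field(default_factory=dict)   # segment -> float array
    n_sites: dict = field(default_factory=dict)  # segment -> int array

    def axis(self) -> tuple[np.ndarray, np.ndarray]:
        """(levels, n_sites) concatenated left-to-right along the meta-TE axis."""
        lv = np.concatenate([
            self.levels["upstream"], self.levels["interior_5p"],
            self.levels["interior_3p"][::-1], self.levels["downstream"],
        ])
        ns = np.concatenate([
            self.n_sites["upstream"], self.n_sites["interior_5p"],
            self.n_sites["interior_3p"][::-1], self.n_sites["downstream"],
        ])
        return lv, ns


@dataclass
class RelativePositionHistogram:
    """Occurrences of points at scaled [0,1] positions over their features."""

    positions: np.ndarray
    counts: np.ndarray
    edges: np.ndarray


def classify_tes(
    tes: Sequence[GenomicInterval],
    boundaries: tuple[int, int] = DEFAULT_CLASS_BOUNDARIES,
) -> dict[str, list[GenomicInterval]]:
    """Split TEs into three length classes (default <1 kb, 1-2 kb, >=2 kb)."""
    b0, b1 = boundaries
    if not b0 < b1:
        raise ValidationError("class boundaries must be strictly increasing")
    kb = lambda x: f"{x / 1000:g}kb"
    labels = (f"<{kb(b0)}", f"{kb(b0)}-{kb(b1)}", f">={kb(b1)}")
    out: dict[str, list[GenomicInterval]] = {lab: [] for lab in labels}
    for te in tes:
        if te.length < b0:
            out[labels[0]].append(te)
        elif te.length < b1:
            out[labels[1]].append(te)
        else:
            out[labels[2]].append(te)
    return out


def build_meta_profile(
    methylome: StageMethylome,
    tes_of_class: Sequence[GenomicInterval],
    context: str,
    flank: int = 4000,
    bin_size: int = 10,
    length_class: str = "",
) -> MetaProfile:
    """Pool methylation over end-aligned TEs of one length class.

    The interior budget per side is floor(shortest_length / 2 / bin_size)
    bins, so interior bins never overlap within the shortest class
    member.  Each bin's value is the pooled level (sum C / sum C+T) over
    every site falling into that bin across all TEs; sites in the shared
    flank of two nearby TEs contribute to both.
    """
    if flank <= 0 or bin_size <= 0:
        raise ValidationError("flank and bin_size must be positive")
    if not tes_of_class:
        raise ValidationError("empty TE class")
    min_len = min(t.length for t in tes_of_class)
    budget = min_len // 2 // bin_size
    n_flank = flank // bin_size

    df = methylome.subset_context(context)
    by_chrom = {
        chrom: (
            sub["pos"].to_numpy(),
            sub["n_meth"].to_numpy(),
            sub["n_unmeth"].to_numpy(),
        )
        for chrom, sub in df.groupby("chrom", sort=False)
    }

    sums = {s: np.zeros(n, dtype=float)
            for s, n in zip(SEGMENTS, (n_flank, budget, budget, n_flank))}
    tots = {s: np.zeros_like(v) for s, v in sums.items()}
    ns = {s: np.zeros(v.shape, dtype=int) for s, v in sums.items()}

    for te in tes_of_class:
        if te.chrom not in by_chrom:
            continue
        pos, nm, nu = by_chrom[te.chrom]
        lo = np.searchsorted(pos, te.start - flank, side="left")
        hi = np.searchsorted(pos, te.end + flank, side="left")
        p, m, u = pos[lo:hi], nm[lo:hi], nu[lo:hi]
        if not len(p):
            continue
        minus = te.strand == "-"
        # distance of each site from the 5' and 3' borders along the TE axis
        if minus:
            off5 = te.end - 1 - p      # >=0 inside, <0 in the 5' (genomic right) flank
            off3 = p - te.start
        else:
            off5 = p - te.start
            off3 = te.end - 1 - p
        inside = (p >= te.start) & (p < te.end)
        up = off5 < 0
        down = off3 < 0
        _pool(sums, tots, ns, "upstream",
              n_flank - 1 - (-off5[up] - 1) // bin_size,
              m[up], u[up], n_flank)
        _pool(sums, tots, ns, "downstream",
              (-off3[down] - 1) // bin_size, m[down], u[down], n_flank)
        b5 = off5[inside] // bin_size
        keep5 = b5 < budget
        _pool(sums, tots, ns, "interior_5p", b5[keep5],
              m[inside][keep5], u[inside][keep5], budget)
        b3 = off3[inside] // bin_size
        keep3 = b3 < budget
        _pool(sums, tots, ns, "interior_3p", b3[keep3],
              m[inside][keep3], u[inside][keep3], budget)

    prof = MetaProfile(length_class or f"n={len(tes_of_class)}", context,
                       bin_size, flank, int(budget))
    for s in SEGMENTS:
        with np.errstate(invalid="ignore", divide="ignore"):
            prof.levels[s] = np.where(tots[s] > 0, sums[s] / tots[s], np.nan)
        prof.n_sites[s] = ns[s]
    return prof


def _pool(sums, tots, ns, segment, idx, m, u, n_bins):
    if not len(idx):
        return
    idx = idx.astype(int)
    np.add.at(sums[segment], idx, m)
    np.add.at(tots[segment], idx, m + u)
    np.add.at(ns[segment], idx, 1)


def relative_positions(
    features: Sequence[GenomicInterval],
    points: Sequence[tuple[str, float]],
    n_bins: int = 50,
) -> RelativePositionHistogram:
    """Scale point positions to [0,1] over their containing feature.

    Each point must lie inside at least one feature; when several
    contain it, the smallest (then leftmost) is used, so the histogram
    total equals the input count.  Minus-strand features are mirrored.
    """
    trees: dict[str, IntervalTree] = {}
    feats: dict[tuple, GenomicInterval] = {}
    for f in features:
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
    rel = np.empty(len(points), dtype=float)
    for i, (chrom, x) in enumerate(points):
        tree = trees.get(chrom)
        hits = sorted(tree.overlap(x, x + 1e-9), key=lambda h: (h.end - h.begin, h.begin)) if tree else []
        if not hits:
            raise ValidationError(f"point {chrom}:{x} lies inside no feature")
        f: GenomicInterval = hits[0].data
        r = (x - f.start) / f.length
        rel[i] = 1.0 - r if f.strand == "-" else r
    counts, edges = np.histogram(rel, bins=n_bins, range=(0.0, 1.0))
    return RelativePositionHistogram(rel, counts, edges)
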