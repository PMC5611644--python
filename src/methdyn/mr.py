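"""Methylated-region (MR) calling from fixed-width windows.

The genome is tiled into non-overlapping 100-nt windows per context; a
window is methylated when its pooled level reaches the context threshold
(CG 40%, CHG 20%, CHH 10%, inclusive), and maximal runs of methylated
windows (with an optional gap budget) are merged into MRs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CONTEXTS, StageMethylome, ValidationError

#: Context-specific window-level thresholds ("reached at least", inclusive).
MR_THRESHOLDS: Mapping[str, float] = {"CG": 0.40, "CHG": 0.20, "CHH": 0.10}

DEFAULT_WINDOW = 100


@dataclass(frozen=True)
class WindowMethylation:
    """One fixed-width tile with pooled counts for a single context."""

    chrom: str
    start: int
    end: int
    context: str
    n_sites: int
    sum_meth: int
    sum_unmeth: int

    @property
    def level(self) -> float:
        total = self.sum_meth + self.sum_unmeth
        return self.sum_meth / total if total > 0 else float("nan")


@dataclass(frozen=True)
class MethylatedRegion:
    chrom: str
    start: int
    end: int
    context: str
    level: float       # coverage-weighted pooled level of member windows
    n_windows: int     # methylated windows merged into the region

    @property
    def length(self) -> int:
        return self.end - self.start


def tile_windows(
    methylome: StageMethylome,
    context: str,
    window_size: int = DEFAULT_WINDOW,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[WindowMethylation]:
    """Tile each chromosome from coordinate 0 into non-overlapping windows.

    Every covered cytosine of ``context`` lands in exactly one window by
    position (half-open bins).  Windows with no covered site carry an
    undefined (NaN) level.  ``chrom_sizes`` fixes the tiling extent; when
    absent it is inferred from the last covered site per chromosome.
    """
    if window_size <= 0:
        raise ValidationError("window_size must be positive")
    df = methylome.subset_context(context)
    out: list[WindowMethylation] = []
    chroms = (
        sorted(chrom_sizes) if chrom_sizes is not None else methylome.chromosomes()
    )
    for chrom in chroms:
        sub = df[df["chrom"] == chrom]
        covered = sub[(sub["n_meth"] + sub["n_unmeth"]) > 0]
        if chrom_sizes is not None:
            n_win = -(-chrom_sizes[chrom] // window_size)
        elif len(covered):
            n_win = int(covered["pos"].max()) // window_size + 1
        else:
            continue
        pos = covered["pos"].to_numpy()
        idx = pos // window_size
        sum_m = np.bincount(idx, weights=covered["n_meth"], minlength=n_win)
        sum_u = np.bincount(idx, weights=covered["n_unmeth"], minlength=n_win)
        n_sites = np.bincount(idx, minlength=n_win)
        for w in range(n_win):
            out.append(WindowMethylation(
                chrom, w * window_size, (w + 1) * window_size, context,
                int(n_sites[w]), int(sum_m[w]), int(sum_u[w]),
            ))
    return out


def score_window(
    window: WindowMethylation,
    thresholds: Mapping[str, float] = MR_THRESHOLDS,
) -> bool | None:
    """Methylated flag for one window; None when the level is undefined.

    The comparison is inclusive: a window exactly at its context threshold
    is methylated.
    """
    total = window.sum_meth + window.sum_unmeth
    if total == 0:
        return None
    return window.level >= thresholds[window.context]


def merge_mrs(
    windows: Sequence[WindowMethylation],
    thresholds: Mapping[str, float] = MR_THRESHOLDS,
    max_gap_windows: int = 0,
    min_sites: int = 1,
) -> list[MethylatedRegion]:
    """Merge runs of methylated windows into MRs.

    Up to ``max_gap_windows`` consecutive non-methylated or unscored
    windows may sit inside a region; unscored windows consume gap budget
    (conservative extension).  Windows with fewer than ``min_sites``
    covered cytosines are never scored methylated.  Region boundaries are
    set by methylated windows only, and the region level is the pooled
    (coverage-weighted) ratio over its methylated members.
    """
    by_key: dict[tuple[str, str], list[WindowMethylation]] = {}
    for w in windows:
        by_key.setdefault((w.chrom, w.context), []).append(w)
    regions: list[MethylatedRegion] = []
    for (chrom, context), ws in sorted(by_key.items()):
        ws = sorted(ws, key=lambda w: w.start)
        run: list[WindowMethylation] = []
        gap = 0
        for w in ws:
            flag = score_window(w, thresholds)
            meth = bool(flag) and w.n_sites >= min_sites
            if meth:
                run.append(w)
                gap = 0
            elif run:
                gap += 1
                if gap > max_gap_windows:
                    regions.append(_finish_region(run, chrom, context))
                    run, gap = [], 0
        if run:
            regions.append(_finish_region(run, chrom, context))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def _finish_region(run, chrom, context) -> MethylatedRegion:
    sm = sum(w.sum_meth for w in run)
    su = sum(w.sum_unmeth for w in run)
    return MethylatedRegion(
        chrom, run[0].start, run[-1].end, context,
        sm / (sm + su), len(run),
    )


def call_mrs(
    methylome: StageMethylome,
    context: str,
    window_size: int = DEFAULT_WINDOW,
    thresholds: Mapping[str, float] = MR_THRESHOLDS,
    max_gap_windows: int = 0,
    min_sites: int = 1,
    chrom_sizes: Mapping[str, int] | None = None,
) -> list[MethylatedRegion]:
    """Tile, score and merge in one call."""
    windows = tile_windows(methylome, context, window_size, chrom_sizes)
    return merge_mrs(windows, thresholds, max_gap_windows, min_sites)


def summarize_mrs(groups: Mapping[str, Sequence[MethylatedRegion]]) -> pd.DataFrame:
    """Count and length/level quartiles per labelled MR group (stage, context...)."""
    rows = []
    for label, regions in groups.items():
        if not regions:
            rows.append({"group": label, "count": 0})
            continue
        lengths = np.array([r.length for r in regions], dtype=float)
        levels = np.array([r.level for r in regions], dtype=float)
        q = lambda a, p: float(np.quantile(a, p))
        rows.append({
            "group": label,
            "count": len(regions),
            "length_q25": q(lengths, 0.25),
            "length_median": q(lengths, 0.5),
            "length_q75": q(lengths, 0.75),
            "level_q25": q(levels, 0.25),
            "level_median": q(levels, 0.5),
            "level_q75": q(levels, 0.75),
        })
    return pd.DataFrame(rows)
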