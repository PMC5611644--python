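"""Chromosome-scale stage comparisons, saturated-CHH cataloguing, and the
DMR heat matrix with deterministic complete-linkage ordering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .io import GenomicInterval, StageMethylome, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ChromProfile:
    """Per-100-kb pooled levels of two stages along one chromosome."""

    chrom: str
    window: int
    starts: np.ndarray
    level_a: np.ndarray      # NaN where the window has no covered site
    level_b: np.ndarray
    series: np.ndarray       # ratio a/(b+eps) or difference a-b per window
    trend: np.ndarray        # polynomial least-squares fit of the series
    mode: str


@dataclass
class SaturatedSiteCatalog:
    """CHH sites with 100% methylation at adequate coverage, per stage."""

    stage: str
    min_cov: int
    table: pd.DataFrame      # chrom, pos, strand, coverage, te_ids

    def positions(self) -> set:
        return set(zip(self.table["chrom"], self.table["pos"],
                       self.table["strand"]))

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class DmrHeatMatrix:
    """DMR x (stage, context) matrix of unweighted mean site levels."""

    values: np.ndarray                  # rows x columns, NaN = undefined
    columns: list                       # (stage, context) tuples
    dmrs: list
    n_dropped: int

    def cg_submatrix(self) -> np.ndarray:
        idx = [i for i, (_, c) in enumerate(self.columns) if c == "CG"]
        if not idx:
            raise ValidationError("matrix has no CG columns")
        return self.values[:, idx]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{s}|{c}" for s, c in self.columns]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "chrom", [d.chrom for d in self.dmrs])
        df.insert(1, "start", [d.start for d in self.dmrs])
        df.insert(2, "end", [d.end for d in self.dmrs])
        return df


def chrom_profile(
    meth_a: StageMethylome,
    meth_b: StageMethylome,
    context: str,
    chrom: str,
    chrom_length: int,
    window: int = 100_000,
    pseudocount: float = 1e-3,
    degree: int = 3,
    mode: str = "ratio",
) -> ChromProfile:
    """Windowed stage-to-stage comparison along one chromosome.

    Pooled window levels; series = level_a / (level_b + pseudocount)
    (``mode="ratio"``) or level_a - level_b (``mode="diff"``); the trend
    is a least-squares polynomial (default cubic, capturing the
    pericentromeric bump; degree 1 gives a straight regression line).
    """
    if window > chrom_length:
        warnings.warn(f"window {window} exceeds {chrom} length; using one window")
        window = chrom_length
    n_win = -(-chrom_length // window)
    la = _window_levels(meth_a, context, chrom, window, n_win)
    lb = _window_levels(meth_b, context, chrom, window, n_win)
    if mode == "ratio":
        series = la / (lb + pseudocount)
    elif mode == "diff":
        series = la - lb
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    starts = np.arange(n_win) * window
    mid = starts + window / 2
    ok = np.isfinite(series)
    trend = np.full(n_win, np.nan)
    if ok.sum() > degree:
        coef = np.polynomial.polynomial.polyfit(mid[ok], series[ok], degree)
        trend[ok] = np.polynomial.polynomial.polyval(mid[ok], coef)
    return ChromProfile(chrom, window, starts, la, lb, series, trend, mode)


def _window_levels(meth, context, chrom, window, n_win) -> np.ndarray:
    df = meth.subset_context(context)
    df = df[df["chrom"] == chrom]
    idx = df["pos"].to_numpy() // window
    keep = idx < n_win
    sm = np.bincount(idx[keep], weights=df["n_meth"].to_numpy()[keep],
                     minlength=n_win)
    tot = sm + np.bincount(idx[keep], weights=df["n_unmeth"].to_numpy()[keep],
                           minlength=n_win)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, sm / tot, np.nan)


def find_saturated_chh(
    methylome: StageMethylome,
    min_cov: int = 5,
    tes: Sequence[GenomicInterval] | None = None,
) -> SaturatedSiteCatalog:
    """Catalog CHH sites where every covering read reports methylation.

    A site qualifies when n_unmeth == 0 and n_meth >= min_cov; each is
    associated with the ids of TEs containing it.
    """
    if min_cov < 1:
        raise ValidationError("min_cov must be >= 1")
    df = methylome.subset_context("CHH")
    sat = df[(df["n_unmeth"] == 0) & (df["n_meth"] >= min_cov)].copy()
    te_ids = [""] * len(sat)
    if tes:
        trees: dict[str, IntervalTree] = {}
        for t in tes:
            trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, t.id)
        te_ids = []
        for chrom, pos in zip(sat["chrom"], sat["pos"]):
            tree = trees.get(chrom)
            hits = sorted(h.data for h in tree.overlap(pos, pos + 1)) if tree else []
            te_ids.append(",".join(hits))
    out = pd.DataFrame({
        "chrom": sat["chrom"].to_numpy(),
        "pos": sat["pos"].to_numpy(),
        "strand": sat["strand"].to_numpy(),
        "coverage": sat["n_meth"].to_numpy(),
        "te_ids": te_ids,
    })
    return SaturatedSiteCatalog(methylome.stage, min_cov, out)


def build_heat_matrix(
    dmrs: Sequence,
    stage_methylomes: Mapping[str, StageMethylome],
    contexts: Sequence[str] = ("CG", "CHG", "CHH"),
) -> DmrHeatMatrix:
    """Mean per-site methylation of each DMR across stages and contexts.

    Cells are the *unweighted* mean of per-site levels of covered
    cytosines overlapping the DMR.  Rows (DMRs) with no covered cytosine
    in some stage are dropped and counted.
    """
    if not dmrs:
        raise ValidationError("no DMRs supplied")
    if len(stage_methylomes) < 2:
        raise ValidationError("need at least two stages")
    stages = list(stage_methylomes)
    cache: dict[tuple[str, str, str], tuple[np.ndarray, np.ndarray]] = {}
    for stage, meth in stage_methylomes.items():
        for ctx in contexts:
            sub = meth.subset_context(ctx)
            for chrom, grp in sub.groupby("chrom", sort=False):
                cov = (grp["n_meth"] + grp["n_unmeth"]).to_numpy()
                lvl = np.where(cov > 0, grp["n_meth"].to_numpy() / np.maximum(cov, 1),
                               np.nan)
                cache[(stage, ctx, chrom)] = (grp["pos"].to_numpy(), lvl)

    columns = [(s, c) for s in stages for c in contexts]
    rows, kept, dropped = [], [], 0
    for d in dmrs:
        row = np.full(len(columns), np.nan)
        covered_per_stage = {s: 0 for s in stages}
        for j, (stage, ctx) in enumerate(columns):
            pos, lvl = cache.get((stage, ctx, d.chrom), (np.array([]), np.array([])))
            lo = np.searchsorted(pos, d.start, side="left")
            hi = np.searchsorted(pos, d.end, side="left")
            vals = lvl[lo:hi]
            vals = vals[np.isfinite(vals)]
            covered_per_stage[stage] += len(vals)
            if len(vals):
                row[j] = float(vals.mean())
        if min(covered_per_stage.values()) == 0:
            dropped += 1
            continue
        rows.append(row)
        kept.append(d)
    if not rows:
        raise ValidationError("every DMR row was dropped for missing coverage")
    if dropped:
        logger.info("dropped %d/%d DMRs uncovered in some stage",
                    dropped, len(dmrs))
    return DmrHeatMatrix(np.vstack(rows), columns, kept, dropped)


def cluster_rows(matrix: DmrHeatMatrix) -> np.ndarray:
    """Deterministic complete-linkage / Manhattan row order on CG columns.

    Rows are first put into a canonical order (lexicographic on CG
    values, remaining columns as tie keys) so the result is invariant to
    input row permutation; the dendrogram's children are ordered by
    cluster size, then smallest canonical index.  Returns the row order
    as indices into the input matrix; non-CG columns follow the same
    permutation by construction.
    """
    cg = matrix.cg_submatrix()
    if not np.all(np.isfinite(cg)):
        raise ValidationError("undefined CG cell; filter rows before clustering")
    n = cg.shape[0]
    if n == 1:
        return np.array([0])
    other_idx = [i for i, (_, c) in enumerate(matrix.columns) if c != "CG"]
    tie_keys = matrix.values[:, other_idx] if other_idx else np.zeros((n, 0))
    sort_key = np.hstack([cg, np.nan_to_num(tie_keys, nan=-1.0)])
    canon = np.lexsort(sort_key.T[::-1])  # first column most significant
    data = cg[canon]
    Z = linkage(data, method="complete", metric="cityblock")
    order = _deterministic_leaf_order(Z, n)
    return canon[order]


def _deterministic_leaf_order(Z: np.ndarray, n: int) -> np.ndarray:
    """Leaves of a scipy linkage, children ordered by (size, min leaf index)."""
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    for k, (a, b, _d, _c) in enumerate(Z):
        la, lb = members.pop(int(a)), members.pop(int(b))
        first, second = sorted((la, lb), key=lambda m: (len(m), min(m)))
        members[n + k] = first + second
    (leaves,) = members.values()
    return np.array(leaves)


def ordered_heat_matrix(matrix: DmrHeatMatrix) -> DmrHeatMatrix:
    """The heat matrix with rows in clustering order."""
    order = cluster_rows(matrix)
    return DmrHeatMatrix(
        matrix.values[order], list(matrix.columns),
        [matrix.dmrs[i] for i in order], matrix.n_dropped,
    )
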