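"""Domain types and readers/writers shared by every pipeline stage.

All coordinates are 0-based half-open internally; 1-based formats
(cytosine reports, GFF3) are converted at the I/O boundary.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")

#: Columns of the internal methylome table, in order.
METHYLOME_COLUMNS = ("chrom", "pos", "strand", "context", "n_meth", "n_unmeth")


class FormatError(ValueError):
    """Raised when a file cannot be parsed (malformed line, unknown extension)."""


class ValidationError(ValueError):
    """Raised when parsed content violates a domain invariant."""


@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine's bisulfite read counts.

    ``n_meth`` counts reads that retained C (methylated), ``n_unmeth``
    reads converted to T.  ``pos`` is 0-based.
    """

    chrom: str
    pos: int
    strand: str
    context: str
    n_meth: int
    n_unmeth: int

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def level(self) -> float:
        """Methylation level n_meth / coverage; undefined (NaN) at zero coverage."""
        cov = self.coverage
        return self.n_meth / cov if cov > 0 else float("nan")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) with an annotation kind and identifier."""

    chrom: str
    start: int
    end: int
    kind: str = "other"
    id: str = ""
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SmallRNARead:
    """A mapped small-RNA read; length is derived from the interval."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


class StageMethylome:
    """Per-cytosine methylation calls for one developmental stage.

    Thin wrapper over a pandas DataFrame with columns
    ``chrom, pos, strand, context, n_meth, n_unmeth`` (pos 0-based), sorted
    by (chrom, pos, strand) with no duplicate (chrom, pos, strand) keys.
    """

    def __init__(self, table: pd.DataFrame, stage: str = ""):
        df = table.loc[:, list(METHYLOME_COLUMNS)].copy()
        for col in ("pos", "n_meth", "n_unmeth"):
            df[col] = df[col].astype(np.int64)
        bad = ~df["context"].isin(CONTEXTS)
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"unknown context {df['context'].iloc[idx]!r} at record {idx}"
            )
        if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any():
            raise ValidationError("negative read counts")
        df = df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
        dup = df.duplicated(["chrom", "pos", "strand"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValidationError(
                f"duplicate record at {row.chrom}:{row.pos}({row.strand})"
            )
        self._df = df.reset_index(drop=True)
        self.stage = stage

    @classmethod
    def from_records(
        cls, records: Iterable[CytosineRecord], stage: str = ""
    ) -> "StageMethylome":
        rows = [
            (r.chrom, r.pos, r.strand, r.context, r.n_meth, r.n_unmeth)
            for r in records
        ]
        df = pd.DataFrame(rows, columns=list(METHYLOME_COLUMNS))
        if df.empty:
            df = _empty_methylome_frame()
        return cls(df, stage=stage)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[CytosineRecord]:
        for row in self._df.itertuples(index=False):
            yield CytosineRecord(
                row.chrom, int(row.pos), row.strand, row.context,
                int(row.n_meth), int(row.n_unmeth),
            )

    def records(self) -> Iterator[CytosineRecord]:
        return iter(self)

    def subset_context(self, context: str) -> pd.DataFrame:
        """View of the table restricted to one cytosine context."""
        if context not in CONTEXTS:
            raise ValidationError(f"unknown context {context!r}")
        return self._df[self._df["context"] == context]

    def chromosomes(self) -> list[str]:
        return sorted(self._df["chrom"].unique())

    @property
    def coverage(self) -> np.ndarray:
        return (self._df["n_meth"] + self._df["n_unmeth"]).to_numpy()

    @property
    def levels(self) -> np.ndarray:
        cov = self.coverage.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self._df["n_meth"].to_numpy() / cov, np.nan)

    def global_level(self, context: str | None = None) -> float:
        """Pooled methylation level (sum C / sum C+T), optionally per context."""
        df = self._df if context is None else self.subset_context(context)
        total = int(df["n_meth"].sum() + df["n_unmeth"].sum())
        return float(df["n_meth"].sum() / total) if total else float("nan")


def _empty_methylome_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "context": pd.Series(dtype=str),
            "n_meth": pd.Series(dtype=np.int64),
            "n_unmeth": pd.Series(dtype=np.int64),
        }
    )


# ---------------------------------------------------------------------------
# cytosine report (Bismark-style TSV dialect)
# ---------------------------------------------------------------------------

def read_cytosine_report(
    path: str | os.PathLike, min_coverage: int = 1, stage: str = ""
) -> StageMethylome:
    """Read a cytosine-report TSV into a :class:`StageMethylome`.

    Expected tab-separated columns: chrom, pos (1-based), strand, n_meth,
    n_unmeth, context[, trinucleotide].  Records with coverage below
    ``min_coverage`` are dropped.  Positions are converted to 0-based.
    """
    if min_coverage < 0:
        raise ValidationError("min_coverage must be >= 0")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 6 tab-separated fields, "
                    f"got {len(parts)}"
                )
            chrom, pos_s, strand, nm_s, nu_s, context = parts[:6]
            try:
                pos, n_meth, n_unmeth = int(pos_s), int(nm_s), int(nu_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field: {exc}")
            if strand not in STRANDS:
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            if context not in CONTEXTS:
                raise ValidationError(
                    f"{path}:{lineno}: unknown context token {context!r}"
                )
            if n_meth < 0 or n_unmeth < 0:
                raise ValidationError(f"{path}:{lineno}: negative count")
            if n_meth + n_unmeth >= min_coverage:
                rows.append((chrom, pos - 1, strand, context, n_meth, n_unmeth))
    df = (
        pd.DataFrame(rows, columns=list(METHYLOME_COLUMNS))
        if rows
        else _empty_methylome_frame()
    )
    meth = StageMethylome(df, stage=stage)
    logger.info("read %d cytosine records from %s", len(meth), path)
    return meth


def write_cytosine_report(methylome: StageMethylome, path: str | os.PathLike) -> None:
    """Write a methylome back to the cytosine-report dialect (1-based positions)."""
    df = methylome.df.copy()
    df["pos"] = df["pos"] + 1
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"])
    logger.info("wrote %d cytosine records to %s", len(df), path)


# ---------------------------------------------------------------------------
# annotations (BED / GFF3)
# ---------------------------------------------------------------------------

def read_annotations(
    path: str | os.PathLike,
    kind: str,
    feature_types: Sequence[str] | None = None,
) -> list[GenomicInterval]:
    """Read gene/TE/pericentromere annotations from BED or GFF3.

    BED is taken as 0-based half-open, GFF3 as 1-based inclusive; both are
    converted to the internal 0-based half-open convention and sorted per
    chromosome.  ``feature_types`` optionally restricts GFF3 rows by their
    type column.
    """
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".bed":
        intervals = _read_bed(path, kind)
    elif ext in (".gff", ".gff3"):
        intervals = _read_gff3(path, kind, feature_types)
    else:
        raise FormatError(f"unknown annotation extension {ext!r} for {path}")
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    logger.info("read %d %s annotations from %s", len(intervals), kind, path)
    return intervals


def _read_bed(path, kind) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start_s, end_s = parts[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate: {exc}")
            if end <= start:
                raise ValidationError(
                    f"{path}:{lineno}: empty interval {chrom}:{start}-{end}"
                )
            name = parts[3] if len(parts) > 3 and parts[3] else f"{kind}_{lineno}"
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "+"
            out.append(GenomicInterval(chrom, start, end, kind, name, strand))
    return out


def _read_gff3(path, kind, feature_types) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{lineno}: GFF3 needs 9 columns")
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = parts[:9]
            if feature_types is not None and ftype not in feature_types:
                continue
            try:
                start, end = int(start_s) - 1, int(end_s)  # 1-based incl -> half-open
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate: {exc}")
            if end <= start:
                raise ValidationError(
                    f"{path}:{lineno}: empty interval after conversion"
                )
            ident = f"{kind}_{lineno}"
            for fld in attrs.split(";"):
                if fld.startswith("ID="):
                    ident = fld[3:]
                    break
            out.append(
                GenomicInterval(
                    chrom, start, end, kind, ident,
                    strand if strand in ("+", "-") else "+",
                )
            )
    return out


def write_annotations_bed(
    intervals: Sequence[GenomicInterval], path: str | os.PathLike
) -> None:
    """Write annotation intervals as BED6 (score column 0)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# region output (MRs / DMRs as BED6)
# ---------------------------------------------------------------------------

def write_regions(regions: Sequence, path: str | os.PathLike) -> None:
    """Write called regions (MRs or DMRs) as BED6.

    Name = ``<context>_<direction>`` for DMRs, ``<context>_MR`` for MRs;
    score = mean |difference| (DMRs) or level (MRs) x1000, capped at 1000.
    """
    with open(path, "w") as fh:
        for r in regions:
            context = getattr(r, "context", "NA")
            direction = getattr(r, "direction", None)
            if direction is not None:
                name = f"{context}_{direction}"
                score_val = abs(getattr(r, "mean_diff"))
            else:
                name = f"{context}_MR"
                score_val = getattr(r, "level", 0.0)
            score = min(1000, int(round(score_val * 1000)))
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score}\t.\n")
    logger.info("wrote %d regions to %s", len(regions), path)


def read_regions(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read a BED6 region file back into plain intervals (kind = BED name)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: region BED needs >= 4 columns")
            out.append(
                GenomicInterval(
                    parts[0], int(parts[1]), int(parts[2]),
                    kind=parts[3], id=f"region_{lineno}",
                    strand=parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "+",
                )
            )
    return out


# ---------------------------------------------------------------------------
# small-RNA read tables
# ---------------------------------------------------------------------------

def read_sirna_table(
    path: str | os.PathLike, min_length: int = 18, max_length: int = 30
) -> list[SmallRNARead]:
    """Read small-RNA reads from a BED3/TSV (chrom, start, end) table.

    Reads whose length falls outside [min_length, max_length] are dropped
    at read-in (adapter fragments / degradation products).
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: need chrom, start, end")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValidationError(f"{path}:{lineno}: empty read interval")
            if min_length <= end - start <= max_length:
                out.append(SmallRNARead(chrom, start, end))
    logger.info("read %d small-RNA reads from %s", len(out), path)
    return out


def write_sirna_table(reads: Sequence[SmallRNARead], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
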