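"""Synthetic genomes, multi-stage methylomes and siRNA libraries with recorded truth.

The generator emulates the qualitative methylation dynamics of early
Arabidopsis development: CG methylation high and stable over TEs at all
stages; CHH methylation low in seedlings, elevated in embryos and
saturated (probability 1.0) at a planted set of RdDM-target CHH sites on
TE edges in the mature embryo; CHG intermediate.  Sequencing counts are
binomial draws at truncated-Poisson coverage.  Every planted feature is
recorded in a :class:`TruthTable` so downstream callers can be scored
against known truth.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenomicInterval, SmallRNARead, StageMethylome, METHYLOME_COLUMNS

STAGES = ("early_embryo", "mature_embryo", "seedling_4d", "seedling_10d")
COMPARTMENTS = ("te_edge", "te_interior", "gene_body", "background")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


def default_stage_profiles() -> dict:
    """True methylation probabilities per (stage, context, compartment).

    Encodes the developmental dynamics the pipeline is meant to resolve:
    CG on TEs ~0.85 at every stage, gene-body CG ~0.15; CHH on TEs 0.10 in
    seedlings, 0.25 in early embryos, 0.60 at mature-embryo TE edges;
    CHG intermediate between the two.
    """
    seedling = {
        ("CG", "te_edge"): 0.85, ("CG", "te_interior"): 0.85,
        ("CG", "gene_body"): 0.15, ("CG", "background"): 0.03,
        ("CHG", "te_edge"): 0.35, ("CHG", "te_interior"): 0.40,
        ("CHG", "gene_body"): 0.02, ("CHG", "background"): 0.02,
        ("CHH", "te_edge"): 0.10, ("CHH", "te_interior"): 0.10,
        ("CHH", "gene_body"): 0.02, ("CHH", "background"): 0.02,
    }
    early = dict(seedling)
    early.update({("CHH", "te_edge"): 0.25, ("CHH", "te_interior"): 0.25,
                  ("CHG", "te_interior"): 0.45})
    mature = dict(seedling)
    mature.update({("CHH", "te_edge"): 0.60, ("CHH", "te_interior"): 0.35,
                   ("CHG", "te_edge"): 0.45, ("CHG", "te_interior"): 0.50})
    return {
        "early_embryo": early,
        "mature_embryo": mature,
        "seedling_4d": dict(seedling),
        "seedling_10d": dict(seedling),
    }


@dataclass(frozen=True)
class PlantedDMR:
    """A region whose true methylation differs between two stages.

    The hyper member of ``stage_pair`` gets probability baseline + |diff|,
    the other member the baseline; the sign of ``diff`` says which member
    is hyper (positive: the first stage).
    """

    chrom: str
    start: int
    end: int
    context: str
    stage_pair: tuple[str, str]
    diff: float


@dataclass
class SimulationConfig:
    """Full description of one synthetic experiment; the seed determines everything."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    pericentromere_fraction: float = 0.2
    n_tes: int = 300
    te_length_range: tuple[int, int] = (200, 3000)
    te_edge_width: int = 300
    n_genes: int = 300
    gene_length_range: tuple[int, int] = (600, 3000)
    cytosine_spacing: float = 5.0   # mean bp between cytosines per strand
    context_weights: dict = field(
        default_factory=lambda: {"CG": 1.0, "CHG": 1.0, "CHH": 5.0}
    )
    coverage_mean: float = 20.0
    stage_profiles: dict = field(default_factory=default_stage_profiles)
    peri_chh_boost: dict = field(default_factory=lambda: {"early_embryo": 0.15})
    planted_dmrs: list = field(default_factory=list)
    planted_baseline: float = 0.05
    n_saturated_sites: int = 200
    saturated_stage: str = "mature_embryo"
    # siRNA library
    n_sirna_reads: int = 100_000
    sirna_enrichment_fold: float = 10.0
    sirna_frac_2122: float = 0.2

    def validate(self) -> None:
        if not 0 <= self.pericentromere_fraction < 1:
            raise ConfigurationError("pericentromere_fraction must be in [0,1)")
        for stage, prof in self.stage_profiles.items():
            for key, p in prof.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"probability {p} out of [0,1] for {stage}/{key}"
                    )
        if self.te_length_range[0] > self.te_length_range[1]:
            raise ConfigurationError("te_length_range inverted")
        if self.cytosine_spacing <= 1.0:
            raise ConfigurationError("cytosine_spacing must exceed 1 bp")


@dataclass
class TruthTable:
    """Everything the generator planted, for scoring callers against.

    ``mrs``: per (stage, context), intervals whose true probability passes
    the MR threshold; ``dmrs``: planted differential regions; ``saturated``
    : (chrom, pos, strand) of true-probability-1.0 CHH sites.
    """

    mrs: dict = field(default_factory=dict)
    dmrs: list = field(default_factory=list)
    saturated: list = field(default_factory=list)

    def dmr_intervals(
        self, stage_pair: tuple[str, str] | None = None, context: str | None = None
    ) -> list[GenomicInterval]:
        out = []
        for i, d in enumerate(self.dmrs):
            if context is not None and d.context != context:
                continue
            if stage_pair is not None and set(d.stage_pair) != set(stage_pair):
                continue
            out.append(GenomicInterval(d.chrom, d.start, d.end, "planted_dmr",
                                       f"planted_{i}"))
        return out

    def to_json(self, path) -> None:
        payload = {
            "mrs": {f"{s}|{c}": [[iv.chrom, iv.start, iv.end] for iv in ivs]
                    for (s, c), ivs in self.mrs.items()},
            "dmrs": [asdict(d) for d in self.dmrs],
            "saturated": [list(t) for t in self.saturated],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SimulatedGenome:
    """Annotations plus the reference cytosine landscape."""

    chrom_lengths: dict
    tes: list
    genes: list
    pericentromeres: list
    sites: pd.DataFrame  # chrom, pos, strand, context, compartment, peri(bool)

    @property
    def annotations(self) -> list[GenomicInterval]:
        return sorted(self.tes + self.genes,
                      key=lambda iv: (iv.chrom, iv.start, iv.end))


def _substream(seed: int, label: str) -> np.random.Generator:
    """Independent generator for one simulation component.

    Stable CRC32 hash of the label keys the substream so adding a stage
    never perturbs another stage's draws.
    """
    key = zlib.crc32(label.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _place_nonoverlapping(
    rng: np.random.Generator, region: tuple[int, int], lengths: np.ndarray
) -> list[tuple[int, int]]:
    """Place features of given lengths in a region without overlap.

    Free space is split into random gaps (multinomial), giving sorted,
    non-overlapping placements in one pass.
    """
    start, end = region
    total = int(lengths.sum())
    free = (end - start) - total
    if free < 0:
        raise ConfigurationError(
            f"features (total {total} bp) do not fit region of "
            f"{end - start} bp"
        )
    k = len(lengths)
    gaps = rng.multinomial(free, np.full(k + 1, 1.0 / (k + 1)))
    out, cursor = [], start
    for i, ln in enumerate(lengths):
        cursor += int(gaps[i])
        out.append((cursor, cursor + int(ln)))
        cursor += int(ln)
    return out


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Build annotations and the cytosine landscape for one synthetic genome.

    TEs are placed at >= 3x density inside the centered pericentromere;
    genes occupy the arms; cytosines are laid down per strand with
    geometric spacing and contexts drawn at CHH-heavy frequencies.
    """
    config.validate()
    rng = _substream(config.seed, "genome")
    chrom_lengths = {
        f"Chr{i + 1}": config.chrom_length for i in range(config.n_chroms)
    }
    tes: list[GenomicInterval] = []
    genes: list[GenomicInterval] = []
    peris: list[GenomicInterval] = []

    n_te_chrom = config.n_tes // config.n_chroms
    n_gene_chrom = config.n_genes // config.n_chroms
    lo, hi = config.te_length_range
    glo, ghi = config.gene_length_range

    for chrom, L in chrom_lengths.items():
        half = config.pericentromere_fraction / 2
        p0, p1 = int(L * (0.5 - half)), int(L * (0.5 + half))
        if p1 > p0:
            peris.append(GenomicInterval(chrom, p0, p1, "pericentromere",
                                         f"{chrom}_peri"))
        # 60% of TEs into the (default 20%-wide) pericentromere: ~6x arm density
        n_peri = int(round(n_te_chrom * 0.6)) if p1 > p0 else 0
        n_arm_te = n_te_chrom - n_peri

        peri_lengths = rng.integers(lo, hi + 1, size=n_peri)
        for s, e in _place_nonoverlapping(rng, (p0, p1), peri_lengths):
            strand = rng.choice(["+", "-", "."], p=[0.45, 0.45, 0.10])
            tes.append(GenomicInterval(chrom, s, e, "TE",
                                       f"{chrom}_TE{len(tes)}", str(strand)))

        # arms carry the remaining TEs interleaved with all genes
        for arm, frac in (((0, p0), 0.5), ((p1, L), 0.5)):
            n_te_arm = int(round(n_arm_te * frac))
            n_gene_arm = int(round(n_gene_chrom * frac))
            te_lengths = rng.integers(lo, hi + 1, size=n_te_arm)
            gene_lengths = rng.integers(glo, ghi + 1, size=n_gene_arm)
            kinds = np.array(["TE"] * n_te_arm + ["gene"] * n_gene_arm)
            lengths = np.concatenate([te_lengths, gene_lengths])
            order = rng.permutation(len(kinds))
            placements = _place_nonoverlapping(rng, arm, lengths[order])
            for (s, e), kind in zip(placements, kinds[order]):
                strand = str(rng.choice(["+", "-"]))
                if kind == "TE":
                    tes.append(GenomicInterval(chrom, s, e, "TE",
                                               f"{chrom}_TE{len(tes)}", strand))
                else:
                    genes.append(GenomicInterval(chrom, s, e, "gene",
                                                 f"{chrom}_g{len(genes)}", strand))

    sites = _simulate_sites(config, rng, chrom_lengths, tes, genes, peris)
    return SimulatedGenome(chrom_lengths, sorted(tes, key=lambda t: (t.chrom, t.start)),
                           sorted(genes, key=lambda g: (g.chrom, g.start)),
                           peris, sites)


def _simulate_sites(config, rng, chrom_lengths, tes, genes, peris) -> pd.DataFrame:
    ctx_names = list(config.context_weights)
    w = np.array([config.context_weights[c] for c in ctx_names], dtype=float)
    w /= w.sum()
    frames = []
    p_spacing = min(1.0, 1.0 / config.cytosine_spacing)
    for chrom, L in chrom_lengths.items():
        chrom_tes = sorted((t for t in tes if t.chrom == chrom),
                           key=lambda t: t.start)
        chrom_genes = sorted((g for g in genes if g.chrom == chrom),
                             key=lambda g: g.start)
        peri = next((p for p in peris if p.chrom == chrom), None)
        for strand in "+-":
            n_draw = int(L * p_spacing * 1.3) + 10
            steps = rng.geometric(p_spacing, size=n_draw)
            pos = np.cumsum(steps) - 1
            pos = pos[pos < L]
            ctx = rng.choice(len(ctx_names), size=len(pos), p=w)
            comp = _compartments(pos, chrom_tes, chrom_genes, config.te_edge_width)
            in_peri = (
                (pos >= peri.start) & (pos < peri.end)
                if peri is not None
                else np.zeros(len(pos), dtype=bool)
            )
            frames.append(pd.DataFrame({
                "chrom": chrom,
                "pos": pos.astype(np.int64),
                "strand": strand,
                "context": np.array(ctx_names, dtype=object)[ctx],
                "compartment": comp,
                "peri": in_peri,
            }))
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)


def _compartments(pos, tes, genes, edge_width) -> np.ndarray:
    """Assign each position to te_edge / te_interior / gene_body / background."""
    comp = np.full(len(pos), "background", dtype=object)
    g_start = np.array([g.start for g in genes])
    g_end = np.array([g.end for g in genes])
    if len(genes):
        idx = np.searchsorted(g_start, pos, side="right") - 1
        ok = idx >= 0
        in_gene = np.zeros(len(pos), dtype=bool)
        in_gene[ok] = pos[ok] < g_end[idx[ok]]
        comp[in_gene] = "gene_body"
    t_start = np.array([t.start for t in tes])
    t_end = np.array([t.end for t in tes])
    if len(tes):
        idx = np.searchsorted(t_start, pos, side="right") - 1
        ok = idx >= 0
        in_te = np.zeros(len(pos), dtype=bool)
        in_te[ok] = pos[ok] < t_end[idx[ok]]
        comp[in_te] = "te_interior"
        near_edge = np.zeros(len(pos), dtype=bool)
        sel = in_te
        near_edge[sel] = (
            (pos[sel] - t_start[idx[sel]] < edge_width)
            | (t_end[idx[sel]] - pos[sel] <= edge_width)
        )
        comp[near_edge] = "te_edge"
    return comp


def plant_truth(config: SimulationConfig, genome: SimulatedGenome,
                mr_thresholds: dict | None = None) -> TruthTable:
    """Record planted MRs, DMRs and saturated CHH sites for this configuration.

    MR truth per (stage, context) = TE intervals whose true probability
    (min over edge/interior compartments) passes the caller's context
    threshold.  Saturated sites are drawn from CHH positions on TE edges.
    """
    thresholds = mr_thresholds or {"CG": 0.40, "CHG": 0.20, "CHH": 0.10}
    truth = TruthTable(dmrs=list(config.planted_dmrs))
    for stage, prof in config.stage_profiles.items():
        for context, thr in thresholds.items():
            p_te = min(prof.get((context, "te_edge"), 0.0),
                       prof.get((context, "te_interior"), 0.0))
            if p_te >= thr:
                truth.mrs[(stage, context)] = [
                    GenomicInterval(t.chrom, t.start, t.end, "planted_mr", t.id)
                    for t in genome.tes
                ]
    rng = _substream(config.seed, "saturated")
    sites = genome.sites
    cand = sites[(sites["context"] == "CHH") & (sites["compartment"] == "te_edge")]
    n = min(config.n_saturated_sites, len(cand))
    if n:
        pick = rng.choice(len(cand), size=n, replace=False)
        chosen = cand.iloc[np.sort(pick)]
        truth.saturated = list(
            zip(chosen["chrom"], chosen["pos"].astype(int), chosen["strand"])
        )
    return truth


def simulate_stage(
    config: SimulationConfig,
    stage: str,
    genome: SimulatedGenome,
    truth: TruthTable | None = None,
) -> StageMethylome:
    """Draw one stage's methylome: binomial counts at truncated-Poisson coverage."""
    if stage not in config.stage_profiles:
        raise ConfigurationError(f"unknown stage {stage!r}")
    prof = config.stage_profiles[stage]
    sites = genome.sites
    p = np.empty(len(sites), dtype=float)
    ctx = sites["context"].to_numpy()
    comp = sites["compartment"].to_numpy()
    for c in set(ctx):
        for k in COMPARTMENTS:
            mask = (ctx == c) & (comp == k)
            if mask.any():
                p[mask] = prof.get((c, k), 0.0)
    boost = config.peri_chh_boost.get(stage, 0.0)
    if boost:
        mask = (ctx == "CHH") & (comp == "te_interior") & sites["peri"].to_numpy()
        p[mask] = np.minimum(1.0, p[mask] + boost)

    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    for d in config.planted_dmrs:
        if stage not in d.stage_pair:
            continue
        lo_p = config.planted_baseline
        hyper = d.stage_pair[0] if d.diff >= 0 else d.stage_pair[1]
        val = min(1.0, lo_p + abs(d.diff)) if stage == hyper else lo_p
        mask = (
            (chrom_arr == d.chrom)
            & (pos_arr >= d.start) & (pos_arr < d.end)
            & (ctx == d.context)
        )
        p[mask] = val

    if truth is not None and stage == config.saturated_stage and truth.saturated:
        sat = pd.MultiIndex.from_tuples(truth.saturated)
        idx = pd.MultiIndex.from_arrays(
            [chrom_arr, pos_arr, sites["strand"].to_numpy()]
        )
        p[idx.isin(sat)] = 1.0

    rng = _substream(config.seed, f"stage:{stage}")
    cov = rng.poisson(config.coverage_mean, size=len(sites))
    cov = np.maximum(cov, 1)  # clamp: every site sequenced at least once
    n_meth = rng.binomial(cov, p)
    df = pd.DataFrame({
        "chrom": chrom_arr,
        "pos": pos_arr,
        "strand": sites["strand"].to_numpy(),
        "context": ctx,
        "n_meth": n_meth.astype(np.int64),
        "n_unmeth": (cov - n_meth).astype(np.int64),
    })
    return StageMethylome(df, stage=stage)


def simulate_sirnas(
    config: SimulationConfig,
    genome: SimulatedGenome,
    truth: TruthTable,
) -> tuple[list[SmallRNARead], int]:
    """Draw a small-RNA library: 24-nt reads enriched over planted CHH-hyper loci.

    Returns (reads, library_total).  Target intervals are the planted
    CHH DMRs whose hyper member is the saturated stage (mature embryo);
    their per-bp read rate is ``sirna_enrichment_fold`` times background.
    A ``sirna_frac_2122`` fraction of the library is 21-22-nt reads
    scattered uniformly.
    """
    rng = _substream(config.seed, "sirna")
    targets = []
    for d in truth.dmrs:
        if d.context != "CHH":
            continue
        hyper = d.stage_pair[0] if d.diff >= 0 else d.stage_pair[1]
        if hyper == config.saturated_stage:
            targets.append((d.chrom, d.start, d.end))
    genome_bp = sum(genome.chrom_lengths.values())
    target_bp = sum(e - s for _, s, e in targets)
    fold = config.sirna_enrichment_fold

    n24 = int(round(config.n_sirna_reads * (1 - config.sirna_frac_2122)))
    n2122 = config.n_sirna_reads - n24
    # background rate lam such that lam*(genome - targets) + fold*lam*targets = n24;
    # an infinite fold means zero background (every 24-nt read is target-derived)
    if np.isinf(fold) and target_bp:
        lam, target_rate = 0.0, n24 / target_bp
    else:
        lam = n24 / (genome_bp - target_bp + fold * target_bp) if genome_bp else 0.0
        target_rate = fold * lam

    reads: list[SmallRNARead] = []
    chroms = list(genome.chrom_lengths)
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    # background 24-nt reads: uniform over the genome, thinned out of targets
    n_bg = rng.poisson(lam * genome_bp)
    for r in _uniform_reads(rng, chroms, lengths, n_bg, 24):
        if not any(r.chrom == c and s <= r.start < e for c, s, e in targets):
            reads.append(r)
    # enriched reads inside each target
    for chrom, s, e in targets:
        n_t = rng.poisson(target_rate * (e - s))
        starts = rng.integers(s, max(s + 1, e - 24), size=n_t)
        reads.extend(SmallRNARead(chrom, int(x), int(x) + 24) for x in starts)
    # 21-22-nt reads, uniform
    for ln in (21, 22):
        reads.extend(_uniform_reads(rng, chroms, lengths, n2122 // 2, ln))

    reads.sort(key=lambda r: (r.chrom, r.start))
    return reads, len(reads)


def _uniform_reads(rng, chroms, lengths, n, read_len) -> list[SmallRNARead]:
    if n <= 0:
        return []
    probs = lengths / lengths.sum()
    which = rng.choice(len(chroms), size=n, p=probs)
    out = []
    for i, chrom in enumerate(chroms):
        k = int((which == i).sum())
        if not k:
            continue
        starts = rng.integers(0, max(1, int(lengths[i]) - read_len), size=k)
        out.extend(SmallRNARead(chrom, int(s), int(s) + read_len) for s in starts)
    return out


@dataclass
class Experiment:
    """A fully simulated study: genome, truth, one methylome per stage, siRNAs."""

    config: SimulationConfig
    genome: SimulatedGenome
    truth: TruthTable
    stages: dict
    sirnas: list
    sirna_library_total: int


def random_planted_dmrs(
    config: SimulationConfig,
    genome: SimulatedGenome,
    n: int,
    context: str = "CHH",
    stage_pair: tuple[str, str] = ("mature_embryo", "seedling_4d"),
    diff: float = 0.3,
    length_range: tuple[int, int] = (300, 1000),
    grid: int = 100,
) -> list[PlantedDMR]:
    """Draw non-overlapping grid-aligned background intervals to plant as DMRs.

    Intervals avoid TEs and genes so the planted difference is the only
    methylation dynamic inside them; alignment to the analysis grid makes
    truth boundaries coincide with bin boundaries.
    """
    rng = _substream(config.seed, "planted_dmrs")
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_lengths}
    for iv in genome.tes + genome.genes:
        occupied[iv.chrom].append((iv.start, iv.end))
    out: list[PlantedDMR] = []
    attempts = 0
    while len(out) < n and attempts < n * 200:
        attempts += 1
        chrom = list(genome.chrom_lengths)[rng.integers(len(genome.chrom_lengths))]
        L = genome.chrom_lengths[chrom]
        ln = int(rng.integers(length_range[0] // grid,
                              length_range[1] // grid + 1)) * grid
        ln = max(grid, ln)
        start = int(rng.integers(0, (L - ln) // grid)) * grid
        end = start + ln
        clash = any(start < e and s < end for s, e in occupied[chrom])
        if clash:
            continue
        occupied[chrom].append((start, end))
        out.append(PlantedDMR(chrom, start, end, context, stage_pair, diff))
    if len(out) < n:
        raise ConfigurationError(f"could only place {len(out)}/{n} planted DMRs")
    return out


def simulate_experiment(
    config: SimulationConfig, stages: Sequence[str] | None = None
) -> Experiment:
    """End-to-end generation: genome, truth table, stage methylomes, siRNA library."""
    config.validate()
    genome = simulate_genome(config)
    truth = plant_truth(config, genome)
    stage_names = list(stages) if stages is not None else list(config.stage_profiles)
    meths = {s: simulate_stage(config, s, genome, truth) for s in stage_names}
    reads, total = simulate_sirnas(config, genome, truth)
    return Experiment(config, genome, truth, meths, reads, total)
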