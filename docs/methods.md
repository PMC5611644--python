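# Methods

This note records the models, parameter choices and numerical decisions
behind `methdyn`, and what the synthetic benchmark does and does not
establish about real data.

## Coordinate and counting conventions

All internal coordinates are 0-based half-open; 1-based formats
(cytosine reports, GFF3) are converted at the I/O boundary, which keeps
window tiling and annotation overlap free of off-by-one drift. Strands
are kept separate — symmetric CG dinucleotides are *not* collapsed —
matching the per-strand cytosine-report dialect and keeping read counts
auditable. Window, bin and region levels are pooled ratios
Σm/(Σm+Σu), i.e. coverage-weighted, everywhere except heat-map cells
(below).

## MR calling

Non-overlapping 100-nt windows per context; a window is methylated when
its pooled level *reaches* the context threshold (CG 0.40, CHG 0.20,
CHH 0.10 — the comparison is inclusive). Maximal runs of methylated
windows merge into MRs; a configurable gap budget (default 0) lets
non-methylated or uncovered windows sit inside a region, with uncovered
windows consuming budget (conservative extension) and region boundaries
set by methylated windows only. A minimum-site gate per window defaults
to 1; the stricter ≥4-site rule belongs to the DMR caller, where it is
part of the bin retention filter. MR level is the pooled ratio over
member methylated windows.

## DMR calling

100-bp bins; per bin one 2×2 Fisher exact test on pooled counts of the
two samples (not per-site tests combined). Site admission: coverage in
[10, 100] in **both** samples; bins with <4 admitted cytosines are
dropped before testing. BH adjustment spans all retained bins
genome-wide per context per comparison. A bin is selected when
q < 0.01 and |Δ| ≥ 0.40/0.20/0.20 (CG/CHG/CHH); the difference
threshold applies at bin level, and the merged DMR reports a
site-count-weighted mean difference. Same-direction bins merge across
at most one vacant 100-bp window; hyper and hypo bins never merge. An
optional consensus helper intersects significant bins across N
user-supplied comparisons (default 1) for replicate designs.

### Fisher exact test numerics

The two-sided p sums hypergeometric point probabilities not exceeding
the observed table's. For grand totals ≤ 300 the sum is computed in
exact integer arithmetic: all point probabilities of a margin-fixed
family share the denominator C(N, K), so the tie comparison reduces to
exact integer comparison of numerators — distinct probabilities can
differ by relative amounts far below double precision, and a log-space
tie rule cannot resolve them. Above 300 the summation runs in log space
(logsumexp) with a relative tie tolerance of 1e-7, where the discrete
spectrum is dense enough that the distinction is numerically
irrelevant. BH adjustment delegates to statsmodels' step-up
implementation behind a validating wrapper.

## Overlap enrichment

RF = k·N/(n₁·n₂); expected overlap n₁·n₂/N. Universe = all annotations
of the compared kind in the supplied file. The p-value is one-sided,
tied to the direction of RF relative to 1 (upper tail P(X ≥ k) for
enrichment, lower tail for depletion), X ~ Hypergeometric(N, n₁, n₂).
RF is undefined (NaN) when either set is empty; p is then 1.

## Meta-TE profiles

Three TE length classes (defaults <1 kb, 1–2 kb, ≥2 kb; boundaries
parameterized). Per class, both borders are aligned; 10-nt bins cover
4-kb flanks and ⌊shortest/2/bin⌋ interior bins per side, so interior
bins never overlap within the shortest member; longer TEs' deep
interiors beyond the budget are not profiled. Minus-strand TEs are
mirrored so bins run 5′→3′; TEs with "." strand are treated as plus
(deterministic fallback). Sites in the shared flank of two nearby TEs
contribute to both profiles — excluding them would bias dense
pericentromeric regions. Bins with no contributing site are NaN, never
zero. Relative-position histograms assign each point to its smallest
containing feature so counts are conserved.

## siRNA quantification

Size classes 21–22 nt and 24 nt. A read overlapping a region by ≥1 bp
counts once per region; RPM divides by the *total* mapped library size,
not the size-class subtotal. Multi-mapping weights are not modelled;
reads count at their given coordinates with weight 1. The group
comparison is a pooled-variance two-sample t-test (Welch by flag).

## Genome views

Chromosome profiles pool 100-kb windows; the stage series is
level_A/(level_B + ε) with ε = 0.001 (difference mode by flag), and the
trend is a least-squares polynomial over window midpoints — degree 1
for a straight regression line, default 3 to let the pericentromeric
bump show. Saturated-CHH sites require every covering read methylated
(n_unmeth = 0) at coverage ≥ 5 (default; the threshold is a free
parameter). Heat-map cells are the **unweighted mean of per-site
levels** of covered cytosines overlapping the DMR — deliberately
different from the callers' pooled ratios, reflecting a per-cytosine
averaging convention; rows uncovered in any stage are dropped and
counted. Row order comes from complete-linkage clustering with
Manhattan distance on the CG columns; rows are first canonically sorted
by value (CG columns, remaining columns as tie keys) and dendrogram
children ordered by (size, min canonical index), which makes the final
ordering invariant to input row permutation — raw linkage leaf order is
not.

## Synthetic-data generator

The generator emulates the study design the pipeline targets: four
stages (early embryo, mature embryo, 4-day and 10-day seedling) over a
genome with a centered pericentromere holding ~60% of TEs (≥3× arm
density), genes on the arms, and cytosines laid down per strand at a
mean spacing of 5 bp with context weights CG:CHG:CHH = 1:1:5.

Default true methylation probabilities encode the qualitative dynamics:
CG on TEs 0.85 at every stage and 0.15 in gene bodies; CHH on TEs 0.10
in seedlings, 0.25 in early embryos (with +0.15 in pericentromeric TE
interiors), and 0.60 at mature-embryo TE edges (0.35 interiors); CHG
intermediate. 200 CHH sites on TE edges are planted at probability 1.0
in the mature embryo (the saturated-site truth). Planted DMRs assign
the hypo member of a stage pair a 0.05 baseline and the hyper member
baseline + |Δ|, on 100-bp-aligned intervals placed outside annotations
so the planted difference is the only dynamic inside them. Coverage is
Poisson (mean 20) with zeros clamped to 1; methylated counts are
binomial. The 24-nt siRNA library is uniform background plus a 10×
(configurable) rate over planted embryonic CHH-hyper loci, with 20% of
the library as uniform 21–22-nt reads. One global seed determines
everything; each component (genome, stage, siRNA, placement) draws from
a substream keyed by a CRC32 hash of its label, so adding a stage never
perturbs another's data.

What the generator does **not** model: bisulfite conversion failure,
mapping bias, copy-number/multimapping structure, sequence composition,
linked sites, or mechanistic endosperm demethylation. Passing the
recovery benchmarks therefore shows the callers are correct *given*
binomially sampled counts at honest coverage — not that they are robust
to alignment artefacts or conversion error in real libraries.

## Benchmark problem sizes

The test suite and acceptance script exercise: the Fisher oracle on all
~245,000 tables with margins ≤ 30; BH on 10,000 random p-vectors; null
false-positive control on ≥5,000 CHH bins (600-kb null genome, 20×);
DMR recovery on 40 planted CHH DMRs (Δ = 0.3, 300–1,000 bp) in a 1-Mb
genome; and a full four-stage pipeline on a 2-Mb genome with 300 TEs,
200 saturated sites and 30 planted DMRs. These sizes give stable
pass/fail behavior for the property bounds while keeping a full run in
well under a minute per component.

## Known limitations and open choices

- The MR merge rule's gap tolerance and minimum site count are not
  canonical; both are parameters (defaults 0 and 1).
- Whether the DMR difference threshold should also bind on the merged
  mean is ambiguous; it binds per bin, and the merged mean is reported.
- Chromosome-profile "ratio" vs "difference" is a flag; ratio is the
  default, with a pseudocount guarding empty denominators.
- The consensus ("significant in all N comparisons") mode defaults to
  N = 1; multi-replicate designs must supply their own comparisons.
- RPM normalization assumes the supplied library total is the mapped
  total; no remapping or multimapper reweighting is attempted.
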