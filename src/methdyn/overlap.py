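"""Set-overlap enrichment between annotation-associated region sets.

The representation factor (RF) is the observed overlap of two annotation
sets divided by the overlap expected under independence within a finite
universe; significance comes from the hypergeometric tail on the side
the RF points to (upper when RF >= 1, lower otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from .io import GenomicInterval, ValidationError


@dataclass(frozen=True)
class OverlapResult:
    n_universe: int
    n_set1: int
    n_set2: int
    n_overlap: int
    expected: float
    rf: float          # NaN when expected == 0
    p_value: float


def annotation_sets(
    dmrs_a: Sequence, dmrs_b: Sequence, universe_annotations: Sequence[GenomicInterval]
) -> tuple[set, set, int]:
    """Distinct annotation ids touched by each DMR list, plus the universe size.

    Both DMR lists must have been run through annotation association.
    """
    if not universe_annotations:
        raise ValidationError("empty annotation universe")
    ids1 = {a for d in dmrs_a for a in d.annotations}
    ids2 = {a for d in dmrs_b for a in d.annotations}
    return ids1, ids2, len({iv.id for iv in universe_annotations})


def representation_factor(
    n_universe: int, n_set1: int, n_set2: int, n_overlap: int
) -> OverlapResult:
    """Observed/expected overlap with a one-sided hypergeometric p-value."""
    if not (0 <= n_set1 <= n_universe and 0 <= n_set2 <= n_universe):
        raise ValidationError("set sizes exceed universe")
    if not 0 <= n_overlap <= min(n_set1, n_set2):
        raise ValidationError("overlap exceeds a set size")
    if n_overlap < n_set1 + n_set2 - n_universe:
        raise ValidationError("overlap below the forced minimum")
    expected = n_set1 * n_set2 / n_universe
    rf = n_overlap / expected if expected > 0 else float("nan")
    # X ~ Hypergeom(universe, set1 marked, set2 drawn)
    if expected == 0:
        p = 1.0
    elif rf >= 1:
        p = float(hypergeom.sf(n_overlap - 1, n_universe, n_set1, n_set2))
    else:
        p = float(hypergeom.cdf(n_overlap, n_universe, n_set1, n_set2))
    return OverlapResult(n_universe, n_set1, n_set2, n_overlap,
                         expected, rf, min(1.0, p))


def overlap_dmr_sets(
    dmrs_a: Sequence, dmrs_b: Sequence, universe_annotations: Sequence[GenomicInterval]
) -> OverlapResult:
    """RF enrichment of the annotations shared by two DMR lists."""
    ids1, ids2, n_universe = annotation_sets(dmrs_a, dmrs_b, universe_annotations)
    return representation_factor(n_universe, len(ids1), len(ids2),
                                 len(ids1 & ids2))


def venn_counts(sets: dict[str, Iterable], n_universe: int) -> dict:
    """Exclusive Venn region counts for 2 or 3 named sets, plus pairwise RFs."""
    names = list(sets)
    if len(names) not in (2, 3):
        raise ValidationError("venn_counts supports 2 or 3 sets")
    ss = {k: set(v) for k, v in sets.items()}
    out: dict = {}
    if len(names) == 2:
        a, b = (ss[n] for n in names)
        out["counts"] = {
            names[0]: len(a - b), names[1]: len(b - a), "both": len(a & b),
        }
    else:
        a, b, c = (ss[n] for n in names)
        out["counts"] = {
            names[0]: len(a - b - c),
            names[1]: len(b - a - c),
            names[2]: len(c - a - b),
            f"{names[0]}&{names[1]}": len((a & b) - c),
            f"{names[0]}&{names[2]}": len((a & c) - b),
            f"{names[1]}&{names[2]}": len((b & c) - a),
            "all": len(a & b & c),
        }
    out["pairwise_rf"] = {
        f"{x}|{y}": representation_factor(
            n_universe, len(ss[x]), len(ss[y]), len(ss[x] & ss[y])
        )
        for i, x in enumerate(names)
        for y in names[i + 1:]
    }
    return out
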