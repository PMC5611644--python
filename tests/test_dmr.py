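import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methdyn.dmr import (
    DMR,
    BinComparison,
    DmrThresholds,
    associate_annotations,
    bh_adjust,
    bins_to_frame,
    build_bins,
    call_dmr_bins,
    call_dmrs,
    consensus_bins,
    fisher_exact_2x2,
    merge_dmrs,
)
from methdyn.io import GenomicInterval, ValidationError

from conftest import make_methylome
from _oracles import bh_adjusted_oracle, fisher_two_sided_oracle


def make_bin(start, diff, q, context="CHH", n_sites=4, chrom="Chr1"):
    """A bin with the requested level difference (sample depth 100)."""
    a = int(round((0.5 + diff / 2) * 100))
    b = int(round((0.5 - diff / 2) * 100))
    return BinComparison(chrom, start, start + 100, context,
                         a, 100 - a, b, 100 - b, n_sites, 0.0, q)


class TestFisher:
    def test_identical_proportions_give_p_one(self):
        assert fisher_exact_2x2(5, 5, 5, 5) == 1.0

    def test_extreme_table_matches_enumeration(self):
        # both one-sided extremes carry probability 1/C(20,10)
        assert fisher_exact_2x2(10, 0, 0, 10) == pytest.approx(2 / 184756,
                                                               abs=1e-15)

    @pytest.mark.parametrize("table", [
        (2, 8, 3, 7), (1, 9, 8, 2), (0, 5, 5, 0), (7, 3, 2, 8), (4, 0, 0, 4),
    ])
    def test_agrees_with_exact_oracle(self, table):
        got = fisher_exact_2x2(*table)
        want = float(fisher_two_sided_oracle(*table))
        assert got == pytest.approx(want, abs=1e-12)

    def test_large_table_log_space_path(self):
        # grand total > 300 exercises the log-space branch
        got = fisher_exact_2x2(200, 100, 100, 200)
        import scipy.stats as ss
        want = ss.fisher_exact([[200, 100], [100, 200]])[1]
        assert got == pytest.approx(want, rel=1e-9)

    def test_empty_row_returns_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert fisher_exact_2x2(0, 0, 3, 7) == 1.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_2x2(-1, 2, 3, 4)

    def test_symmetric_in_rows(self):
        assert fisher_exact_2x2(2, 8, 6, 4) == fisher_exact_2x2(6, 4, 2, 8)


class TestBH:
    def test_hand_executed_stepup(self):
        q = bh_adjust([0.01, 0.02, 0.03])
        assert q == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_matches_stepup_oracle_and_dominates_p(self, ps):
        q = bh_adjust(ps)
        assert np.allclose(q, bh_adjusted_oracle(np.array(ps)), atol=1e-12)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        # monotone when sorted by p
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestBuildBins:
    def cov_rows(self, specs, chrom="Chr1"):
        """specs: (pos, cov_a, cov_b) at 50% methylation in a, 10% in b."""
        a = [(chrom, p, "+", "CHH", ca // 2, ca - ca // 2) for p, ca, _ in specs]
        b = [(chrom, p, "+", "CHH", cb // 10, cb - cb // 10) for p, _, cb in specs]
        return make_methylome(a), make_methylome(b)

    def test_bin_with_three_passing_sites_dropped(self):
        a, b = self.cov_rows([(0, 20, 20), (10, 20, 20), (20, 20, 20)])
        assert build_bins(a, b, "CHH") == []

    def test_low_coverage_site_in_either_sample_excluded(self):
        # 4 sites but one at coverage 9 in sample b -> 3 passing -> dropped
        a, b = self.cov_rows([(0, 20, 20), (10, 20, 20), (20, 20, 20), (30, 20, 9)])
        assert build_bins(a, b, "CHH") == []
        a, b = self.cov_rows([(0, 20, 20), (10, 20, 20), (20, 20, 20), (30, 20, 10)])
        (bin_,) = build_bins(a, b, "CHH")
        assert bin_.n_sites_passing == 4

    def test_high_coverage_site_excluded(self):
        a, b = self.cov_rows([(0, 20, 20), (10, 20, 20), (20, 20, 20), (30, 101, 20)])
        assert build_bins(a, b, "CHH") == []

    def test_mismatched_chromosomes_rejected(self):
        a = make_methylome([("Chr1", 0, "+", "CHH", 10, 10)])
        b = make_methylome([("Chr2", 0, "+", "CHH", 10, 10)])
        with pytest.raises(ValidationError, match="chromosome"):
            build_bins(a, b, "CHH")

    def test_pooled_counts_and_q_dominates_p(self):
        specs = [(p, 20, 20) for p in range(0, 40, 10)]
        a, b = self.cov_rows(specs)
        (bin_,) = build_bins(a, b, "CHH")
        assert bin_.a_meth == 40 and bin_.b_meth == 8
        assert bin_.level_a == pytest.approx(0.5)
        assert bin_.diff == pytest.approx(0.4)
        assert bin_.q_value >= bin_.p_value


class TestCallBins:
    def test_selection_rules(self):
        thr = DmrThresholds()
        selected = call_dmr_bins([make_bin(0, 0.45, 0.001, "CG")], thr)
        assert len(selected) == 1
        # difference threshold binds regardless of q
        assert call_dmr_bins([make_bin(0, 0.39, 1e-10, "CG")], thr) == []
        # FDR binds regardless of difference
        assert call_dmr_bins([make_bin(0, 0.25, 0.02, "CHH")], thr) == []

    def test_direction_is_sign_of_diff(self):
        thr = DmrThresholds()
        (d,) = merge_dmrs(call_dmr_bins([make_bin(0, -0.5, 1e-4)], thr))
        assert d.direction == "hypo" and d.mean_diff < 0


class TestMerge:
    def test_one_gap_bin_merges_two_do_not(self):
        b1, b2 = make_bin(0, 0.3, 1e-4), make_bin(200, 0.3, 1e-4)
        (d,) = merge_dmrs([b1, b2], merge_gap_windows=1)
        assert (d.start, d.end, d.n_bins) == (0, 300, 2)
        b3 = make_bin(300, 0.3, 1e-4)
        assert len(merge_dmrs([b1, b3], merge_gap_windows=1)) == 2

    def test_adjacent_hyper_and_hypo_stay_separate(self):
        ds = merge_dmrs([make_bin(0, 0.3, 1e-4), make_bin(100, -0.3, 1e-4)])
        assert sorted(d.direction for d in ds) == ["hyper", "hypo"]

    def test_mean_diff_weighted_by_site_counts(self):
        b1 = make_bin(0, 0.2, 1e-4, n_sites=4)
        b2 = make_bin(100, 0.5, 1e-4, n_sites=12)
        (d,) = merge_dmrs([b1, b2])
        assert d.mean_diff == pytest.approx((0.2 * 4 + 0.5 * 12) / 16)


class TestAssociate:
    def test_one_bp_overlap_associates(self):
        d = DMR("Chr1", 150, 250, "CHH", "hyper", 0.3, 1)
        te = GenomicInterval("Chr1", 200, 600, "TE", "TE1")
        (out,) = associate_annotations([d], [te])
        assert out.annotations == ("TE1",) and not out.intergenic

    def test_half_open_adjacency_is_no_overlap(self):
        d = DMR("Chr1", 0, 100, "CHH", "hyper", 0.3, 1)
        te = GenomicInterval("Chr1", 100, 200, "TE", "TE1")
        (out,) = associate_annotations([d], [te])
        assert out.intergenic

    def test_spanning_dmr_gets_both_ids(self):
        d = DMR("Chr1", 0, 1000, "CHH", "hyper", 0.3, 1)
        tes = [GenomicInterval("Chr1", 100, 200, "TE", "TE1"),
               GenomicInterval("Chr1", 300, 400, "TE", "TE2")]
        (out,) = associate_annotations([d], tes)
        assert out.annotations == ("TE1", "TE2")


def test_consensus_requires_significance_in_every_comparison():
    c1 = [make_bin(0, 0.3, 1e-4), make_bin(100, 0.3, 1e-4)]
    c2 = [make_bin(100, 0.25, 1e-3)]
    assert [b.start for b in consensus_bins([c1, c2])] == [100]
    assert consensus_bins([]) == []


def test_swapping_samples_flips_directions_and_negates_diffs(small_stages):
    a, b = small_stages["mature_embryo"], small_stages["seedling_4d"]
    thr = DmrThresholds()
    fwd = build_bins(a, b, "CHH", thr)
    rev = build_bins(b, a, "CHH", thr)
    assert len(fwd) == len(rev)
    for x, y in zip(fwd, rev):
        assert (x.chrom, x.start) == (y.chrom, y.start)
        assert x.diff == pytest.approx(-y.diff)
        assert x.p_value == pytest.approx(y.p_value, abs=1e-12)
        assert x.q_value == pytest.approx(y.q_value, abs=1e-12)
    d_fwd = merge_dmrs(call_dmr_bins(fwd, thr))
    d_rev = merge_dmrs(call_dmr_bins(rev, thr))
    flip = {"hyper": "hypo", "hypo": "hyper"}
    assert {(d.chrom, d.start, d.end, flip[d.direction]) for d in d_fwd} == {
        (d.chrom, d.start, d.end, d.direction) for d in d_rev}


def test_full_call_yields_annotated_te_dmrs(small_stages, small_genome):
    dmrs = call_dmrs(small_stages["mature_embryo"], small_stages["seedling_4d"],
                     "CHH", annotations=small_genome.annotations)
    assert dmrs
    hyper = [d for d in dmrs if d.direction == "hyper"]
    # embryonic CHH gain concentrates on TEs
    te_frac = np.mean([any(a.startswith("Chr1_TE") for a in d.annotations)
                       for d in hyper])
    assert te_frac > 0.8
    frame = bins_to_frame(build_bins(small_stages["mature_embryo"],
                                     small_stages["seedling_4d"], "CHH"))
    assert {"p_value", "q_value", "diff"} <= set(frame.columns)
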