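import itertools

import numpy as np
import pytest
from scipy import special

from cnvpop.calling import GAIN, LOSS, CNVSegment
from cnvpop.errors import InputDataError
from cnvpop.regions import (
    CNVR,
    CNV_SIZE_BINS_KB,
    CNVR_SIZE_BINS_KB,
    chromosome_count_regression,
    merge_calls_to_cnvrs,
    population_cnvr_sets,
    summarize_sizes,
)

from conftest import build_norm, vectors_with_exact_correlation


def _segment(norm, w0, w1, direction=GAIN):
    """CNVSegment over grid windows [w0, w1)."""
    grid = norm.grid.windows
    return CNVSegment(
        chrom=str(grid["chrom"].iloc[w0]),
        start=int(grid["start"].iloc[w0]),
        end=int(grid["end"].iloc[w1 - 1]),
        direction=direction,
        window_indices=tuple(range(w0, w1)),
        mean_rd=norm.values[w0:w1].mean(axis=0),
    )


class TestCallToCnvrMerge:
    def test_close_identical_calls_merge(self):
        # window size 100: calls [0,1000) and [1100,2000); gap 100 < 0.2*1900
        base = np.abs(np.random.default_rng(0).normal(1, 0.3, 24))
        values = np.tile(base, (20, 1))
        norm = build_norm(values, window_size=100)
        calls = [_segment(norm, 0, 10), _segment(norm, 11, 20)]
        cnvrs = merge_calls_to_cnvrs(calls, norm)
        assert len(cnvrs) == 1
        assert (cnvrs[0].start, cnvrs[0].end) == (0, 2000)
        assert cnvrs[0].cnvr_type == "GAIN"
        assert cnvrs[0].call_ids == (0, 1)

    def test_distant_calls_never_merge(self):
        # calls [0,1000) and [1500,2400): gap 500 > 0.2*1900 = 380
        base = np.abs(np.random.default_rng(0).normal(1, 0.3, 24))
        values = np.tile(base, (24, 1))
        norm = build_norm(values, window_size=100)
        calls = [_segment(norm, 0, 10), _segment(norm, 15, 24)]
        assert len(merge_calls_to_cnvrs(calls, norm)) == 2

    @pytest.mark.parametrize("r, merged", [(0.52, True), (0.50, False)])
    def test_merge_boundary_at_alpha_001(self, r, merged):
        """n=24: r=0.52 has p ~ 0.0092 < 0.01; r=0.50 has p ~ 0.0128."""
        n = 24
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p = 2 * special.stdtr(n - 2, -abs(t))
        assert (p < 0.01) == merged  # the t-CDF oracle agrees with the claim
        x, y = vectors_with_exact_correlation(r, n, seed=3)
        values = np.vstack([1 + 0.05 * x, 1 + 0.05 * y])
        norm = build_norm(values, window_size=1000)
        calls = [_segment(norm, 0, 1), _segment(norm, 1, 2)]
        cnvrs = merge_calls_to_cnvrs(calls, norm, alpha=0.01)
        assert len(cnvrs) == (1 if merged else 2)

    def test_mixed_direction_constituents_become_both(self):
        base = np.abs(np.random.default_rng(1).normal(1, 0.3, 24))
        values = np.tile(base, (4, 1))
        norm = build_norm(values, window_size=100)
        calls = [_segment(norm, 0, 2, GAIN), _segment(norm, 2, 4, LOSS)]
        cnvrs = merge_calls_to_cnvrs(calls, norm)
        assert len(cnvrs) == 1 and cnvrs[0].cnvr_type == "BOTH"

    def test_every_call_lands_in_exactly_one_cnvr(self):
        rng = np.random.default_rng(9)
        values = np.abs(rng.normal(1, 0.25, (60, 24)))
        norm = build_norm(values, window_size=400)
        calls = [
            _segment(norm, s, s + rng.integers(1, 4), rng.choice([GAIN, LOSS]))
            for s in range(0, 55, 5)
        ]
        cnvrs = merge_calls_to_cnvrs(calls, norm)
        assert len(cnvrs) <= len(calls)
        ids = sorted(i for r in cnvrs for i in r.call_ids)
        assert ids == list(range(len(calls)))


def _oracle_fixpoint(calls, norm, gap_fraction, alpha, n):
    """Slow re-derivation: repeatedly merge the leftmost eligible sorted
    neighbor pair (gap + correlation rule), recomputing the merged region's
    RD vector, until no pair merges."""

    def region_vec(chrom, start, end):
        idx = norm.grid.windows_overlapping(chrom, start, end)
        return norm.values[idx].mean(axis=0)

    items = [
        {"chrom": c.chrom, "start": c.start, "end": c.end, "dirs": {c.direction},
         "ids": {i}, "vec": c.mean_rd}
        for i, c in enumerate(calls)
    ]
    while True:
        items.sort(key=lambda d: (d["chrom"], d["start"], d["end"]))
        for a, b in zip(items, items[1:]):
            if a["chrom"] != b["chrom"]:
                continue
            gap = b["start"] - a["end"]
            combined = (a["end"] - a["start"]) + (b["end"] - b["start"])
            if gap >= gap_fraction * combined:
                continue
            x, y = a["vec"], b["vec"]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            p = 0.0 if abs(r) >= 1 else 2 * special.stdtr(
                n - 2, -abs(r * np.sqrt((n - 2) / (1 - r * r)))
            )
            if p < alpha:
                a["end"] = max(a["end"], b["end"])
                a["dirs"] |= b["dirs"]
                a["ids"] |= b["ids"]
                a["vec"] = region_vec(a["chrom"], a["start"], a["end"])
                items.remove(b)
                break
        else:
            return {
                (d["chrom"], d["start"], d["end"], frozenset(d["ids"]))
                for d in items
            }


@pytest.mark.parametrize("seed", range(4))
def test_cnvr_merge_matches_pairwise_fixpoint_oracle(seed):
    rng = np.random.default_rng(seed)
    n_w, n_i = 90, 24
    values = np.abs(rng.normal(1, 0.2, (n_w, n_i)))
    # correlated blocks make some neighbors mergeable
    for s in range(0, n_w - 6, 9):
        base = rng.normal(1, 0.35, n_i)
        for k in range(6):
            values[s + k] = np.abs(base + rng.normal(0, rng.uniform(0.02, 0.5), n_i))
    norm = build_norm(values, window_size=500)
    calls, w = [], 0
    while w < n_w - 3 and len(calls) < 25:
        width = int(rng.integers(1, 4))
        calls.append(_segment(norm, w, w + width, int(rng.choice([GAIN, LOSS], p=[0.75, 0.25]))))
        w += width + int(rng.integers(1, 3))
    cnvrs = merge_calls_to_cnvrs(calls, norm, gap_fraction=0.2, alpha=0.01)
    got = {(r.chrom, r.start, r.end, frozenset(r.call_ids)) for r in cnvrs}
    assert got == _oracle_fixpoint(calls, norm, 0.2, 0.01, n_i)


def test_population_sets_all_shared():
    r = CNVR("chr1", 0, 1000, "GAIN", np.zeros(2))
    res = population_cnvr_sets({"A": [r], "B": [r], "C": [r]})
    assert res.venn == {("A", "B", "C"): 1}
    assert res.n_union == 1


def test_population_sets_disjoint():
    rs = {
        "A": [CNVR("chr1", 0, 100, "GAIN", np.zeros(2))],
        "B": [CNVR("chr1", 200, 300, "GAIN", np.zeros(2))],
        "C": [CNVR("chr2", 0, 100, "LOSS", np.zeros(2))],
    }
    res = population_cnvr_sets(rs)
    assert res.venn == {("A",): 1, ("B",): 1, ("C",): 1}
    assert res.n_union == 3


def test_population_sets_partial_overlap_components():
    rs = {
        "A": [CNVR("chr1", 0, 150, "GAIN", np.zeros(2))],
        "B": [CNVR("chr1", 100, 250, "GAIN", np.zeros(2))],
        "C": [CNVR("chr1", 400, 500, "GAIN", np.zeros(2))],
    }
    res = population_cnvr_sets(rs)
    assert res.venn == {("A", "B"): 1, ("C",): 1}


def test_venn_counts_are_permutation_invariant_and_sum_to_union():
    rng = np.random.default_rng(10)
    pops = {"A": [], "B": [], "C": []}
    for pop in pops:
        for _ in range(30):
            s = int(rng.integers(0, 100_000))
            pops[pop].append(CNVR("chr1", s, s + int(rng.integers(500, 5000)),
                                  "GAIN", np.zeros(1)))
    base = population_cnvr_sets(pops)
    assert sum(base.venn.values()) == base.n_union
    for order in itertools.permutations(pops):
        res = population_cnvr_sets({p: pops[p] for p in order})
        assert res.venn == base.venn


class TestSizeSummary:
    def test_cnvr_bins_example(self):
        frac = summarize_sizes([1500, 2500, 9000], CNVR_SIZE_BINS_KB)
        assert frac["1-2kb"] == pytest.approx(1 / 3)
        assert frac["2-4kb"] == pytest.approx(1 / 3)
        assert frac[">8kb"] == pytest.approx(1 / 3)

    def test_single_bin(self):
        frac = summarize_sizes([800] * 7, CNV_SIZE_BINS_KB)
        assert frac["0-2kb"] == 1.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        lengths = rng.integers(100, 20_000, size=200)
        for bins in (CNV_SIZE_BINS_KB, CNVR_SIZE_BINS_KB):
            assert summarize_sizes(lengths, bins).sum() == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(InputDataError):
            summarize_sizes([])


class TestChromosomeRegression:
    def test_proportional_counts_give_r2_one(self):
        lengths = {"c1": 100, "c2": 200, "c3": 300}
        _, _, r2 = chromosome_count_regression({"c1": 10, "c2": 20, "c3": 30}, lengths)
        assert r2 == pytest.approx(1.0)

    def test_constant_counts_give_r2_zero(self):
        lengths = {"c1": 100, "c2": 200, "c3": 300}
        _, _, r2 = chromosome_count_regression({"c1": 5, "c2": 5, "c3": 5}, lengths)
        assert r2 == 0.0

    def test_hand_computed_example(self):
        """lengths 100/200/300, counts 1/2/4: R^2 = 27/28 by direct OLS."""
        lengths = {"c1": 100, "c2": 200, "c3": 300}
        slope, intercept, r2 = chromosome_count_regression(
            {"c1": 1, "c2": 2, "c3": 4}, lengths
        )
        assert r2 == pytest.approx(27 / 28, abs=1e-9)
        assert slope == pytest.approx(0.015)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InputDataError):
            chromosome_count_regression({"c1": 1, "c2": 2}, {"c1": 100, "c2": 200})
        with pytest.raises(InputDataError):
            chromosome_count_regression(
                {"c1": 1, "c2": 2, "c3": 3}, {"c1": 100, "c2": 100, "c3": 100}
            )
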