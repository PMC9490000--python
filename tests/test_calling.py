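import numpy as np
import pandas as pd
import pytest
from scipy import special

from cnvpop.calling import (
    GAIN,
    LOSS,
    NORMAL,
    CallingParams,
    call_individual_events,
    candidate_windows,
    classify_windows,
    correlation_significant,
    low_coverage_mask,
    merge_adjacent_windows,
    summarize_events,
)
from cnvpop.errors import ParameterError
from cnvpop.simulate import simulate_depth, simulate_genome, simulate_populations, TruthSet
from cnvpop.windows import make_window_grid, normalize_depth

from conftest import build_norm, vectors_with_exact_correlation


@pytest.mark.parametrize(
    "rd, stdev, expected",
    [
        (0.50, 0.10, LOSS),  # passes both statistical and empirical criteria
        (0.70, 0.10, NORMAL),  # statistically low but above the 0.65 cutoff
        (1.40, 0.25, NORMAL),  # above 1.35 but within 2 stdev of baseline
        (0.79, 0.10, NORMAL),  # below 1 - 2*stdev yet above the 0.65 cutoff
    ],
)
def test_classification_is_conjunctive(rd, stdev, expected, norm_factory):
    # build a column whose ddof=0 stdev is exactly `stdev` and contains `rd`:
    # inject the target rd into a +/-stdev alternating background of mean 1
    n = 2000
    col = np.ones(n)
    col[: n // 2] = 1 + stdev
    col[n // 2 :] = 1 - stdev
    norm = norm_factory(col.reshape(-1, 1))
    norm.values[0, 0] = rd  # one window of interest; stdev already recorded
    states = classify_windows(norm)
    assert states.states[0, 0] == expected


def test_no_loss_above_cutoff_no_gain_below_cutoff():
    """Conjunctive thresholds: LOSS => RD < 0.65, GAIN => RD > 1.35, always."""
    rng = np.random.default_rng(3)
    values = rng.gamma(20, 0.05, size=(500, 8))
    norm = build_norm(values)
    states = classify_windows(norm).states
    assert np.all(values[states == LOSS] < 0.65)
    assert np.all(values[states == GAIN] > 1.35)


def test_calling_params_validation():
    with pytest.raises(ParameterError):
        CallingParams(del_cutoff=1.2)
    with pytest.raises(ParameterError):
        CallingParams(merge_alpha=1.5)


class TestCandidateFilter:
    def _setup(self, n_ind, loss_rds):
        """Window 0 carries losses at the given RDs; window 1 is clean."""
        values = np.ones((50, n_ind))
        values += np.linspace(-0.01, 0.01, 50)[:, None]  # tiny spread, stdev ~ 0.006
        for j, rd in enumerate(loss_rds):
            values[0, j] = rd
        norm = build_norm(values)
        states = classify_windows(norm)
        return states, norm

    def test_two_of_24_carriers_pass_frequency(self):
        states, norm = self._setup(24, [0.5, 0.5])
        cand = candidate_windows(states, norm)
        assert (0, "LOSS") in set(zip(cand["window"], cand["direction"]))

    def test_single_non_homozygous_carrier_dropped(self):
        states, norm = self._setup(24, [0.5])
        cand = candidate_windows(states, norm)
        assert 0 not in set(cand["window"])

    def test_three_homozygous_carriers_pass_despite_low_frequency(self):
        states, norm = self._setup(80, [0.1, 0.1, 0.1])  # 3/80 = 0.0375 < 0.05
        cand = candidate_windows(states, norm)
        row = cand[(cand["window"] == 0) & (cand["direction"] == "LOSS")]
        assert len(row) == 1 and int(row["n_homozygous"].iloc[0]) == 3


def test_low_coverage_windows_masked():
    rng = np.random.default_rng(5)
    genome_values = np.full((100, 4), 7.0) + rng.normal(0, 0.2, (100, 4))
    genome_values[17] = 0.05  # dead window
    from cnvpop.windows import GenomeLayout, RawDepthMatrix, make_window_grid

    genome = GenomeLayout.from_pairs([("chr1", 100 * 800)])
    raw = RawDepthMatrix(
        make_window_grid(genome, 800), ("a", "b", "c", "d"), genome_values
    )
    mask = low_coverage_mask(raw, 0.10)
    assert mask[17] and mask.sum() == 1


class TestAdjacentWindowMerge:
    def _two_window_norm(self, r, n=24, seed=0):
        x, y = vectors_with_exact_correlation(r, n, seed)
        values = np.vstack([1.0 + 0.05 * x, 1.0 + 0.05 * y])
        return build_norm(values)

    def _candidates(self):
        return pd.DataFrame(
            {"window": [0, 1], "direction": ["GAIN", "GAIN"],
             "n_carriers": [2, 2], "n_homozygous": [0, 0]}
        )

    @pytest.mark.parametrize(
        "r, merged",
        [
            (1.0 - 1e-12, True),  # near-perfect correlation
            (0.0, False),
            (0.41, True),   # p ~ 0.047 < 0.05 at n=24
            (0.40, False),  # p ~ 0.053 >= 0.05
        ],
    )
    def test_merge_boundary_at_alpha_005(self, r, merged):
        norm = self._two_window_norm(r)
        segs = merge_adjacent_windows(self._candidates(), norm, alpha=0.05)
        if merged:
            assert len(segs) == 1 and segs[0].window_indices == (0, 1)
        else:
            assert len(segs) == 2

    def test_boundary_p_values_match_t_cdf_oracle(self):
        """p = 2*(1 - T_cdf(|t|, df=n-2)) with t = r*sqrt((n-2)/(1-r^2))."""
        n = 24
        for r, expect_significant in ((0.41, True), (0.40, False)):
            t = r * np.sqrt((n - 2) / (1 - r * r))
            p = 2 * special.stdtr(n - 2, -abs(t))
            assert (p < 0.05) == expect_significant
            x, y = vectors_with_exact_correlation(r, n)
            assert correlation_significant(x, y, 0.05) == expect_significant

    def test_constant_vector_never_merges(self):
        values = np.ones((2, 24))
        values[1] += np.linspace(0, 0.1, 24)
        norm = build_norm(values)
        segs = merge_adjacent_windows(self._candidates(), norm, alpha=0.05)
        assert len(segs) == 2

    def test_merge_never_mixes_directions_or_spans_gaps(self):
        rng = np.random.default_rng(8)
        values = np.tile(rng.normal(1, 0.2, 24), (5, 1))  # identical rows, r = 1
        norm = build_norm(values)
        cand = pd.DataFrame(
            {"window": [0, 1, 3, 4], "direction": ["GAIN", "LOSS", "GAIN", "GAIN"],
             "n_carriers": 1, "n_homozygous": 0}
        )
        segs = merge_adjacent_windows(cand, norm, alpha=0.05)
        by_dir = {(s.direction, s.window_indices) for s in segs}
        # window 1 differs in direction; windows 3-4 are separated from 0 by
        # the non-candidate window 2
        assert by_dir == {(GAIN, (0,)), (LOSS, (1,)), (GAIN, (3, 4))}


def _union_find_oracle(cand, norm, alpha, n):
    """Independent re-derivation: union adjacent same-direction candidate
    pairs whose correlation t-test is significant, then read off groups."""
    parent = {}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    keys = [(int(w), d) for w, d in zip(cand["window"], cand["direction"])]
    for k in keys:
        parent[k] = k
    chroms = norm.grid.windows["chrom"].to_numpy()
    for w, d in keys:
        nxt = (w + 1, d)
        if nxt in parent and chroms[w] == chroms[w + 1]:
            x, y = norm.values[w], norm.values[w + 1]
            if np.ptp(x) > 0 and np.ptp(y) > 0:
                r = np.corrcoef(x, y)[0, 1]
                if abs(r) < 1:
                    t = r * np.sqrt((n - 2) / (1 - r * r))
                    p = 2 * special.stdtr(n - 2, -abs(t))
                else:
                    p = 0.0
                if p < alpha:
                    parent[find(nxt)] = find((w, d))
    groups = {}
    for k in keys:
        groups.setdefault(find(k), []).append(k)
    return {tuple(sorted(w for w, _ in g)) + (g[0][1],) for g in groups.values()}


@pytest.mark.parametrize("seed", range(5))
def test_window_merge_matches_union_find_oracle(seed):
    """Transitive left-to-right merging equals union-find over significant
    adjacent pairs on random 50-window x 24-individual instances."""
    rng = np.random.default_rng(seed)
    n_w, n_i = 50, 24
    values = np.abs(rng.normal(1, 0.15, (n_w, n_i)))
    # plant correlated stretches so some pairs merge
    for s in range(0, n_w - 4, 7):
        base = rng.normal(1, 0.3, n_i)
        for k in range(3):
            values[s + k] = np.abs(base + rng.normal(0, rng.uniform(0.01, 0.6), n_i))
    norm = build_norm(values)
    wins = sorted(rng.choice(n_w, size=25, replace=False))
    cand = pd.DataFrame(
        {"window": wins,
         "direction": [rng.choice(["GAIN", "LOSS"], p=[0.8, 0.2]) for _ in wins],
         "n_carriers": 1, "n_homozygous": 0}
    )
    segs = merge_adjacent_windows(cand, norm, alpha=0.05)
    got = {s.window_indices + (s.direction_name,) for s in segs}
    assert got == _union_find_oracle(cand, norm, 0.05, n_i)


class TestIndividualEvents:
    def test_single_carrier_three_window_gain(self):
        values = np.ones((5, 6))
        values += np.linspace(-0.02, 0.02, 5)[:, None]
        values[1:4, 0] = 2.0  # one individual duplicated over 3 windows
        norm = build_norm(values)
        states = classify_windows(norm)
        cand = candidate_windows(states, norm)
        segs = merge_adjacent_windows(cand, norm, 0.05)
        events = call_individual_events(segs, norm)
        assert len(events) == 1
        ev = events[0]
        assert (ev.individual, ev.direction, ev.length) == ("s0", GAIN, 2400)
        summary = summarize_events(events)
        assert summary["mean_length_kb"].iloc[0] == pytest.approx(2.4)

    def test_no_candidates_no_events(self):
        norm = build_norm(np.ones((5, 6)))
        states = classify_windows(norm)
        cand = candidate_windows(states, norm)
        assert len(cand) == 0
        assert call_individual_events([], norm) == []


def test_null_panel_candidate_rate_below_one_percent():
    """Poisson 7x depth, 24 individuals, no planted CNVs: the frequency
    filter suppresses noise to <= 1% candidate windows."""
    genome, _, _ = simulate_genome(n_chromosomes=1, chrom_length=2_400_000,
                                   n_genes=1, n_qtls=1, seed=21)
    grid = make_window_grid(genome, 800)
    truth = simulate_populations(genome, grid, n_shared=0, n_unique=0,
                                 n_divergent=0, seed=22)
    raw = simulate_depth(truth, grid, mean_depth=7.0, noise="poisson", seed=23)
    norm = normalize_depth(raw)
    states = classify_windows(norm)
    cand = candidate_windows(states, norm)
    assert len(set(cand["window"])) / grid.n_windows <= 0.01
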