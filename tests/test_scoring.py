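import math

import numpy as np
import pytest

from coevcontact import (
    ScoreCalibration,
    block_apc,
    coupling_strength,
    gremlin_score,
    normalize_ncs,
    rank_pairs,
    score_midpoint,
    score_pairs,
    summed_pair_coupling,
)
from coevcontact.potts import PottsModel, Q


def symmetric_table(rng, L):
    s = np.abs(rng.normal(1.0, 0.3, (L, L)))
    s = (s + s.T) / 2
    np.fill_diagonal(s, 0.0)
    return s


class TestCouplingStrength:
    def test_zero_matrix(self):
        assert coupling_strength(np.zeros((Q, Q))) == 0.0

    def test_constant_matrix(self):
        assert coupling_strength(np.full((Q, Q), 0.7)) == pytest.approx(0.7)

    def test_matches_direct_formula(self, rng):
        w = rng.normal(0, 1, (Q, Q))
        got = coupling_strength(w)
        assert got == pytest.approx(np.sqrt(np.mean(w[:20, :20] ** 2)))
        assert coupling_strength(w, include_gap=True) == pytest.approx(
            np.sqrt(np.mean(w**2))
        )


class TestBlockAPC:
    def test_rank_one_inter_block_cancels(self, rng):
        p, L = 6, 13
        s = symmetric_table(rng, L)
        a = np.abs(rng.normal(1, 0.4, p))
        b = np.abs(rng.normal(1, 0.4, L - p))
        s[:p, p:] = np.outer(a, b)
        s[p:, :p] = s[:p, p:].T
        corr = block_apc(s, p)
        assert np.abs(corr[:p, p:]).max() < 1e-10

    def test_spike_on_rank_one_background(self, rng):
        p, L = 5, 11
        s = symmetric_table(rng, L)
        a = np.abs(rng.normal(1, 0.2, p))
        b = np.abs(rng.normal(1, 0.2, L - p))
        inter = np.outer(a, b)
        inter[2, 3] += 1.7
        s[:p, p:] = inter
        s[p:, :p] = inter.T
        corr = block_apc(s, p)
        # direct evaluation of the formula at the spiked entry
        mb = inter[2].mean()
        ma = inter[:, 3].mean()
        grand = inter.mean()
        want = inter[2, 3] - mb * ma / grand
        assert corr[2, p + 3] == pytest.approx(want, rel=1e-12)

    def test_two_by_two_toy_matches_hand_computation(self):
        # p = 2, q = 2; hand-computed averages for the inter block
        s = np.zeros((4, 4))
        inter = np.array([[1.0, 2.0], [3.0, 4.0]])
        s[:2, :2] = [[0, 0.5], [0.5, 0]]
        s[2:, 2:] = [[0, 0.8], [0.8, 0]]
        s[:2, 2:] = inter
        s[2:, :2] = inter.T
        corr = block_apc(s, 2)
        grand = 2.5
        # corrected(0, 2) = 1 - (1.5 * 2.0) / 2.5 = -0.2
        assert corr[0, 2] == pytest.approx(1.0 - 1.5 * 2.0 / grand)
        assert corr[1, 3] == pytest.approx(4.0 - 3.5 * 3.0 / grand)
        # intra blocks: row mean = 0.5 (only one partner), grand = 0.5
        assert corr[0, 1] == pytest.approx(0.5 - 0.5 * 0.5 / 0.5)

    def test_symmetry_preserved(self, rng):
        s = symmetric_table(rng, 9)
        corr = block_apc(s, 4)
        assert np.allclose(corr, corr.T)

    def test_degenerate_block_raises(self):
        s = np.zeros((6, 6))
        with pytest.raises(ValueError, match="degenerate"):
            block_apc(s, 3)


class TestNormalizeNCS:
    def test_scaling_by_top_mean(self, rng):
        L = 8
        s = symmetric_table(rng, L)
        ncs = normalize_ncs(s)
        top_k = round(3 * L / 2)
        iu, ju = np.triu_indices(L, k=1)
        top_mean = np.sort(s[iu, ju])[-top_k:].mean()
        assert np.allclose(ncs, s / top_mean)

    def test_top_k_mean_is_one(self, rng):
        L = 10
        ncs = normalize_ncs(symmetric_table(rng, L))
        iu, ju = np.triu_indices(L, k=1)
        top_k = round(3 * L / 2)
        assert np.sort(ncs[iu, ju])[-top_k:].mean() == pytest.approx(1.0)

    def test_six_position_brute_force(self):
        s = np.zeros((6, 6))
        vals = np.arange(1, 16, dtype=float)
        iu, ju = np.triu_indices(6, k=1)
        s[iu, ju] = vals
        s = s + s.T
        ncs = normalize_ncs(s)  # top 9 of 15 values
        want = s / np.mean(np.sort(vals)[-9:])
        assert np.allclose(ncs, want)

    def test_nonpositive_normalizer_raises(self):
        s = -symmetric_table(np.random.default_rng(0), 6)
        with pytest.raises(ValueError, match="normalizer"):
            normalize_ncs(s)


class TestGremlinScore:
    def test_midpoint_is_half(self):
        cal = ScoreCalibration()
        mu = score_midpoint(100, 50, cal)
        assert gremlin_score(mu**2, 100, 50, cal=cal) == pytest.approx(0.5)

    def test_monotone_in_ncs_and_depth(self):
        grid = np.linspace(0.1, 4.0, 15)
        scores = [gremlin_score(x, 200, 100) for x in grid]
        assert np.all(np.diff(scores) > 0)
        depths = [gremlin_score(1.5, n, 100) for n in (50, 100, 200, 400)]
        assert np.all(np.diff(depths) > 0)

    def test_printed_constants_example(self):
        # N/L = 2, top pair ncs = 2 -> x = sqrt(2), mu = 0.47/3 + 0.96
        mu = 0.47 / 3 + 0.96
        want = 1.0 / (1.0 + math.exp(-9.77 * (math.sqrt(2.0) - mu)))
        assert gremlin_score(2.0, 200, 100) == pytest.approx(want, rel=1e-12)

    def test_negative_ncs_floored(self):
        out = gremlin_score(-0.5, 100, 50)
        assert 0 < out < 1
        assert out == gremlin_score(0.0, 100, 50)

    def test_always_in_open_interval(self, rng):
        for _ in range(50):
            x = rng.uniform(-1, 10)
            n = rng.uniform(1, 1e4)
            val = gremlin_score(x, n, 50)
            assert 0.0 < val < 1.0


def toy_scores(rng, p=4, q=4, N=100):
    L = p + q
    w = rng.normal(0, 0.2, (L, L, Q, Q))
    w = (w + w.transpose(1, 0, 3, 2)) / 2
    w[np.arange(L), np.arange(L)] = 0
    model = PottsModel(np.zeros((L, Q)), w)
    return score_pairs(model, boundary=p, N=N)


class TestScoreTable:
    def test_regions_partition_pairs(self, rng):
        sc = toy_scores(rng)
        t = sc.table
        assert len(t) == 8 * 7 // 2
        assert set(t.region) <= {"AA", "BB", "AB"}
        assert (t[t.region == "AB"].i < 4).all()
        assert (t[t.region == "AB"].j >= 4).all()

    def test_summed_pair_coupling(self, rng):
        sc = toy_scores(rng)
        t = sc.table
        vals = t[t.region == "AB"].ncs.to_numpy()
        thr = np.median(vals)
        want = vals[vals >= thr].sum()
        assert summed_pair_coupling(sc, threshold=thr) == pytest.approx(want)
        assert summed_pair_coupling(sc, threshold=np.inf) == 0.0

    def test_rank_pairs_filters_and_orders(self, rng):
        sc = toy_scores(rng)
        top = rank_pairs(sc, which="inter", top_n=1)
        inter = sc.inter()
        assert top.gremlin_score.iloc[0] == inter.gremlin_score.max()
        ranked = rank_pairs(sc, which="inter")
        assert (ranked.region == "AB").all()
        assert (ranked.gremlin_score.diff().dropna() <= 1e-15).all()

    def test_ranking_deterministic_under_permutation(self, rng):
        sc = toy_scores(rng)
        shuffled = sc.table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        sc2 = type(sc)(table=shuffled, boundary=sc.boundary, N=sc.N, L=sc.L)
        r1 = rank_pairs(sc, "inter")[["i", "j"]].to_numpy()
        r2 = rank_pairs(sc2, "inter")[["i", "j"]].to_numpy()
        assert np.array_equal(r1, r2)

    def test_top_pair_anchors_calibration_chain(self, rng):
        sc = toy_scores(rng)
        inter = sc.inter()
        top_row = inter.loc[inter.ncs.idxmax()]
        top = gremlin_score(top_row.ncs, sc.N, sc.L)
        assert top_row.gremlin_score == pytest.approx(top)
        other = inter.drop(index=top_row.name).iloc[0]
        want = gremlin_score(other.ncs, sc.N, sc.L, top_score=top)
        assert other.gremlin_score == pytest.approx(want)


class TestScoreBounds:
    """The calibrated score is a proper probability for any input."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.floats(min_value=-5, max_value=50, allow_nan=False),
        st.floats(min_value=1, max_value=1e5),
        st.floats(min_value=2, max_value=500),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_score_in_unit_interval(self, ncs, N, L):
        # mathematically the sigmoid lies in the open interval; in double
        # precision it saturates to exactly 1.0 once sigma*(x - mu) > ~36
        val = gremlin_score(ncs, N, L)
        assert 0.0 < val <= 1.0
        if ncs <= 10:
            assert val < 1.0
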