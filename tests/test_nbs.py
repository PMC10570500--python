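import numpy as np
import pytest
from scipy import stats as sps

from richnet import edgewise_paired_t, nbs_paired, suprathreshold_components
from _oracles import flood_fill_components


def sym(mats):
    return [m + m.T for m in mats]


def random_pairs(rng, s=6, n=8, t=60):
    pre = [np.corrcoef(rng.standard_normal((t, n)), rowvar=False) for _ in range(s)]
    post = [np.corrcoef(rng.standard_normal((t, n)), rowvar=False) for _ in range(s)]
    return pre, post


class TestEdgewisePairedT:
    def test_identical_sessions_give_zero(self, rng):
        pre, _ = random_pairs(rng)
        t = edgewise_paired_t(pre, [p.copy() for p in pre])
        assert np.all(t == 0)

    def test_constant_nonzero_difference_flagged(self):
        shift = np.full((3, 3), 0.1)
        np.fill_diagonal(shift, 0)
        pre = [np.zeros((3, 3))] * 4
        post = [shift.copy()] * 4
        with pytest.warns(UserWarning, match="constant nonzero"):
            t = edgewise_paired_t(pre, post)
        assert t[0, 1] == 0.0

    def test_matches_one_sample_t_oracle(self):
        d = np.array([0.1, 0.2, 0.3, 0.1, 0.2])
        n = 2
        pre = [np.zeros((n, n)) for _ in d]
        post = []
        for v in d:
            m = np.zeros((n, n))
            m[0, 1] = m[1, 0] = v
            post.append(m)
        t = edgewise_paired_t(pre, post)
        expected = sps.ttest_1samp(d, 0.0).statistic
        assert t[0, 1] == pytest.approx(expected, abs=1e-12)
        # and against the textbook formula
        assert t[0, 1] == pytest.approx(d.mean() / (d.std(ddof=1) / np.sqrt(5)), abs=1e-12)

    def test_mismatched_lists_rejected(self, rng):
        pre, post = random_pairs(rng, s=4)
        with pytest.raises(ValueError, match="match"):
            edgewise_paired_t(pre[:3], post)


class TestSuprathresholdComponents:
    def make_tmap(self, n, hot_edges, value=5.0):
        t = np.zeros((n, n))
        for i, j in hot_edges:
            t[i, j] = t[j, i] = value
        return t

    def test_hand_drawn_graph(self):
        t = self.make_tmap(6, [(1, 2), (2, 3), (4, 5)])
        comps = suprathreshold_components(t, 3.0)
        assert [c.size for c in comps] == [2, 1]
        np.testing.assert_array_equal(comps[0].edges, [[1, 2], [2, 3]])

    def test_no_suprathreshold_edges(self):
        comps = suprathreshold_components(np.zeros((5, 5)), 3.0)
        assert comps == []

    def test_direction_selects_sign(self):
        t = self.make_tmap(4, [(0, 1)], value=-5.0) + self.make_tmap(4, [(2, 3)], value=4.0)
        assert [c.size for c in suprathreshold_components(t, 3, "positive")] == [1]
        neg = suprathreshold_components(t, 3, "negative")
        assert [tuple(neg[0].edges[0])] == [(0, 1)]
        assert len(suprathreshold_components(t, 3, "two_sided")) == 2

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 11))
            mask = np.triu(rng.random((n, n)) < 0.25, 1)
            edges = np.argwhere(mask)
            t = self.make_tmap(n, edges)
            comps = suprathreshold_components(t, 3.0)
            got = sorted(
                sorted(map(tuple, c.edges.tolist())) for c in comps
            )
            edge_list = sorted(map(tuple, edges.tolist()))
            oracle = flood_fill_components(edge_list, n)
            expected = sorted(sorted(edge_list[k] for k in comp) for comp in oracle)
            assert got == expected

    def test_raising_threshold_never_grows_components(self, rng):
        pre, post = random_pairs(rng, s=8)
        tmap = edgewise_paired_t(pre, post)
        sizes = []
        for thr in (0.5, 1.0, 2.0, 3.0):
            comps = suprathreshold_components(tmap, thr, "two_sided")
            sizes.append(sum(c.size for c in comps))
        assert sizes == sorted(sizes, reverse=True)


class TestNBSPaired:
    def test_determinism_under_seed(self, rng):
        pre, post = random_pairs(rng, s=6)
        a = nbs_paired(pre, post, n_permutations=200, seed=9)
        b = nbs_paired(pre, post, n_permutations=200, seed=9)
        np.testing.assert_array_equal(a.null_max_sizes, b.null_max_sizes)
        assert [c.p_value for c in a.components] == [c.p_value for c in b.components]

    def test_planted_large_effect_hits_p_floor(self, rng):
        s, n = 20, 12
        hot = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 7), (7, 8), (8, 9), (9, 10)]
        pre = []
        post = []
        for _ in range(s):
            base = np.zeros((n, n))
            noise = rng.normal(0, 0.01, (n, n))
            noise = np.triu(noise, 1)
            noise = noise + noise.T
            pre.append(base + noise)
            eff = np.zeros((n, n))
            for i, j in hot:
                eff[i, j] = eff[j, i] = 0.5
            noise2 = np.triu(rng.normal(0, 0.01, (n, n)), 1)
            post.append(base + eff + noise2 + noise2.T)
        res = nbs_paired(pre, post, threshold=3, n_permutations=500, seed=3)
        big = res.components[0]
        assert big.size >= len(hot)
        planted = {tuple(e) for e in hot}
        found = {tuple(e) for e in big.edges.tolist()}
        assert planted <= found
        # p sits near the permutation floor: only near-unanimous sign flips
        # can reproduce a component this large
        assert 1 / 501 <= big.p_value < 0.05
        assert big.p_value == pytest.approx(
            (1 + (res.null_max_sizes >= big.size).sum()) / 501
        )

    def test_p_values_positive_and_monotone_in_size(self, rng):
        pre, post = random_pairs(rng, s=8, n=12)
        res = nbs_paired(pre, post, threshold=1.5, n_permutations=300, seed=1)
        ps = [c.p_value for c in res.components]
        sizes = [c.size for c in res.components]
        assert all(p >= 1 / 301 for p in ps)
        for (s1, p1), (s2, p2) in zip(zip(sizes, ps), zip(sizes[1:], ps[1:])):
            if s1 >= s2:
                assert p1 <= p2

    def test_few_permutations_warn(self, rng):
        pre, post = random_pairs(rng, s=4)
        with pytest.warns(UserWarning, match="unstable"):
            nbs_paired(pre, post, n_permutations=50, seed=0)
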