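"""Statistics layer: Spearman/t conversion, permutation null, BH-FDR,
exact Wilcoxon, rank-biserial screen, UPGMA — each against an independent
oracle (closed form, exhaustive enumeration, or a hand-rolled step-up)."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import rmsfnet as rn
from rmsfnet.corrstats import WilcoxonResult, cut_containing, upgma_cluster

from conftest import toy_dataset


class TestSpearmanMatrix:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),  # 1 - 6*2/(4*15)
        ],
    )
    def test_pairwise_values(self, x, y, expected):
        # duplicating every trajectory is a linear map on ranks, so the
        # Spearman value is unchanged while the dataset gets valid V/P pairs
        m = np.repeat(np.array([x, y], dtype=float), 2, axis=1)
        ds = toy_dataset(m)
        rho, _ = rn.spearman_matrix(ds)
        assert rho[0, 1] == pytest.approx(expected)

    def test_matches_scipy_on_random_data(self, rng):
        m = rng.random((6, 10))
        ds = toy_dataset(m)
        rho, _ = rn.spearman_matrix(ds)
        expected = stats.spearmanr(m, axis=1).statistic
        assert np.allclose(rho, expected)

    def test_constant_residue_flagged_and_nan(self, rng):
        m = rng.random((4, 8)) + 0.1
        m[2, :] = 0.5
        ds = toy_dataset(m)
        rho, degenerate = rn.spearman_matrix(ds)
        assert degenerate.tolist() == [False, False, True, False]
        assert np.isnan(rho[2, 0]) and np.isnan(rho[0, 2])
        assert rho[2, 2] == 1.0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        st.floats(0.1, 5.0, allow_nan=False),
        st.floats(0.0, 2.0, allow_nan=False),
    )
    def test_invariant_to_monotone_transform(self, scale, shift):
        rng = np.random.default_rng(99)
        m = rng.random((3, 8)) + 0.05
        transformed = m.copy()
        transformed[1] = np.exp(scale * m[1] + shift)  # strictly monotone
        r1, _ = rn.spearman_matrix(toy_dataset(m))
        r2, _ = rn.spearman_matrix(toy_dataset(transformed))
        assert np.allclose(r1, r2)


class TestTFromRho:
    def test_zero_maps_to_zero(self):
        assert rn.t_from_rho(0.0, 26) == 0.0

    def test_closed_form_value(self):
        # independent evaluation of 0.5*sqrt(24/0.75)
        assert rn.t_from_rho(0.5, 26) == pytest.approx(0.5 * math.sqrt(24 / 0.75))
        assert rn.t_from_rho(0.5, 26) == pytest.approx(2.828427, abs=1e-6)

    def test_unit_rho_gives_signed_sentinel(self):
        assert rn.t_from_rho(1.0, 26) == np.inf
        assert rn.t_from_rho(-1.0, 26) == -np.inf

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            rn.t_from_rho(0.5, 2)


def enumerate_null_rho(n):
    """Oracle: rho over all n! rank permutations against the identity."""
    identity = list(range(1, n + 1))
    return [
        stats.spearmanr(identity, perm).statistic
        for perm in itertools.permutations(identity)
    ]


class TestPermutationNull:
    def test_exhaustive_n3_matches_enumeration(self):
        null = rn.exhaustive_null(3)
        rho_expected = sorted([1.0, 0.5, 0.5, -0.5, -0.5, -1.0])
        t_expected = sorted(rn.t_from_rho(np.array(rho_expected), 3))
        assert np.allclose(null.t_values, t_expected)

    def test_null_mean_within_4se(self, null26):
        finite = null26.t_values[np.isfinite(null26.t_values)]
        se = finite.std() / np.sqrt(len(finite))
        assert abs(finite.mean()) < 4 * se

    def test_same_seed_reproduces(self):
        a = rn.build_null(8, resamples=2000, seed=5)
        b = rn.build_null(8, resamples=2000, seed=5)
        assert np.array_equal(a.t_values, b.t_values)

    def test_chunked_generation_streams_full_count(self):
        a = rn.build_null(8, resamples=5000, seed=5, chunk=1000)
        b = rn.build_null(8, resamples=5000, seed=5, chunk=1000)
        assert a.resamples == 5000
        assert np.array_equal(a.t_values, b.t_values)


class TestPValue:
    def test_t_zero_gives_p_one(self, null26):
        assert rn.pvalue_two_tailed(0.0, null26, 26) == pytest.approx(1.0, abs=1e-4)

    def test_exhaustive_n3_perfect_rho(self):
        null = rn.exhaustive_null(3)
        t_obs = rn.t_from_rho(1.0, 3)
        assert rn.pvalue_two_tailed(t_obs, null, 3) == pytest.approx(2 / 6)

    def test_never_zero(self, null26):
        p = rn.pvalue_two_tailed(np.inf, null26, 26)
        assert p >= 1 / (null26.resamples + 1) > 0

    def test_n_mismatch_rejected(self, null26):
        with pytest.raises(ValueError, match="n="):
            rn.pvalue_two_tailed(1.0, null26, 13)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_monte_carlo_matches_enumeration_within_3se(self, n):
        """Resampled permutation p agrees with the exact n! enumeration."""
        exact_rho = np.array(enumerate_null_rho(n))
        null = rn.build_null(n, resamples=100_000, seed=n)
        for rho_obs in (0.4, 0.7, 0.9):
            t_obs = rn.t_from_rho(rho_obs, n)
            p_mc = rn.pvalue_two_tailed(t_obs, null, n)
            p_exact = np.mean(np.abs(exact_rho) >= rho_obs - 1e-12)
            se = math.sqrt(max(p_exact * (1 - p_exact), 1e-12) / null.resamples)
            assert abs(p_mc - p_exact) <= 3 * se + 2 / null.resamples


def bh_stepup_oracle(p):
    """Classical BH decision rule, implemented directly from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    thresh = 0.05 * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    k = np.max(np.nonzero(below)[0]) + 1 if below.any() else 0
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    adj = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out, reject


class TestBhAdjust:
    def test_worked_example(self):
        adj, _ = rn.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        adj, flags = rn.bh_adjust(np.array([0.2]))
        assert adj[0] == pytest.approx(0.2) and not flags[0]

    def test_all_ones(self):
        adj, flags = rn.bh_adjust(np.ones(10))
        assert np.all(adj == 1.0) and not flags.any()

    def test_nan_excluded(self):
        adj, flags = rn.bh_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(adj[1]) and not flags[1]

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=60))
    def test_matches_stepup_oracle(self, p_list):
        p = np.array(p_list)
        adj, flags = rn.bh_adjust(p, q=0.05)
        adj_o, reject_o = bh_stepup_oracle(p)
        assert np.allclose(adj, adj_o)
        assert np.array_equal(flags, reject_o)
        assert np.all(np.diff(np.sort(adj)) >= -1e-12)  # monotone
        assert np.all(adj >= p - 1e-12)


def wilcoxon_bruteforce(x, y, alternative):
    """Oracle: enumerate every sign assignment of the 2^n informative pairs."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = np.array([
        sum(r for r, s in zip(ranks, signs) if s > 0)
        for signs in itertools.product([-1, 1], repeat=n)
    ])
    p_greater = np.mean(ws >= w_obs - 1e-9)
    p_less = np.mean(ws <= w_obs + 1e-9)
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2 * min(p_greater, p_less))


class TestWilcoxonExact:
    def test_all_positive_n3_greater(self):
        res = rn.wilcoxon_exact_paired([2, 3, 4], [1, 1, 1], alternative="greater")
        assert res.p_value == pytest.approx(0.125)  # 1/2^3

    def test_swap_flips_alternative(self, rng):
        x = rng.random(10)
        y = rng.random(10)
        p1 = rn.wilcoxon_exact_paired(x, y, alternative="greater").p_value
        p2 = rn.wilcoxon_exact_paired(y, x, alternative="less").p_value
        assert p1 == pytest.approx(p2)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            rn.wilcoxon_exact_paired([1.0, 2.0], [1.0, 2.0])

    def test_matches_scipy_exact_on_tie_free_data(self, rng):
        for _ in range(5):
            x = rng.random(12)
            y = rng.random(12)
            ours = rn.wilcoxon_exact_paired(x, y, alternative="two_sided")
            ref = stats.wilcoxon(x, y, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(ref.pvalue)

    @pytest.mark.parametrize("n", [4, 7, 10, 13])
    @pytest.mark.parametrize("alternative", ["two_sided", "greater", "less"])
    def test_matches_bruteforce_enumeration(self, n, alternative):
        rng = np.random.default_rng(n * 7 + len(alternative))
        x = np.round(rng.random(n), 2)  # rounding induces occasional ties
        y = np.round(rng.random(n), 2)
        if np.all(x == y):
            x[0] += 0.5
        ours = rn.wilcoxon_exact_paired(x, y, alternative=alternative)
        assert ours.p_value == pytest.approx(wilcoxon_bruteforce(x, y, alternative))

    def test_zero_handling_logged_count(self):
        res = rn.wilcoxon_exact_paired([1, 2, 2, 5], [1, 1, 1, 1], alternative="greater")
        assert res.n_zero == 1 and res.n_used == 3
        assert isinstance(res, WilcoxonResult)


class TestRankBiserial:
    def test_complete_separation(self):
        assert rn.rank_biserial([5, 6, 7], [1, 2]) == 1.0

    def test_identical_multisets_zero(self):
        assert rn.rank_biserial([1, 2, 3], [3, 1, 2]) == 0.0

    def test_worked_example(self):
        assert rn.rank_biserial([1, 3], [2, 4]) == -0.5

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=8),
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=8),
    )
    def test_bounded_and_antisymmetric(self, a, b):
        r = rn.rank_biserial(a, b)
        assert -1.0 <= r <= 1.0
        assert r == pytest.approx(-rn.rank_biserial(b, a))


class TestImmunogenicityScreen:
    def test_planted_effect_ranks_first(self):
        truth = rn.TruthSpec(
            n_heavy=20, n_peptide=9,
            condition_effects={rn.ResidueKey("peptide", 6): 0.8},
            sigma=0.15, seed=21,
        )
        study = rn.simulate_rmsf(truth)
        screen = rn.immunogenicity_screen(study.dataset, resamples=2000, seed=1, top_k=3)
        best = study.dataset.residues[int(np.argmax(np.abs(screen.r_rb)))]
        assert best == rn.ResidueKey("peptide", 6)
        assert screen.p_values[best] == min(screen.p_values.values())
        assert screen.r_rb[study.dataset.residues.index(best)] > 0.5

    def test_null_p_not_extreme(self):
        study = rn.simulate_rmsf(rn.null_truth(seed=5, n_pairs=8))
        # shrink to a few residues for speed
        screen = rn.immunogenicity_screen(study.dataset, resamples=1000, seed=2, top_k=2)
        # under the null even the top |r_rb| of 189 residues should not reach
        # the permutation floor
        assert min(screen.p_values.values()) > 1 / 1001

    def test_same_seed_reproducible(self, default_study):
        a = rn.immunogenicity_screen(default_study.dataset, resamples=500, seed=9, top_k=2)
        b = rn.immunogenicity_screen(default_study.dataset, resamples=500, seed=9, top_k=2)
        assert a.p_values == b.p_values


class TestUpgma:
    def test_perfect_correlation_merges_at_zero(self):
        rho = np.array([[1.0, 1.0, 0.2], [1.0, 1.0, 0.2], [0.2, 0.2, 1.0]])
        residues = [rn.ResidueKey("heavy", i) for i in (1, 2, 3)]
        tree = upgma_cluster(rho, residues)
        assert tree.linkage[0, 2] == pytest.approx(0.0)

    def test_average_linkage_height(self):
        # d(AB)=1, d(AC)=d(BC)=4 -> AB at 1, then C at (4+4)/2 = 4
        d = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], float)
        rho = 1 - d
        residues = [rn.ResidueKey("heavy", i) for i in (1, 2, 3)]
        tree = upgma_cluster(rho, residues)
        assert tree.linkage[0, 2] == pytest.approx(1.0)
        assert tree.linkage[1, 2] == pytest.approx(4.0)

    def test_cut_containing_focal(self):
        d = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], float)
        residues = [rn.ResidueKey("heavy", i) for i in (1, 2, 3)]
        tree = upgma_cluster(1 - d, residues)
        partition, height = cut_containing(tree, residues[0])
        assert height == pytest.approx(1.0)
        assert {residues[0], residues[1]} in partition

    def test_isolated_focal_threshold_is_root(self):
        d = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], float)
        residues = [rn.ResidueKey("heavy", i) for i in (1, 2, 3)]
        tree = upgma_cluster(1 - d, residues)
        partition, height = cut_containing(tree, residues[2])
        assert height == pytest.approx(4.0)
        assert any(len(c) == 3 for c in partition)

    def test_focal_absent_raises(self):
        d = np.array([[0, 1], [1, 0]], float)
        residues = [rn.ResidueKey("heavy", i) for i in (1, 2)]
        tree = upgma_cluster(1 - d, residues)
        with pytest.raises(ValueError):
            cut_containing(tree, rn.ResidueKey("peptide", 1))

    def test_heights_nondecreasing_on_real_corr(self, default_corr):
        keep = ~default_corr.degenerate
        kept = [r for r, k in zip(default_corr.residues, keep) if k]
        tree = upgma_cluster(default_corr.rho[np.ix_(keep, keep)], kept)
        assert np.all(np.diff(tree.linkage[:, 2]) >= -1e-12)


class TestCorrelateEndToEnd:
    def test_result_invariants(self, default_corr):
        c = default_corr
        assert np.allclose(c.rho, c.rho.T, equal_nan=True)
        assert np.allclose(np.diag(c.rho), 1.0)
        iu = np.triu_indices(len(c.residues), 1)
        valid = ~np.isnan(c.p_raw[iu])
        assert np.all(c.p_adj[iu][valid] >= c.p_raw[iu][valid] - 1e-12)
        assert not c.mask.diagonal().any()
        assert np.array_equal(c.mask, c.mask.T)
        # mask implies both significance conditions
        assert np.all(c.p_adj[c.mask] < c.alpha)
        assert np.all(np.abs(c.rho[c.mask]) >= c.rho_min)
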