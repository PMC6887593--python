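"""Statistical core against closed-form oracles and independent libraries."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from mirsubtypes.rankstats import (
    bh_adjust,
    bonferroni_adjust,
    dunn_posthoc,
    kruskal_wallis,
    mann_whitney,
    spearman,
    spearman_matrix,
)

THREE_GROUPS = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]


class TestKruskalWallis:
    def test_hand_oracle(self):
        # ranks 1..9, group mean ranks 2, 5, 8: H = 12/(9*10) * 3*(9+9) = 7.2
        res = kruskal_wallis(THREE_GROUPS)
        assert res.H == pytest.approx(7.2, abs=1e-12)
        assert res.df == 2
        assert res.p == pytest.approx(math.exp(-3.6), abs=1e-12)

    def test_identical_groups_give_zero(self):
        res = kruskal_wallis([[1, 2], [1, 2]])
        assert res.H == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_degenerate_all_equal(self):
        res = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert res.degenerate and res.H == 0.0 and res.p == 1.0

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            groups = [
                np.round(rng.normal(size=rng.integers(3, 12)), 1) for _ in range(rng.integers(2, 5))
            ]
            ours = kruskal_wallis(groups)
            ref = sps.kruskal(*groups)
            assert ours.H == pytest.approx(ref.statistic, abs=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1], []])


class TestDunn:
    def test_hand_oracle(self):
        # pair (1,3): z = (2-8)/sqrt(7.5*(2/3)) = -6/sqrt(5)
        res = dunn_posthoc(THREE_GROUPS, labels=["g1", "g2", "g3"])
        r13 = next(r for r in res if {r.group_a, r.group_b} == {"g1", "g3"})
        assert r13.z == pytest.approx(-6 / math.sqrt(5), abs=1e-12)
        assert r13.p == pytest.approx(2 * sps.norm.sf(6 / math.sqrt(5)), abs=1e-12)
        assert r13.p == pytest.approx(0.0072903581, abs=1e-9)
        assert r13.direction == -1

    def test_antisymmetry(self):
        fwd = dunn_posthoc([[1, 5, 3], [9, 7, 8]], labels=["a", "b"])[0]
        rev = dunn_posthoc([[9, 7, 8], [1, 5, 3]], labels=["b", "a"])[0]
        assert fwd.z == pytest.approx(-rev.z, abs=1e-12)
        assert fwd.p == pytest.approx(rev.p, abs=1e-12)

    def test_tie_variance_bruteforce(self):
        """Adding a tie pair shrinks the variance term by sum(t^3-t)/(12(N-1))."""
        groups = [[1.0, 2.0, 7.0], [3.0, 4.0, 5.0], [6.0, 8.0, 9.0]]
        tied = [[1.0, 2.0, 7.0], [3.0, 3.0, 5.0], [6.0, 8.0, 9.0]]  # one tie pair
        pooled = np.concatenate(tied)
        # brute-force tie sum over value groups
        tie_sum = sum(
            c**3 - c for c in (list(pooled).count(v) for v in set(pooled.tolist()))
        )
        assert tie_sum == 2**3 - 2
        N = pooled.size
        var_plain = N * (N + 1) / 12.0
        var_tied = var_plain - tie_sum / (12.0 * (N - 1))

        def z_for(gs, var):
            r = sps.rankdata(np.concatenate(gs))
            ra, rb = r[:3].mean(), r[3:6].mean()
            return (ra - rb) / math.sqrt(var * (2.0 / 3.0))

        r = dunn_posthoc(tied, labels=["a", "b", "c"])
        r_ab = next(x for x in r if {x.group_a, x.group_b} == {"a", "b"})
        assert r_ab.z == pytest.approx(z_for(tied, var_tied), abs=1e-12)

    def test_direction_matches_separation(self):
        res = dunn_posthoc([[10, 11, 12], [1, 2, 3]], labels=["hi", "lo"])[0]
        assert res.direction == 1 and res.z > 0

    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=3,
            max_size=15,
            unique=True,
        ),
        st.integers(min_value=1, max_value=14),
    )
    def test_kw_equals_z_squared_for_two_groups(self, values, split):
        """On tie-free data with k=2, the omnibus H equals Dunn's z^2."""
        split = min(split, len(values) - 1)
        a, b = values[:split], values[split:]
        H = kruskal_wallis([a, b]).H
        z = dunn_posthoc([a, b])[0].z
        assert H == pytest.approx(z * z, abs=1e-9)


class TestMannWhitney:
    def test_complete_separation_exact(self):
        # U = 0; two-sided p = 2 / C(6,3) = 0.1
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.U == 0.0
        assert res.method == "exact"
        assert res.p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples(self):
        res = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.p > 0.9

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            a = rng.normal(size=rng.integers(2, 9))
            b = rng.normal(size=rng.integers(2, 9))
            ours = mann_whitney(a, b)
            ref = sps.mannwhitneyu(a, b, method="exact")
            assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_and_approx_agree_near_boundary(self):
        """Both branches computed on the same tie-free n=20 vs 20 data."""
        rng = np.random.default_rng(8)
        worst = 0.0
        for _ in range(20):
            a = rng.normal(size=20)
            b = rng.normal(size=20) + rng.normal(0, 0.3)
            pe = mann_whitney(a, b, method="exact").p
            pa = mann_whitney(a, b, method="approx").p
            worst = max(worst, abs(pe - pa))
        assert worst < 0.01

    def test_tie_corrected_approx_matches_scipy(self):
        rng = np.random.default_rng(5)
        a = np.round(rng.normal(size=30), 1)
        b = np.round(rng.normal(size=25), 1)
        ours = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, method="asymptotic")
        assert ours.method == "approx"
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-10)


class TestSpearman:
    def test_monotone_extremes(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).rho == 1.0
        assert spearman([1, 2, 3, 4], [40, 30, 20, 10]).rho == -1.0
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).p == 0.0

    def test_hand_ranks(self):
        # ranks equal values; Pearson on ranks: cov 8 / sqrt(10 * 10) = 0.8
        res = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.rho == pytest.approx(0.8, abs=1e-12)
        t = 0.8 * math.sqrt(3 / (1 - 0.64))
        assert res.p == pytest.approx(2 * sps.t.sf(t, 3), abs=1e-12)
        ref = sps.spearmanr([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_missing_pairs_dropped(self):
        res = spearman([1, 2, np.nan, 4, 5], [5, 4, 1, 2, 1])
        assert res.n == 4

    def test_zero_variance_flagged(self):
        res = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert not res.valid

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])

    def test_matrix_matches_scalar(self):
        rng = np.random.default_rng(17)
        X = np.round(rng.normal(size=(4, 25)), 1)  # ties included
        Y = np.round(rng.normal(size=(3, 25)), 1)
        rho, p = spearman_matrix(X, Y)
        for i in range(4):
            for j in range(3):
                ref = spearman(X[i], Y[j])
                assert rho[i, j] == pytest.approx(ref.rho, abs=1e-12)
                assert p[i, j] == pytest.approx(ref.p, abs=1e-12)


class TestAdjustments:
    def test_bh_equal_spacing(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_bh_single(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=30)
    )
    def test_bh_bruteforce_and_statsmodels(self, ps):
        """Step-up oracle: adjusted_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
        ps = np.asarray(ps)
        m = ps.size
        order = np.argsort(ps, kind="stable")
        expected = np.empty(m)
        for rank_pos, idx in enumerate(order):
            vals = [
                ps[order[j]] * m / (j + 1) for j in range(rank_pos, m)
            ]
            expected[idx] = min(1.0, min(vals))
        got = bh_adjust(ps)
        assert got == pytest.approx(expected, abs=1e-12)
        from statsmodels.stats.multitest import multipletests

        ref = multipletests(ps, method="fdr_bh")[1]
        assert got == pytest.approx(ref, abs=1e-12)

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=30)
    )
    def test_adjusted_bounds_and_rank_preservation(self, ps):
        ps = np.asarray(ps)
        adj = bh_adjust(ps)
        assert np.all(adj >= ps - 1e-15) and np.all(adj <= 1.0)
        # BH preserves the ordering of raw p-values
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_bonferroni(self):
        assert bonferroni_adjust([0.01], m=50)[0] == pytest.approx(0.5)
        assert bonferroni_adjust([0.5], m=3)[0] == 1.0
        assert bonferroni_adjust([0.3], m=1)[0] == pytest.approx(0.3)
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2], m=1)
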