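import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from normbench import (
    adjust_bonferroni,
    delta_pair,
    delta_select,
    estimate_surrogates,
    normalize_global,
    normalize_none,
    normalize_quantile,
    normalize_rank,
    quantile_reference,
    sva_test,
    t_test,
)

from conftest import make_matrix


class TestNone:
    def test_identity_and_labels(self, small_matrix):
        out = normalize_none(small_matrix)
        np.testing.assert_array_equal(out.values, small_matrix.values)
        assert out.group_of == small_matrix.group_of
        again = normalize_none(out)
        np.testing.assert_array_equal(again.values, out.values)


class TestGlobal:
    def test_single_column_mean_subtraction(self):
        m = make_matrix(np.column_stack([[1.0, 2, 3]] * 4))
        out = normalize_global(m)
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 0.0, 1.0])

    def test_idempotent(self, gaussian_matrix):
        once = normalize_global(gaussian_matrix)
        twice = normalize_global(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-14)

    def test_column_means_zero_against_oracle(self, rng):
        m = make_matrix(rng.normal(size=(50, 8)), groups="AAAABBBB")
        out = normalize_global(m)
        # brute-force oracle: subtract plainly computed per-column means
        expected = m.values - np.array(
            [sum(m.values[:, j]) / 50 for j in range(8)]
        )
        np.testing.assert_allclose(out.values, expected, atol=1e-12)
        assert np.abs(out.values.mean(axis=0)).max() < 1e-12


class TestRank:
    def test_fractional_ranks(self):
        m = make_matrix(np.column_stack([[0.3, 0.1, 0.2]] * 4))
        out = normalize_rank(m)
        np.testing.assert_allclose(out.values[:, 0], [3 / 3, 1 / 3, 2 / 3])

    def test_ties_get_midranks(self):
        m = make_matrix(np.column_stack([[5.0, 5.0, 1.0]] * 4))
        out = normalize_rank(m)
        np.testing.assert_allclose(out.values[:, 0], [2.5 / 3, 2.5 / 3, 1 / 3])

    @given(
        scale=st.floats(0.1, 10),
        shift=st.floats(-100, 100),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_transform_invariance(self, scale, shift, seed):
        vals = np.random.default_rng(seed).normal(size=(20, 4))
        m = make_matrix(vals)
        transformed = make_matrix(scale * vals + shift)
        np.testing.assert_allclose(
            normalize_rank(m).values, normalize_rank(transformed).values
        )

    def test_tie_free_column_is_permutation_of_grid(self, gaussian_matrix):
        out = normalize_rank(gaussian_matrix)
        g = gaussian_matrix.n_genes
        for j in range(out.n_arrays):
            np.testing.assert_allclose(
                np.sort(out.values[:, j]), np.arange(1, g + 1) / g
            )


class TestQuantile:
    def test_reference_of_two_arrays(self):
        m = make_matrix(
            np.column_stack([[1.0, 2, 3], [2.0, 4, 6], [1.0, 2, 3], [2.0, 4, 6]])
        )
        ref = quantile_reference(m)
        np.testing.assert_allclose(ref.q, [1.5, 3.0, 4.5])

    def test_two_array_brute_force(self):
        m = make_matrix(
            np.column_stack([[1.0, 2, 3], [6.0, 2, 4], [1.0, 2, 3], [6.0, 2, 4]])
        )
        out = normalize_quantile(m)
        # every column's sorted values equal the reference; ranks preserved
        ref = quantile_reference(m).q
        for j in range(4):
            np.testing.assert_allclose(np.sort(out.values[:, j]), ref)
            np.testing.assert_array_equal(
                np.argsort(out.values[:, j]), np.argsort(m.values[:, j])
            )

    def test_identical_arrays_unchanged(self):
        m = make_matrix(np.column_stack([[1.0, 5, 3]] * 4))
        out = normalize_quantile(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_idempotent_and_columns_share_distribution(self, gaussian_matrix):
        once = normalize_quantile(gaussian_matrix)
        sorted_cols = np.sort(once.values, axis=0)
        for j in range(1, once.n_arrays):
            np.testing.assert_allclose(sorted_cols[:, j], sorted_cols[:, 0])
        np.testing.assert_allclose(
            once.values.mean(axis=0), np.full(once.n_arrays, once.values.mean(axis=0)[0])
        )
        twice = normalize_quantile(once)
        np.testing.assert_allclose(twice.values, once.values)

    def test_reference_is_fixed_point(self, gaussian_matrix):
        once = normalize_quantile(gaussian_matrix)
        np.testing.assert_allclose(
            quantile_reference(once).q, quantile_reference(gaussian_matrix).q
        )


class TestDeltaPair:
    def test_pairing_structure_g4(self):
        # variances ascending with gene index by construction
        vals = np.array([[0.0, 0.1, -0.1, 0.0], [0, 1, -1, 0], [0, 2, -2, 0], [0, 3, -3, 0]])
        m = make_matrix(vals)
        pd_ = delta_pair(m)
        assert pd_.pair_members0 == [("g1", "g2"), ("g3", "g4")]
        assert pd_.pair_members1 == [("g2", "g3"), ("g4", "g1")]

    def test_difference_values_brute_force(self):
        vals = np.array([[0.0, 0.1, -0.1, 0.0], [0, 1, -1, 0], [0, 2, -2, 0], [0, 3, -3, 0]])
        m = make_matrix(vals)
        pd_ = delta_pair(m)
        np.testing.assert_allclose(pd_.diffs0, np.array([vals[1] - vals[0], vals[3] - vals[2]]))
        np.testing.assert_allclose(pd_.diffs1, np.array([vals[2] - vals[1], vals[0] - vals[3]]))

    def test_each_gene_once_per_offset(self, gaussian_matrix):
        pd_ = delta_pair(gaussian_matrix)
        for members in (pd_.pair_members0, pd_.pair_members1):
            flat = [g for pair in members for g in pair]
            assert sorted(flat) == sorted(gaussian_matrix.gene_ids)

    def test_odd_gene_count_drops_lowest_variance(self, rng):
        m = make_matrix(rng.normal(size=(5, 4)))
        with pytest.warns(UserWarning, match="odd gene count"):
            pd_ = delta_pair(m)
        assert pd_.diffs0.shape[0] == 2

    def test_shared_array_effect_cancels_exactly(self, rng):
        # well-separated gene variances keep the sort order stable under the
        # small common per-array offsets, which then cancel in every diff
        base = rng.normal(size=(10, 6)) * np.geomspace(0.5, 30, 10)[:, None]
        offsets = rng.normal(size=6) * 0.05
        clean = make_matrix(base, groups="AAABBB")
        shifted = make_matrix(base + offsets[None, :], groups="AAABBB")
        pc, ps = delta_pair(clean), delta_pair(shifted)
        assert pc.pair_members0 == ps.pair_members0
        np.testing.assert_allclose(pc.diffs0, ps.diffs0, atol=1e-12)
        np.testing.assert_allclose(pc.diffs1, ps.diffs1, atol=1e-12)


class TestDeltaSelect:
    @staticmethod
    def _adj(flags, n):
        p = np.where(flags, 0.001, 0.9)
        return adjust_bonferroni(p / n, alpha=0.05)

    def _pd(self, rng):
        return delta_pair(make_matrix(rng.normal(size=(4, 4)) * np.arange(1, 5)[:, None]))

    def test_intersection_logic(self, rng):
        pd_ = self._pd(rng)
        # offset-0: reject only the pair holding the 2 lowest-variance genes;
        # offset-1: reject only the middle pair -> intersection is one gene
        a0 = self._adj(np.array([True, False]), 2)
        a1 = self._adj(np.array([True, False]), 2)
        got = delta_select(a0, a1, pd_)
        shared = set(pd_.pair_members0[0]) & set(pd_.pair_members1[0])
        assert got == shared and len(got) == 1

    def test_no_rejections_empty(self, rng):
        pd_ = self._pd(rng)
        a = self._adj(np.array([False, False]), 2)
        assert delta_select(a, a, pd_) == set()

    def test_all_rejected_all_genes(self, rng):
        pd_ = self._pd(rng)
        a = self._adj(np.array([True, True]), 2)
        assert delta_select(a, a, pd_) == set(pd_.template.gene_ids)

    def test_mismatched_pair_counts_error(self, rng):
        pd_ = self._pd(rng)
        bad = self._adj(np.array([True, True, False]), 3)
        good = self._adj(np.array([True, True]), 2)
        with pytest.raises(ValueError):
            delta_select(bad, good, pd_)


class TestSurrogates:
    def test_k0_empty(self, gaussian_matrix):
        sv = estimate_surrogates(gaussian_matrix, 0)
        assert sv.H.shape == (8, 0)

    def test_columns_orthonormal(self, gaussian_matrix):
        sv = estimate_surrogates(gaussian_matrix, 3)
        np.testing.assert_allclose(sv.H.T @ sv.H, np.eye(3), atol=1e-8)

    def test_k_too_large_rejected(self, gaussian_matrix):
        with pytest.raises(ValueError):
            estimate_surrogates(gaussian_matrix, 6)

    def test_planted_factor_recovery(self, rng):
        # strong array-level factor balanced within both groups, so it is
        # uncorrelated with the phenotype and survives residualization
        n_arr, g = 8, 200
        factor = np.tile([1.0, -1.0], 4)
        loadings = rng.normal(2.0, 0.3, size=g)
        vals = loadings[:, None] * factor[None, :] + rng.normal(0, 0.1, (g, n_arr))
        m = make_matrix(vals, groups="AAAABBBB")
        sv = estimate_surrogates(m, 1)
        corr = np.corrcoef(sv.H[:, 0], factor)[0, 1]
        assert abs(corr) > 0.95


class TestSvaTest:
    def test_k0_reduces_to_pooled_t(self, gaussian_matrix):
        f = sva_test(gaussian_matrix, estimate_surrogates(gaussian_matrix, 0))
        t = t_test(gaussian_matrix)
        np.testing.assert_allclose(f.statistic, t.statistic**2, rtol=1e-10)
        np.testing.assert_allclose(f.p_raw, t.p_raw, rtol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        vals = rng.normal(size=(2, 8))
        m = make_matrix(vals, groups="AAAABBBB")
        sv = estimate_surrogates(m, 1)
        f = sva_test(m, sv)
        # brute-force least squares for gene 0
        y = vals[0]
        group = np.array([1.0] * 4 + [0.0] * 4)
        x0 = np.column_stack([np.ones(8), sv.H[:, 0]])
        x1 = np.column_stack([x0, group])
        rss = []
        for x in (x0, x1):
            beta = np.linalg.solve(x.T @ x, x.T @ y)
            r = y - x @ beta
            rss.append(r @ r)
        f_oracle = (rss[0] - rss[1]) / (rss[1] / (8 - 3))
        assert f.statistic[0] == pytest.approx(f_oracle, rel=1e-10)
        from scipy import stats as sps

        assert f.p_raw[0] == pytest.approx(sps.f.sf(f_oracle, 1, 5), rel=1e-10)

    def test_p_in_unit_interval(self, rng):
        m = make_matrix(rng.normal(size=(30, 10)), groups="AAAAABBBBB")
        f = sva_test(m, estimate_surrogates(m, 2))
        assert ((f.p_raw >= 0) & (f.p_raw <= 1)).all()
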