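import numpy as np
import pytest
from scipy import stats

from litgwas import (
    KernelSpec,
    cauchy_combine,
    compute_sqcp,
    lit_single_snp,
    region_test,
    spectral_factorize,
    ulit_statistic,
    weighted_chisq_sf,
    wlit_statistic,
)


def _centered(rng, n, d):
    M = rng.standard_normal((n, d))
    return M - M.mean(axis=0)


class TestSpectralFactorize:
    def test_single_column(self, rng):
        v = _centered(rng, 30, 1)[:, 0]
        f = spectral_factorize(v)
        np.testing.assert_allclose(f.eigenvalues, [v @ v])
        np.testing.assert_allclose(np.abs(f.eigenvectors[:, 0]),
                                   np.abs(v) / np.linalg.norm(v))

    def test_orthogonal_columns_eigenvalues(self):
        M = np.zeros((6, 2))
        M[:3, 0] = [2, -2, 0]  # norm sqrt(8)... use explicit norms 2 and 1
        M = np.array([[2.0, 0], [-2.0, 0], [0, 1.0], [0, -1.0]])
        M -= M.mean(axis=0)
        f = spectral_factorize(M)
        np.testing.assert_allclose(f.eigenvalues, [8.0, 2.0])

    def test_dense_reconstruction(self, rng):
        M = _centered(rng, 200, 6)
        f = spectral_factorize(M)
        K = (f.eigenvectors * f.eigenvalues) @ f.eigenvectors.T
        np.testing.assert_allclose(K, M @ M.T, atol=1e-8)
        np.testing.assert_allclose(f.eigenvectors.T @ f.eigenvectors,
                                   np.eye(f.d), atol=1e-10)

    def test_zero_matrix_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            spectral_factorize(np.zeros((10, 2)))

    def test_projection_kernel_unit_eigenvalues(self, rng):
        f = spectral_factorize(_centered(rng, 40, 3),
                               KernelSpec(kind="projection"))
        np.testing.assert_allclose(f.eigenvalues, 1.0)


class TestTraceIdentities:
    @pytest.mark.parametrize("n,d1,d2", [(100, 4, 1), (150, 9, 3), (300, 15, 2)])
    def test_wlit_matches_dense_kernels(self, rng, n, d1, d2):
        Z = _centered(rng, n, d1)
        X = _centered(rng, n, d2)
        T, _ = wlit_statistic(spectral_factorize(Z), spectral_factorize(X), n)
        dense = np.trace((X @ X.T) @ (Z @ Z.T)) / n
        assert abs(T - dense) < 1e-8 * max(1.0, abs(dense))

    @pytest.mark.parametrize("n,d1,d2", [(100, 4, 1), (150, 9, 3)])
    def test_ulit_matches_dense_projection_kernels(self, rng, n, d1, d2):
        Z = _centered(rng, n, d1)
        X = _centered(rng, n, d2)
        T, _ = ulit_statistic(spectral_factorize(Z), spectral_factorize(X), n)
        P = lambda M: M @ np.linalg.pinv(M.T @ M) @ M.T
        dense = np.trace(P(X) @ P(Z)) / n
        assert abs(T - dense) < 1e-10

    def test_orthogonal_features_give_zero(self, rng):
        x = np.array([-1.0, -1.0, 1.0, 1.0])
        z = np.array([-1.0, 1.0, -1.0, 1.0])  # orthogonal to x
        T, _ = wlit_statistic(spectral_factorize(z), spectral_factorize(x), 4)
        assert abs(T) < 1e-12

    def test_selfmatch_toy_value(self):
        x = np.array([-1.0, -1.0, 1.0, 1.0])
        T, _ = wlit_statistic(spectral_factorize(x), spectral_factorize(x), 4)
        assert T == pytest.approx((x @ x) ** 2 / 4)  # = 4

    def test_invariance_to_joint_permutation(self, rng):
        n = 80
        Z = _centered(rng, n, 5)
        x = _centered(rng, n, 1)
        perm = rng.permutation(n)
        T1, _ = wlit_statistic(spectral_factorize(Z), spectral_factorize(x), n)
        T2, _ = wlit_statistic(spectral_factorize(Z[perm]),
                               spectral_factorize(x[perm]), n)
        assert T1 == pytest.approx(T2, rel=1e-10)

    def test_ulit_invariant_to_rotation_of_z_basis(self, rng):
        n = 60
        Z = _centered(rng, n, 4)
        x = _centered(rng, n, 1)
        Q = np.linalg.qr(rng.standard_normal((4, 4)))[0]
        T1, _ = ulit_statistic(spectral_factorize(Z), spectral_factorize(x), n)
        T2, _ = ulit_statistic(spectral_factorize(Z @ Q),
                               spectral_factorize(x), n)
        assert T1 == pytest.approx(T2, rel=1e-10)


class TestWeightedChisqSf:
    def test_chi2_1_closed_form(self):
        assert weighted_chisq_sf(3.841, [1.0]) == pytest.approx(
            stats.chi2.sf(3.841, 1), abs=1e-12)

    def test_exponential_closed_form(self):
        # 0.5*chi2_2 is Exponential(1)
        assert weighted_chisq_sf(3.0, [0.5, 0.5]) == pytest.approx(
            np.exp(-3.0), abs=1e-12)

    def test_monte_carlo_oracle(self, rng):
        w = np.array([2.0, 1.0, 0.5])
        q = 7.0
        draws = (w * rng.chisquare(1, (10_000_000, 3))).sum(axis=1)
        mc = (draws > q).mean()
        se = np.sqrt(mc * (1 - mc) / draws.size)
        assert abs(weighted_chisq_sf(q, w) - mc) < 3 * se

    def test_equal_weights_match_chi2(self):
        for q in (0.5, 3.0, 20.0):
            assert weighted_chisq_sf(q, [0.25] * 6) == pytest.approx(
                stats.chi2.sf(q / 0.25, 6), abs=1e-10)

    def test_strictly_decreasing_in_q(self):
        w = [3.0, 1.0, 0.4, 0.1]
        qs = np.linspace(0.01, 60, 200)
        ps = [weighted_chisq_sf(q, w) for q in qs]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_deep_tail_is_finite_and_ordered(self):
        w = [2.0, 1.0, 0.5]
        p1 = weighted_chisq_sf(200.0, w)
        p2 = weighted_chisq_sf(400.0, w)
        assert 0 < p2 < p1 < 1e-15

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            weighted_chisq_sf(1.0, [1.0, -0.5])

    def test_q_zero_gives_one(self):
        assert weighted_chisq_sf(0.0, [1.0, 2.0]) == 1.0


class TestCauchyCombine:
    def test_identity_on_half(self):
        assert cauchy_combine([0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("p", [0.001, 0.01, 0.1, 0.3, 0.7, 0.99])
    def test_identical_pvalues_fixed_point(self, p):
        assert cauchy_combine([p, p]) == pytest.approx(p, rel=1e-9)

    def test_printed_formula_value(self):
        # mean of tan((0.5-p)pi) for (0.01, 0.5) referred to standard Cauchy
        assert cauchy_combine([0.01, 0.5]) == pytest.approx(0.0200, abs=5e-5)

    def test_tiny_pvalues_stable(self):
        p = cauchy_combine([1e-50, 0.8])
        assert p == pytest.approx(2e-50, rel=1e-3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cauchy_combine([])


class TestLitSingleSnp:
    def test_null_pvalues_uniform(self, rng):
        n, r = 400, 3
        pw, pu, pa = [], [], []
        for _ in range(600):
            E = rng.standard_normal((n, r))
            x = rng.binomial(2, 0.3, n).astype(float)
            Z = compute_sqcp(E - E.mean(axis=0))
            res = lit_single_snp(Z, x - x.mean())
            pw.append(res.p_wlit)
            pu.append(res.p_ulit)
            pa.append(res.p_alit)
        for p in (pw, pu, pa):
            assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_permutation_oracle(self, rng):
        """Asymptotic wLIT p agrees with a permutation p on a small toy."""
        n = 60
        E = rng.standard_normal((n, 2))
        x = rng.binomial(2, 0.4, n).astype(float)
        Z = compute_sqcp(E - E.mean(axis=0))
        res = lit_single_snp(Z, x - x.mean(), permutations=100_000, rng=rng)
        se = np.sqrt(res.p_wlit_perm * (1 - res.p_wlit_perm) / 100_000)
        # asymptotic null at n=60 is approximate; allow a generous band
        assert abs(res.p_wlit - res.p_wlit_perm) < max(5 * se, 0.05)
        assert abs(res.p_ulit - res.p_ulit_perm) < max(5 * se, 0.05)

    def test_duplicate_z_columns_are_harmless(self, rng):
        n = 120
        E = rng.standard_normal((n, 3))
        x = rng.binomial(2, 0.3, n).astype(float)
        Z = compute_sqcp(E - E.mean(axis=0)).values
        Zdup = np.column_stack([Z, Z[:, 0]])
        r1 = lit_single_snp(Z, x - x.mean())
        r2 = lit_single_snp(Zdup, x - x.mean())
        # the duplicate adds no new direction: rank and the projection-kernel
        # (uLIT) p-value are unchanged; wLIT reweights eigenvalues by design
        assert r1.d1 == r2.d1
        assert r1.p_ulit == pytest.approx(r2.p_ulit, rel=1e-8)

    def test_monomorphic_snp_rejected(self, rng):
        Z = rng.standard_normal((50, 3))
        with pytest.raises(ValueError, match="monomorphic"):
            lit_single_snp(Z, np.zeros(50))

    def test_ulit_p_equals_chi2_closed_form(self, rng):
        n = 150
        E = rng.standard_normal((n, 3))
        x = rng.binomial(2, 0.25, n).astype(float)
        Z = compute_sqcp(E - E.mean(axis=0))
        res = lit_single_snp(Z, x - x.mean())
        closed = stats.chi2.sf(n * n * res.t_ulit, df=res.d1 * res.d2)
        assert res.p_ulit == pytest.approx(closed, abs=1e-10)


class TestRegionTest:
    def test_m0_one_reduces_to_single_snp(self, rng):
        n = 100
        E = rng.standard_normal((n, 3))
        x = rng.binomial(2, 0.3, n).astype(float)
        Z = compute_sqcp(E - E.mean(axis=0))
        r1 = lit_single_snp(Z, x - x.mean())
        r2 = region_test(Z, (x - x.mean())[:, None])
        assert r1.p_wlit == pytest.approx(r2.p_wlit, rel=1e-10)
        assert r1.p_ulit == pytest.approx(r2.p_ulit, rel=1e-10)

    def test_duplicate_snp_columns_reduce_rank(self, rng):
        n = 100
        E = rng.standard_normal((n, 3))
        x = rng.binomial(2, 0.3, n).astype(float)
        Z = compute_sqcp(E - E.mean(axis=0))
        X2 = np.column_stack([x, x])
        with pytest.warns(UserWarning, match="collinear"):
            r2 = region_test(Z, X2)
        r1 = region_test(Z, x[:, None])
        assert r2.d2 == 1
        assert r1.p_wlit == pytest.approx(r2.p_wlit, rel=1e-8)

    def test_null_uniform_m0_5(self, rng):
        n = 300
        ps = []
        for _ in range(400):
            E = rng.standard_normal((n, 2))
            X = rng.binomial(2, 0.3, (n, 5)).astype(float)
            Z = compute_sqcp(E - E.mean(axis=0))
            ps.append(region_test(Z, X - X.mean(axis=0)).p_alit)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
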