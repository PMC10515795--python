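import numpy as np
import pytest
from scipy import stats

from litgwas import (
    CovariateMatrix,
    GenotypeVector,
    TraitMatrix,
    additive_cross_trait_test,
    compute_sqcp,
    dominance_retest,
    gc_adjust,
    genomic_inflation,
    iaf_standardize,
    ld_adjust_and_retest,
    lit_single_snp,
    marginal_test,
    residualize,
)


class TestGenomicInflation:
    def test_reference_median_gives_one(self):
        assert genomic_inflation(np.full(200, 0.5)) == pytest.approx(1.0)

    def test_doubled_chisq_gives_two(self, rng):
        chi = 2.0 * rng.chisquare(1, 100_000)
        p = stats.chi2.sf(chi, 1)
        assert genomic_inflation(p) == pytest.approx(2.0, rel=0.05)

    def test_uniform_pvalues_give_one(self, rng):
        p = rng.uniform(size=100_000)
        assert genomic_inflation(p) == pytest.approx(1.0, rel=0.02)

    def test_few_pvalues_warns(self):
        with pytest.warns(UserWarning, match="noisy"):
            genomic_inflation(np.linspace(0.01, 0.99, 50))


class TestGcAdjust:
    def test_lambda_one_is_identity(self, rng):
        p = rng.uniform(size=100)
        np.testing.assert_array_equal(gc_adjust(p, 1.0), p)

    def test_lambda_below_one_leaves_unchanged(self, rng):
        p = rng.uniform(size=100)
        np.testing.assert_array_equal(gc_adjust(p, 0.8), p)

    def test_closed_form_value(self):
        # chi2(p=0.05) = 3.8415; /2 -> 1.9207; sf -> 0.16578
        adj = gc_adjust(np.array([0.05]), 2.0)[0]
        expected = stats.chi2.sf(stats.chi2.isf(0.05, 1) / 2.0, 1)
        assert adj == pytest.approx(expected, abs=1e-12)
        assert adj == pytest.approx(0.1658, abs=2e-4)

    def test_order_preserved(self, rng):
        p = np.sort(rng.uniform(size=50))
        adj = gc_adjust(p, 1.37)
        assert np.all(np.diff(adj) >= 0)


class TestAdditiveCrossTraitTest:
    def test_null_uniform(self, rng):
        n = 300
        ps = []
        for _ in range(300):
            Y = rng.standard_normal((n, 3))
            x = rng.binomial(2, 0.3, n).astype(float)
            ps.append(additive_cross_trait_test(Y, x - x.mean()).p_alit)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_power_on_additive_signal(self, rng):
        n = 10_000
        x = rng.binomial(2, 0.3, n).astype(float)
        Y = np.column_stack([0.2 * x + rng.standard_normal(n),
                             rng.standard_normal(n)])
        res = additive_cross_trait_test(Y - Y.mean(0), x - x.mean())
        assert res.p_alit < 5e-8

    def test_single_trait_matches_marginal_regression(self, rng):
        n = 500
        x = rng.binomial(2, 0.3, n).astype(float)
        y = 0.1 * x + rng.standard_normal(n)
        res = additive_cross_trait_test(y[:, None], x - x.mean())
        marg = marginal_test((y - y.mean())[:, None], x - x.mean())
        assert res.p_wlit == pytest.approx(marg.pvalues[0], abs=1e-6)


def _toy_traits(rng, n, r=2):
    Y = rng.standard_normal((n, r))
    return TraitMatrix(Y, np.arange(n), [f"t{k}" for k in range(r)])


class TestLdAdjustAndRetest:
    def test_no_significant_neighbors_equals_plain(self, rng):
        n = 500
        traits = _toy_traits(rng, n)
        lead = GenotypeVector(rng.binomial(2, 0.3, n).astype(float), "lead")
        nb = [GenotypeVector(rng.binomial(2, 0.3, n).astype(float), "nb1")]
        res, info = ld_adjust_and_retest(traits, None, lead, nb, alpha=5e-8)
        assert "unadjusted" in res.flags
        resid = residualize(traits, genotype=lead, studentized=True)
        plain = lit_single_snp(compute_sqcp(resid.values),
                               lead.dosages - lead.dosages.mean(),
                               snp_id="lead")
        assert res.p_alit == pytest.approx(plain.p_alit, rel=1e-9)

    def test_confound_rescued_and_signal_survives(self, rng):
        """An additive neighbor in LD manufactures a spurious interaction at
        the lead SNP; regressing it out removes the artifact, while a true
        GxE signal at the lead survives the same adjustment."""
        n = 30_000
        # asymmetric LD: the neighbor allele rides on the lead haplotype, so
        # Var(neighbor | lead) grows with the lead genotype
        lead_hap = rng.binomial(1, 0.5, (n, 2))
        nb_hap = lead_hap * rng.binomial(1, 0.7, (n, 2))
        lead = lead_hap.sum(axis=1).astype(float)
        neighbor = nb_hap.sum(axis=1).astype(float)

        # confounded case: traits depend on the *neighbor* only, additively;
        # removing only the lead's additive effect leaves residuals whose
        # variance differs by lead genotype (imperfect additive correction)
        Y = 0.6 * neighbor[:, None] + rng.standard_normal((n, 2))
        traits = TraitMatrix(Y, np.arange(n), ["a", "b"])
        lead_gv = GenotypeVector(lead, "lead")
        nb_gv = [GenotypeVector(neighbor, "nb")]
        naive = residualize(traits, genotype=lead_gv, studentized=True)
        p_naive = lit_single_snp(compute_sqcp(naive.values),
                                 lead - lead.mean()).p_alit
        adj, info = ld_adjust_and_retest(traits, None, lead_gv, nb_gv,
                                         alpha=1e-4)
        assert info["n_selected"] == 1
        assert p_naive < 1e-6  # the manufactured artifact is detectable
        assert adj.p_alit > 1e-3  # and the LD adjustment removes it

        # true-signal case: latent interaction at the lead itself
        M = rng.standard_normal(n)
        Y2 = 0.3 * neighbor[:, None] + np.column_stack([
            0.3 * M + 0.25 * M * lead + rng.standard_normal(n),
            0.3 * M + 0.25 * M * lead + rng.standard_normal(n),
        ])
        traits2 = TraitMatrix(Y2, np.arange(n), ["a", "b"])
        adj2, _ = ld_adjust_and_retest(traits2, None, lead_gv, nb_gv,
                                       alpha=1e-4)
        assert adj2.p_alit < 1e-6


class TestDominanceRetest:
    def test_genotype_level_mean_function_controlled(self, rng):
        """Traits driven by a pure genotype-level mean (e.g. indicator X==2)
        yield uniform p-values after the 2-df adjustment."""
        ps = []
        n = 1_000
        for _ in range(200):
            x = rng.binomial(2, 0.4, n).astype(float)
            f = (x == 2).astype(float) * 0.8
            Y = f[:, None] + rng.standard_normal((n, 2))
            traits = TraitMatrix(Y, np.arange(n), ["a", "b"])
            ps.append(dominance_retest(traits, None,
                                       GenotypeVector(x)).p_alit)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_additive_trait_residuals_match_additive_adjustment(self, rng):
        n = 2_000
        x = rng.binomial(2, 0.3, n).astype(float)
        Y = 0.5 * x[:, None] + rng.standard_normal((n, 2))
        traits = TraitMatrix(Y, np.arange(n), ["a", "b"])
        add = residualize(traits, genotype=GenotypeVector(x))
        dom = residualize(traits, genotype=GenotypeVector(x), dominance=True)
        # a purely additive signal leaves nothing for the extra dominance df
        corr = np.corrcoef(add.values[:, 0], dom.values[:, 0])[0, 1]
        assert corr > 0.999

    def test_true_gxe_survives(self, rng):
        n = 50_000
        x = rng.binomial(2, 0.25, n).astype(float)
        M = rng.standard_normal(n)
        Y = np.column_stack([
            0.3 * M + 0.2 * M * x + rng.standard_normal(n),
            0.3 * M + 0.2 * M * x + rng.standard_normal(n),
        ])
        traits = TraitMatrix(Y, np.arange(n), ["a", "b"])
        res = dominance_retest(traits, None, GenotypeVector(x))
        assert res.p_alit < 5e-8

    def test_nonlinear_mean_artifact_removed(self, rng):
        """A purely mean-nonlinear genotype effect (no variance effect)
        fools the additive-only pipeline but is fully absorbed by the 2-df
        genotypic adjustment."""
        n = 2_000
        reps = 120
        naive_hits = adj_ps = 0
        ps = []
        for _ in range(reps):
            x = rng.binomial(2, 0.4, n).astype(float)
            g = np.exp(x)  # convex genotype-level mean, noise added after
            Y = g[:, None] + rng.standard_normal((n, 2))
            traits = TraitMatrix(Y, np.arange(n), ["a", "b"])
            naive = residualize(traits, genotype=GenotypeVector(x),
                                studentized=True)
            p_naive = lit_single_snp(compute_sqcp(naive.values),
                                     x - x.mean()).p_alit
            naive_hits += p_naive < 0.05
            ps.append(dominance_retest(traits, None, GenotypeVector(x)).p_alit)
        assert naive_hits > 0.5 * reps  # the artifact is real
        assert stats.kstest(ps, "uniform").pvalue > 0.01  # and fully removed

    def test_single_level_rejected(self):
        traits = TraitMatrix(np.random.default_rng(0).standard_normal((50, 2)),
                             np.arange(50), ["a", "b"])
        with pytest.raises(ValueError, match="levels"):
            dominance_retest(traits, None, GenotypeVector(np.ones(50)))


class TestIafStandardize:
    def test_no_axes_reduces_to_plain_standardization(self, rng):
        x = rng.binomial(2, 0.3, 400).astype(float)
        out = iaf_standardize(GenotypeVector(x))
        p = x.mean() / 2
        np.testing.assert_allclose(out, (x - 2 * p) / np.sqrt(2 * p * (1 - p)))

    def test_two_subpopulations_unit_variance_within(self, rng):
        n_half = 3_000
        pops = np.repeat([0, 1], n_half)
        freqs = np.where(pops == 0, 0.1, 0.45)
        x = rng.binomial(2, freqs).astype(float)
        out = iaf_standardize(GenotypeVector(x), pops.astype(float))
        for g in (0, 1):
            assert np.var(out[pops == g]) == pytest.approx(1.0, rel=0.1)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            iaf_standardize(GenotypeVector(np.zeros(100), "mono"))
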