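import numpy as np
import pandas as pd
import pytest

from cattletemp.mtm import (
    DesignError,
    MTMDesign,
    build_design,
    fit_mtm,
    summarize_genetics,
)
from cattletemp.pedigree import RelationshipMatrix, build_A
from cattletemp.synthetic import (
    GeneticArchitecture,
    simulate_breeding_values,
    simulate_pedigree,
    simulate_phenotypes,
)


def identity_relationship(n):
    return RelationshipMatrix(np.eye(n), [f"a{i}" for i in range(n)])


class TestDesign:
    def test_build_design_from_phenotype_table(self):
        ped = simulate_pedigree(10, 1, 10, 2, seed=0)
        phen = simulate_phenotypes(ped, seed=0)
        design = build_design(phen.table, build_A(ped),
                              traits=["ds", "ssd", "cvssd"])
        assert design.k == 3
        assert design.x_names[0] == "intercept"
        assert any(n.startswith("year_date_") for n in design.x_names)
        # standardized by default
        np.testing.assert_allclose(design.Y.std(ddof=1), 1.0, atol=1e-12)

    def test_confounded_fixed_effects_named(self):
        n = 30
        Y = pd.DataFrame(np.random.default_rng(0).standard_normal((n, 1)),
                         index=[f"a{i}" for i in range(n)], columns=["y"])
        X = np.column_stack([np.ones(n), np.ones(n)])  # intercept duplicated
        with pytest.raises(DesignError, match="confounded"):
            MTMDesign(Y, X, ["intercept", "dup"], identity_relationship(n))

    def test_unknown_animal_rejected(self):
        ped = simulate_pedigree(5, 1, 4, 1, seed=1)
        phen = simulate_phenotypes(ped, seed=1)
        table = phen.table.copy()
        table.loc[0, "animal_id"] = "stranger"
        with pytest.raises(DesignError, match="missing from the pedigree"):
            build_design(table, build_A(ped))


class TestConjugateOracle:
    def test_single_trait_identity_A_matches_marginal_posterior(self):
        """k=1, A=I, fixed residual variance: the Gibbs posterior of the
        additive variance must match the marginal posterior computed by
        integrating the breeding values out analytically (1-D quadrature).

        With u integrated, y ~ N(0, (s2u + s2e) I) and the prior is the
        1-dimensional inverse-Wishart IW(1, 5) = IG(5/2, 1/2)."""
        rng = np.random.default_rng(21)
        n, s2u_true, s2e = 400, 0.8, 0.5
        y = rng.normal(0, np.sqrt(s2u_true + s2e), size=n)
        Y = pd.DataFrame(y, index=[f"a{i}" for i in range(n)], columns=["y"])
        design = MTMDesign(Y, np.empty((n, 0)), [], identity_relationship(n),
                           scale=None)
        samples = fit_mtm(design, n_iter=12000, n_burnin=2000, thin=2, seed=22,
                          fix_sigma_e=np.array([[s2e]]), calibrate_scale=False)
        draws = samples.flat("sigma_u[y,y]")

        grid = np.linspace(1e-3, 5.0, 4000)
        ss = (y**2).sum()
        loglik = -0.5 * n * np.log(grid + s2e) - 0.5 * ss / (grid + s2e)
        logprior = -(5 / 2 + 1) * np.log(grid) - 0.5 / grid
        post = np.exp(loglik + logprior - (loglik + logprior).max())
        post /= np.trapezoid(post, grid)
        mean_oracle = np.trapezoid(grid * post, grid)
        sd_oracle = np.sqrt(np.trapezoid((grid - mean_oracle) ** 2 * post, grid))
        assert draws.mean() == pytest.approx(mean_oracle, abs=0.25 * sd_oracle)
        assert draws.std() == pytest.approx(sd_oracle, rel=0.15)


class TestInvariances:
    def test_relabeling_animals_leaves_posterior_unchanged(self):
        ped = simulate_pedigree(8, 2, 10, 2, seed=3)
        phen = simulate_phenotypes(ped, seed=3)
        A = build_A(ped)
        table = phen.table
        d1 = build_design(table, A, traits=["ds", "ssd"])
        perm = np.random.default_rng(4).permutation(len(table))
        d2 = build_design(table.iloc[perm].reset_index(drop=True), A,
                          traits=["ds", "ssd"])
        s1 = fit_mtm(d1, n_iter=400, n_burnin=100, thin=1, seed=5,
                     calibrate_scale=False)
        s2 = fit_mtm(d2, n_iter=400, n_burnin=100, thin=1, seed=5,
                     calibrate_scale=False)
        # same model: posterior summaries agree to Monte-Carlo accuracy
        m1 = s1.summary()["mean"].filter(like="sigma_")
        m2 = s2.summary()["mean"].filter(like="sigma_")
        np.testing.assert_allclose(m1, m2, atol=0.12)

    def test_retained_covariance_draws_are_positive_definite(self):
        ped = simulate_pedigree(10, 2, 15, 2, seed=6)
        phen = simulate_phenotypes(ped, seed=6)
        design = build_design(phen.table, build_A(ped), traits=["ds", "ssd", "cvssd"])
        s = fit_mtm(design, n_iter=300, n_burnin=100, thin=1, seed=7,
                    calibrate_scale=False)
        traits = s.extra["trait_names"]
        for kind in ("u", "e"):
            for row in range(s.n_kept):
                M = np.empty((3, 3))
                for a, ta in enumerate(traits):
                    for b, tb in enumerate(traits):
                        i, j = sorted((a, b))
                        M[a, b] = s.draws[0, row, s.parameter_names.index(
                            f"sigma_{kind}[{traits[i]},{traits[j]}]")]
                assert np.linalg.eigvalsh(M).min() > 0

    def test_deterministic_given_seed(self):
        ped = simulate_pedigree(6, 1, 8, 2, seed=8)
        phen = simulate_phenotypes(ped, seed=8)
        design = build_design(phen.table, build_A(ped), traits=["ds", "ssd"])
        a = fit_mtm(design, n_iter=200, n_burnin=50, thin=1, seed=9)
        b = fit_mtm(design, n_iter=200, n_burnin=50, thin=1, seed=9)
        np.testing.assert_array_equal(a.draws, b.draws)


class TestSummaries:
    def test_equal_covariances_give_half_heritability_zero_correlation(self):
        # constant draws with Sigma_u = Sigma_e = I
        names = ["sigma_u[a,a]", "sigma_u[a,b]", "sigma_u[b,b]",
                 "sigma_e[a,a]", "sigma_e[a,b]", "sigma_e[b,b]"]
        vals = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 1.0])
        draws = np.tile(vals, (1, 200, 1))
        from cattletemp.mcmc import PosteriorSamples
        s = PosteriorSamples(draws, names, 0,
                             extra={"trait_names": ["a", "b"]})
        g = summarize_genetics(s)
        assert (g.heritability["mean"] == 0.5).all()
        assert g.genetic_correlation.loc["a", "b"] == 0.0

    def test_correlations_bounded_and_fixed_effect_hpd_reported(self):
        ped = simulate_pedigree(10, 2, 15, 2, seed=10)
        phen = simulate_phenotypes(ped, seed=10)
        design = build_design(phen.table, build_A(ped), traits=["ds", "ssd"])
        s = fit_mtm(design, n_iter=600, n_burnin=200, thin=1, seed=11,
                    calibrate_scale=False)
        g = summarize_genetics(s)
        off = g.genetic_correlation.loc["ds", "ssd"]
        assert -1.0 <= off <= 1.0
        assert np.allclose(np.diag(g.genetic_correlation), 1.0)
        assert {"trait", "effect", "hpd_low", "hpd_high", "significant"} <= \
            set(g.fixed_effects.columns)
        assert (g.fixed_effects["hpd_low"] <= g.fixed_effects["hpd_high"]).all()


def test_identity_A_special_case_matches_independent_sampler():
    """With A = I the model is an ordinary multivariate random-effect model;
    an independent scalar-form Gibbs sampler on a tiny dataset must agree."""
    rng = np.random.default_rng(30)
    n, k = 50, 1
    s2u, s2e = 1.0, 1.0
    y = rng.normal(0, np.sqrt(s2u + s2e), size=n)
    Y = pd.DataFrame(y, index=[f"a{i}" for i in range(n)], columns=["y"])
    design = MTMDesign(Y, np.empty((n, 0)), [], identity_relationship(n))
    ours = fit_mtm(design, n_iter=20000, n_burnin=4000, thin=4, seed=31,
                   calibrate_scale=False)

    # independent scalar implementation (different code path, same model)
    u = np.zeros(n)
    su, se = 0.5, 0.5
    keep = []
    for it in range(20000):
        var = 1.0 / (1.0 / se + 1.0 / su)
        u = var * y / se + rng.standard_normal(n) * np.sqrt(var)
        su = 1.0 / rng.gamma((5 + n) / 2, 2.0 / (1.0 + u @ u))
        r = y - u
        se = 1.0 / rng.gamma((5 + n) / 2, 2.0 / (1.0 + r @ r))
        if it >= 4000 and it % 4 == 0:
            keep.append((su, se))
    keep = np.array(keep)
    assert ours.flat("sigma_u[y,y]").mean() == pytest.approx(
        keep[:, 0].mean(), abs=0.1)
    assert ours.flat("sigma_e[y,y]").mean() == pytest.approx(
        keep[:, 1].mean(), abs=0.1)
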