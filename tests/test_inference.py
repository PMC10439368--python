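"""PERMANOVA and PGLS, checked against closed forms and independent packages."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from frogmorph import inference, phylo as ph
from frogmorph.phylo import PhyloCovariance
from frogmorph.simulate import simulate_tree


def _identity_cov(n):
    return PhyloCovariance(tuple(f"t{i}" for i in range(n)), np.eye(n))


class TestPermanova:
    def test_univariate_two_groups_equals_anova_f(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        groups = ["a"] * 14 + ["b"] * 16
        res = inference.permanova(x[:, None], groups, n_perm=9, seed=0)
        f_classic = stats.f_oneway(x[:14], x[14:]).statistic
        assert res.pseudo_f == pytest.approx(f_classic, rel=1e-10)

    def test_matches_scikit_bio_permanova(self):
        from skbio.stats.distance import DistanceMatrix, permanova as sk_permanova
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(1)
        X = rng.normal(size=(24, 4))
        groups = (["a"] * 8 + ["b"] * 8 + ["c"] * 8)
        res = inference.permanova(X, groups, n_perm=9, seed=0)
        dm = DistanceMatrix(squareform(pdist(X)))
        sk = sk_permanova(dm, grouping=groups, permutations=9)
        assert res.pseudo_f == pytest.approx(sk["test statistic"], rel=1e-8)

    def test_separated_clusters_reach_minimal_p(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.1, (15, 3)),
                       rng.normal(50, 0.1, (15, 3))])
        groups = ["a"] * 15 + ["b"] * 15
        res = inference.permanova(X, groups, n_perm=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_seeded_reproducibility_and_r2_bounds(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 3))
        groups = ["a"] * 10 + ["b"] * 10
        r1 = inference.permanova(X, groups, n_perm=99, seed=7)
        r2 = inference.permanova(X, groups, n_perm=99, seed=7)
        assert r1.p_value == r2.p_value
        assert 0 <= r1.r_squared <= 1

    def test_observed_f_invariant_to_row_relabeling(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(18, 3))
        groups = np.array(["a"] * 6 + ["b"] * 6 + ["c"] * 6)
        perm = rng.permutation(18)
        r1 = inference.permanova(X, groups.tolist(), n_perm=9, seed=0)
        r2 = inference.permanova(X[perm], groups[perm].tolist(), n_perm=9, seed=0)
        assert r1.pseudo_f == pytest.approx(r2.pseudo_f, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="b"):
            inference.permanova(np.zeros((4, 2)), ["a", "a", "a", "b"], n_perm=9)


class TestPairwisePermanova:
    def test_pair_count_and_adjustment_order(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(24, 3))
        groups = ["a"] * 8 + ["b"] * 8 + ["c"] * 8
        res = inference.pairwise_permanova(X, groups, n_perm=49, seed=0)
        assert len(res.pairwise) == 3  # k(k-1)/2 with k=3
        assert (res.pairwise["p_adjusted"] >= res.pairwise["p_raw"] - 1e-12).all()

    def test_adjustments_match_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.01, 0.04, 0.03, 0.2, 0.5])
        for method, sm_name in (("bonferroni", "bonferroni"),
                                ("holm", "holm"), ("bh", "fdr_bh")):
            ours = inference._adjust_p(p, method)
            theirs = multipletests(p, method=sm_name)[1]
            np.testing.assert_allclose(ours, theirs, rtol=1e-12)

    def test_known_shift_flags_only_shifted_pairs(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=(60, 3))
        groups = ["a"] * 20 + ["b"] * 20 + ["c"] * 20
        X = base.copy()
        X[40:] += 8.0  # only group c shifted far away
        res = inference.pairwise_permanova(X, groups, n_perm=199, seed=1)
        tab = res.pairwise.set_index("pair")
        assert tab.loc["a vs c", "p_adjusted"] < 0.05
        assert tab.loc["b vs c", "p_adjusted"] < 0.05
        assert tab.loc["a vs b", "p_adjusted"] > 0.1


class TestPgls:
    def test_identity_covariance_matches_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        n = 40
        x = rng.normal(size=n)
        y = 1.5 + 2.0 * x + rng.normal(size=n)
        design = pd.DataFrame({"x": x})
        fit = inference.pgls_fit(y, design, _identity_cov(n), lam=0.0)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(fit.coefficients["estimate"], ols.params,
                                   rtol=1e-10)
        np.testing.assert_allclose(fit.coefficients["se"], ols.bse, rtol=1e-10)
        np.testing.assert_allclose(fit.coefficients["p"], ols.pvalues,
                                   rtol=1e-8)

    def test_perfect_fit_recovers_beta_exactly(self):
        rng = np.random.default_rng(8)
        tree = simulate_tree(20, seed=1)
        cov = ph.brownian_covariance(tree)
        x = rng.normal(size=20)
        y = 3.0 - 1.2 * x
        fit = inference.pgls_fit(y, pd.DataFrame({"x": x}), cov, lam=1.0)
        np.testing.assert_allclose(fit.coefficients["estimate"], [3.0, -1.2],
                                   rtol=1e-8)

    def test_matches_frozen_phylosig_lambda(self):
        """Intercept-only ML λ and log-likelihood frozen from phytools'
        phylosig(method='lambda') on the 7-tip fixture."""
        from oracle_fixtures import TREE8, TIPS7, Y7

        tree = ph.read_newick(TREE8)
        cov = ph.brownian_covariance(tree, tip_order=TIPS7)
        y = np.array([Y7[t] for t in TIPS7])
        fit = inference.pgls_fit(y, pd.DataFrame(index=TIPS7), cov, lam="ML")
        assert fit.lam == pytest.approx(0.0, abs=1e-3)
        assert fit.log_likelihood == pytest.approx(-2.322683, abs=1e-3)

    def test_profile_peak_beats_grid_endpoints(self):
        rng = np.random.default_rng(9)
        tree = simulate_tree(32, seed=2)
        cov = ph.brownian_covariance(tree)
        L = np.linalg.cholesky(cov.matrix + 1e-12 * np.eye(32))
        y = L @ rng.normal(size=32)
        fit = inference.pgls_fit(y, pd.DataFrame(index=cov.tip_order), cov)
        prof = fit.lam_profile
        best_ll = inference._gls_loglik(
            y, np.ones((32, 1)), cov, fit.lam)[0]
        assert best_ll >= prof["log_likelihood"].iloc[0] - 1e-9
        assert best_ll >= prof["log_likelihood"].iloc[-1] - 1e-9

    def test_lambda_max_exceeds_one_on_nonultrametric_tree(self):
        tree = simulate_tree(24, seed=3, model="yule-rate-heterogeneous")
        cov = ph.brownian_covariance(tree)
        assert ph.lambda_max(cov) > 1.0

    def test_integer_coding_single_coefficient_per_factor(self):
        rng = np.random.default_rng(10)
        n = 30
        groups = rng.choice(["WH", "TJ", "AJ"], size=n).tolist()
        y = rng.normal(size=n)
        fit = inference.pgls_fit(
            y, pd.DataFrame({"lm": groups}), _identity_cov(n), lam=0.0,
            level_orders={"lm": ["WH", "TJ", "AJ"]},
        )
        assert list(fit.coefficients.index) == ["Intercept", "lm"]
        fit_d = inference.pgls_fit(
            y, pd.DataFrame({"lm": groups}), _identity_cov(n), lam=0.0,
            coding="dummy", level_orders={"lm": ["WH", "TJ", "AJ"]},
        )
        assert len(fit_d.coefficients) == 3

    def test_aic_identity(self):
        rng = np.random.default_rng(11)
        n = 25
        y = rng.normal(size=n)
        fit = inference.pgls_fit(y, pd.DataFrame({"x": rng.normal(size=n)}),
                                 _identity_cov(n), lam=0.0)
        assert fit.aic == pytest.approx(
            -2 * fit.log_likelihood + 2 * (fit.k + 2))
        assert fit.df_residual == n - fit.k


class TestSelectModel:
    def test_identical_candidates_tie_broken_by_order(self):
        rng = np.random.default_rng(12)
        n = 30
        x = rng.normal(size=n)
        y = x + rng.normal(size=n)
        d = pd.DataFrame({"x": x})
        fits = inference.select_model(y, {"first": d, "second": d.copy()},
                                      _identity_cov(n))
        assert fits[0].design_description.endswith("first")

    def test_true_predictor_beats_pure_noise_predictor(self):
        rng = np.random.default_rng(13)
        tree = simulate_tree(64, seed=5)
        cov = ph.brownian_covariance(tree)
        wins = 0
        runs = 12
        for _ in range(runs):
            x = rng.normal(size=64)
            z = rng.normal(size=64)
            L = np.linalg.cholesky(cov.matrix + 1e-12 * np.eye(64))
            y = 2.0 * x + 0.5 * (L @ rng.normal(size=64))
            fits = inference.select_model(
                y, {"true": pd.DataFrame({"x": x}),
                    "noise": pd.DataFrame({"z": z}),
                    "both": pd.DataFrame({"x": x, "z": z})},
                cov,
            )
            wins += fits[0].design_description.endswith(("true", "both"))
        assert wins == runs

    def test_simpler_model_usually_wins_under_null_extra_predictor(self):
        rng = np.random.default_rng(14)
        tree = simulate_tree(64, seed=6)
        cov = ph.brownian_covariance(tree)
        L = np.linalg.cholesky(cov.matrix + 1e-12 * np.eye(64))
        wins = 0
        runs = 20
        for _ in range(runs):
            x = rng.normal(size=64)
            z = rng.normal(size=64)  # truly null
            y = 1.5 * x + L @ rng.normal(size=64)
            fits = inference.select_model(
                y, {"simple": pd.DataFrame({"x": x}),
                    "extra": pd.DataFrame({"x": x, "z": z})}, cov,
            )
            wins += fits[0].design_description.endswith("simple")
        assert wins >= int(0.6 * runs)
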