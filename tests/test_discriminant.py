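"""LDA, pFDA, confusion matrices, case-wise and held-out-tip prediction."""

import numpy as np
import pandas as pd
import pytest

from frogmorph import discriminant as da
from frogmorph import phylo as ph
from frogmorph.phylo import PhyloCovariance
from frogmorph.simulate import simulate_tree


def _identity_cov(labels):
    n = len(labels)
    return PhyloCovariance(tuple(labels), np.eye(n))


def _gaussian_classes(rng, means, n_per, sd=1.0):
    X, labels = [], []
    for g, mu in means.items():
        X.append(rng.normal(mu, sd, size=(n_per, len(np.atleast_1d(mu)))))
        labels += [g] * n_per
    return np.vstack(X), labels


class TestLda:
    def test_separated_1d_classes_and_midpoint_boundary(self):
        rng = np.random.default_rng(0)
        X, labels = _gaussian_classes(rng, {"lo": [-10.0], "hi": [10.0]}, 20, 0.5)
        model = da.lda_fit(X, labels)
        preds = da.predict(model, X)
        assert all(p.predicted == t for p, t in zip(preds, labels))
        # equal priors: the posterior flips at the class-mean midpoint
        mid = model.class_means.mean()
        post = da.predict(model, np.array([[mid]]))[0].posterior
        assert post["lo"] == pytest.approx(0.5, abs=1e-6)

    def test_matches_sklearn_lda(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(1)
        X, labels = _gaussian_classes(
            rng, {"a": [0, 0, 0], "b": [2, 0, 1], "c": [0, 2, -1]}, 15)
        model = da.lda_fit(X, labels)
        preds = [p.predicted for p in da.predict(model, X)]
        post = np.array([[p.posterior[g] for g in model.levels]
                         for p in da.predict(model, X)])
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(X, labels)
        assert preds == list(sk.predict(X))
        order = [list(sk.classes_).index(g) for g in model.levels]
        # sklearn pools with denominator n, we use the classical n−k;
        # posteriors therefore agree only approximately
        np.testing.assert_allclose(post, sk.predict_proba(X)[:, order],
                                   atol=0.05)

    def test_null_labels_give_chance_level_test_accuracy(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 6))
        labels = rng.choice(list("abcde"), size=200).tolist()
        model = da.lda_fit(X, labels)
        X_new = rng.normal(size=(500, 6))
        truth_new = rng.choice(list("abcde"), size=500).tolist()
        preds = [p.predicted for p in da.predict(model, X_new)]
        acc = np.mean([p == t for p, t in zip(preds, truth_new)])
        se = np.sqrt(0.2 * 0.8 / 500)
        assert abs(acc - 0.2) < 4 * se

    def test_affine_invariance_of_predictions(self):
        rng = np.random.default_rng(3)
        X, labels = _gaussian_classes(rng, {"a": [0, 0], "b": [1.5, 1.0]}, 25)
        A = rng.normal(size=(2, 2)) + 2 * np.eye(2)
        b = rng.normal(size=2)
        m1 = da.lda_fit(X, labels)
        m2 = da.lda_fit(X @ A + b, labels)
        p1 = [p.predicted for p in da.predict(m1, X)]
        p2 = [p.predicted for p in da.predict(m2, X @ A + b)]
        assert p1 == p2

    def test_posteriors_sum_to_one_and_prior_monotonicity(self):
        rng = np.random.default_rng(4)
        X, labels = _gaussian_classes(rng, {"a": [0.0], "b": [1.0]}, 20)
        m_even = da.lda_fit(X, labels, priors=np.array([0.5, 0.5]))
        m_tilted = da.lda_fit(X, labels, priors=np.array([0.8, 0.2]))
        p_even = da.predict(m_even, X)
        p_tilted = da.predict(m_tilted, X)
        for pe, pt in zip(p_even, p_tilted):
            assert sum(pe.posterior.values()) == pytest.approx(1.0, abs=1e-10)
            assert pt.posterior["a"] >= pe.posterior["a"] - 1e-12

    def test_accuracy_monotone_in_effect_size(self):
        rng = np.random.default_rng(5)
        accs = []
        base = rng.normal(size=(100, 4))
        labels = (["a"] * 50 + ["b"] * 50)
        for delta in (0.0, 0.5, 1.0, 2.0, 4.0):
            X = base.copy()
            X[50:, 0] += delta
            model = da.lda_fit(X, labels)
            preds = [p.predicted for p in da.predict(model, X)]
            accs.append(np.mean([p == t for p, t in zip(preds, labels)]))
        assert all(a2 >= a1 - 1e-12 for a1, a2 in zip(accs, accs[1:]))

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="b"):
            da.lda_fit(np.zeros((3, 2)), ["a", "a", "b"])


class TestConfusion:
    def test_perfect_predictions_identity_matrix(self):
        labels = ["a", "b", "c", "a"]
        cm = da.confusion(labels, labels)
        assert cm.accuracy == pytest.approx(100.0)
        assert np.trace(cm.counts.to_numpy()) == 4

    def test_accuracy_equals_weighted_row_accuracy(self):
        rng = np.random.default_rng(6)
        truth = rng.choice(list("abc"), size=60).tolist()
        pred = rng.choice(list("abc"), size=60).tolist()
        cm = da.confusion(truth, pred)
        row_acc = np.diag(cm.counts.to_numpy()) / cm.row_n.to_numpy()
        weighted = np.sum(row_acc * cm.row_n.to_numpy()) / cm.row_n.sum()
        assert cm.accuracy == pytest.approx(100 * weighted)

    def test_unseen_label_rejected(self):
        with pytest.raises(ValueError, match="z"):
            da.confusion(["a", "b"], ["a", "z"], levels=["a", "b"])

    def test_row_percentages_sum_to_100(self):
        cm = da.confusion(["a", "a", "b", "b", "b"], ["a", "b", "b", "b", "a"])
        np.testing.assert_allclose(cm.row_percent.sum(axis=1), 100.0)


class TestPfda:
    def _setup(self, n=48, seed=7, delta=3.0):
        rng = np.random.default_rng(seed)
        tree = simulate_tree(n, seed=seed)
        cov = ph.brownian_covariance(tree)
        labels = rng.choice(["u", "v", "w"], size=n).tolist()
        L = np.linalg.cholesky(cov.matrix + 1e-12 * np.eye(n))
        X = L @ rng.normal(size=(n, 4))
        shift = {"u": 0.0, "v": delta, "w": -delta}
        X[:, 0] += [shift[g] for g in labels]
        return X, labels, cov

    def test_lambda_zero_equals_lda_exactly(self):
        X, labels, cov = self._setup()
        lda = da.lda_fit(X, labels)
        pfda = da.pfda_fit(X, labels, cov, lam=0.0)
        p1 = [p.predicted for p in da.predict(lda, X)]
        p2 = [p.predicted for p in da.predict(pfda, X)]
        assert p1 == p2
        np.testing.assert_allclose(pfda.class_means, lda.class_means,
                                   atol=1e-10)
        cm1 = da.confusion(labels, p1, levels=lda.levels)
        cm2 = da.confusion(labels, p2, levels=pfda.levels)
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)

    def test_strong_regime_effect_high_training_accuracy(self):
        X, labels, cov = self._setup(delta=4.0)
        pfda = da.pfda_fit(X, labels, cov, lam=1.0)
        preds = [p.predicted for p in da.predict(pfda, X)]
        acc = np.mean([p == t for p, t in zip(preds, labels)])
        assert acc > 0.9

    def test_proportion_of_trace_sums_to_100(self):
        X, labels, cov = self._setup()
        pfda = da.pfda_fit(X, labels, cov, lam=0.5)
        assert pfda.proportion_of_trace.sum() == pytest.approx(100, abs=1e-6)
        assert pfda.directions.shape[1] == min(X.shape[1], len(pfda.levels) - 1)

    def test_constant_predictors_rejected_for_lambda_search(self):
        n = 20
        cov = PhyloCovariance(tuple(f"t{i}" for i in range(n)), np.eye(n))
        labels = ["a"] * 10 + ["b"] * 10
        with pytest.raises(ValueError, match="constant"):
            da.optimal_lambda(np.ones((n, 2)), labels, cov)

    def test_lambda_recovery_separates_bm_from_iid_data(self):
        """λ̂ distributions under λ=1 (Brownian) vs λ=0 (iid) data must
        separate: each replicate pair is simulated on the same tree."""
        high, low = [], []
        for rep in range(8):
            rng = np.random.default_rng(100 + rep)
            n = 64
            tree = simulate_tree(n, seed=200 + rep)
            cov = ph.brownian_covariance(tree)
            labels = rng.choice(["a", "b"], size=n).tolist()
            L = np.linalg.cholesky(cov.matrix + 1e-12 * np.eye(n))
            X_bm = L @ rng.normal(size=(n, 3))
            X_iid = rng.normal(size=(n, 3))
            high.append(da.optimal_lambda(X_bm, labels, cov)[0])
            low.append(da.optimal_lambda(X_iid, labels, cov)[0])
        assert np.mean(high) > 0.7
        assert np.mean(low) < 0.3


class TestHeldOutPrediction:
    def test_star_tree_duplicate_point_predicted_to_its_class(self):
        n = 20
        tips = [f"t{i}" for i in range(n)] + ["held"]
        star = ph.read_newick(
            "(" + ",".join(f"{t}:1" for t in tips) + ");")
        rng = np.random.default_rng(8)
        labels = ["a"] * 10 + ["b"] * 10
        X = rng.normal(size=(n, 3))
        X[10:] += 5.0
        train_cov = ph.brownian_covariance(
            ph.prune_to_taxa(star, tips[:n]), tip_order=tips[:n])
        full_cov = ph.brownian_covariance(star, tip_order=tips)
        model = da.pfda_fit(X, labels, train_cov, lam=0.0)
        held = da.predict_unlabeled_tips(
            model, X[12][None, :], ["held"], full_cov, X)
        assert held[0].predicted == "b"
        assert held[0].posterior["b"] > 0.99

    def test_empty_held_out_set_is_vacuous(self):
        n = 10
        tips = [f"t{i}" for i in range(n)]
        star = ph.read_newick("(" + ",".join(f"{t}:1" for t in tips) + ");")
        cov = ph.brownian_covariance(star, tip_order=tips)
        rng = np.random.default_rng(9)
        X = rng.normal(size=(n, 2))
        X[5:] += 4
        model = da.pfda_fit(X, ["a"] * 5 + ["b"] * 5, cov, lam=0.0)
        assert da.predict_unlabeled_tips(model, np.empty((0, 2)), [], cov, X) == []

    def test_basal_like_held_out_tips_predicted_basal(self):
        """Held-out tips carrying basal-like trait values are mostly routed
        to the basal class."""
        rng = np.random.default_rng(10)
        n = 60
        tree = simulate_tree(n, seed=11)
        tips = tree.tip_labels
        held = tips[:6]
        train = tips[6:]
        labels = (["basal"] * 12 + ["Hyloidea"] * 21 + ["Ranoidea"] * 21)
        means = {"basal": [-2.0, 0.0], "Hyloidea": [2.0, 2.0],
                 "Ranoidea": [2.0, -2.0]}
        X_train = np.array([rng.normal(means[g], 1.0) for g in labels])
        X_held = rng.normal(means["basal"], 1.0, size=(6, 2))
        train_cov = ph.brownian_covariance(
            ph.prune_to_taxa(tree, train), tip_order=train)
        full_cov = ph.brownian_covariance(tree, tip_order=tips)
        model = da.pfda_fit(X_train, labels, train_cov, lam=0.5)
        preds = da.predict_unlabeled_tips(
            model, X_held, held, full_cov, X_train)
        frac = np.mean([p.predicted == "basal" for p in preds])
        assert frac >= 0.5


class TestCasewiseReport:
    def _pred(self, sid, truth, predicted, alt=None, proxy=False):
        return da.CasewisePrediction(
            species_id=sid, true_label=truth, predicted=predicted,
            posterior={predicted: 1.0},
            correct=(predicted == truth),
            matches_alternative=(predicted == alt) if alt else None,
            proxy_label_used=proxy,
        )

    def test_all_primary_correct_gives_zero_alternatives(self):
        preds = [self._pred(f"s{i}", "a", "a") for i in range(5)]
        rep = da.casewise_report(preds)
        assert rep["primary_correct"] == 5
        assert rep["alternative_correct"] == 0

    def test_planted_counts_match_construction(self):
        preds = [
            self._pred("s1", "a", "a"),                    # primary correct
            self._pred("s2", "a", "b", alt="b"),           # alternative
            self._pred("s3", "a", "b"),                    # certain miss
            self._pred("s4", "a", "a", proxy=True),        # proxy correct
            self._pred("s5", "a", "c", proxy=True),        # proxy miss
        ]
        rep = da.casewise_report(preds)
        assert rep["primary_correct"] == 2
        assert rep["alternative_correct"] == 1
        assert rep["proxy_correct"] == 1
        assert rep["misclassified_certain"] == 1

    def test_identical_sets_agree_fully(self):
        preds = [self._pred(f"s{i}", "a", "a") for i in range(4)]
        rep = da.casewise_report(preds, comparison=preds)
        assert rep["agreement_rate"] == 1.0
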