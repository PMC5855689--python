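"""Normal transform, correlation eigenbasis, and the H/L decision scores."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from drugcombo import (ImprovedNaiveBayes, ImprovedNBClassifier, NormalTransform,
                       WhitenedBasis, choose_threshold, roc_auc)
from drugcombo.model import ImprovedNaiveBayesResults


def blom_scores(col):
    """Independent closed-form oracle: Blom offset 3/8, average ranks."""
    col = np.asarray(col, dtype=float)
    n = len(col)
    order = np.argsort(col, kind="stable")
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    for v in np.unique(col):
        ranks[col == v] = ranks[col == v].mean()
    return norm.ppf((ranks - 0.375) / (n + 0.25))


class TestNormalTransform:
    def test_blom_scores_for_three_values(self):
        Z = NormalTransform().fit_transform(np.array([[5.0], [1.0], [3.0]]))
        expected = norm.ppf((np.array([3, 1, 2]) - 0.375) / 3.25)
        np.testing.assert_allclose(Z[:, 0], expected, atol=1e-12)
        np.testing.assert_allclose(Z[:, 0], [0.8694, -0.8694, 0.0], atol=1e-4)

    def test_rank_invariance(self):
        # a column already equal to its own normal scores maps to itself
        base = np.array([[5.0], [1.0], [3.0], [9.0], [2.0]])
        Z1 = NormalTransform().fit_transform(base)
        Z2 = NormalTransform().fit_transform(Z1)
        np.testing.assert_allclose(Z1, Z2, atol=1e-12)

    def test_matches_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, size=(50, 4)).astype(float)
        Z = NormalTransform().fit_transform(X)
        for j in range(4):
            np.testing.assert_allclose(Z[:, j], blom_scores(X[:, j]), atol=1e-12)

    def test_standardized_marginals(self):
        rng = np.random.default_rng(1)
        Z = NormalTransform().fit_transform(rng.exponential(size=(200, 3)))
        assert np.abs(Z.mean(axis=0)).max() < 0.05
        assert np.abs(Z.std(axis=0) - 1).max() < 0.05

    def test_constant_column_flagged_zero(self):
        t = NormalTransform().fit(np.array([[1.0, 2.0], [1.0, 5.0], [1.0, 3.0]]))
        assert t.constant_[0] and not t.constant_[1]
        assert (t.transform(np.array([[7.0, 3.0]]))[:, 0] == 0).all()

    def test_new_values_interpolate_and_clip(self):
        X = np.array([[0.0], [1.0], [2.0], [4.0]])
        t = NormalTransform().fit(X)
        z = t.transform(np.array([[0.0], [0.5], [3.0], [-5.0], [99.0]]))[:, 0]
        fitted = t.transform(X)[:, 0]
        assert fitted[0] < z[1] < fitted[1]          # strict monotone between knots
        assert fitted[2] < z[2] < fitted[3]
        assert z[3] == fitted[0] and z[4] == fitted[3]  # clipped to extremes
        np.testing.assert_allclose(np.interp(0.5, [0, 1, 2, 4], fitted), z[1])

    def test_too_few_samples_and_column_mismatch(self):
        with pytest.raises(ValueError):
            NormalTransform().fit(np.ones((2, 1)))
        t = NormalTransform().fit(np.random.default_rng(0).random((5, 2)))
        with pytest.raises(ValueError, match="column count"):
            t.transform(np.ones((3, 3)))


class TestWhitenedBasis:
    def test_two_by_two_analytic_eigenstructure(self):
        rng = np.random.default_rng(7)
        A = rng.standard_normal((500, 2))
        Z = np.column_stack([A[:, 0], 0.6 * A[:, 0] + 0.8 * A[:, 1]])
        basis = WhitenedBasis.from_transformed(Z)
        r = np.corrcoef(Z, rowvar=False)[0, 1]
        np.testing.assert_allclose(sorted(basis.lambdas), sorted([1 - r, 1 + r]),
                                   atol=1e-12)
        v = np.abs(basis.P[:, 0])
        np.testing.assert_allclose(v, [np.sqrt(0.5)] * 2, atol=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_trace_and_orthonormality_invariants(self, seed):
        rng = np.random.default_rng(seed)
        n_feat = int(rng.integers(2, 8))
        Z = rng.standard_normal((int(rng.integers(10, 60)), n_feat))
        basis = WhitenedBasis.from_transformed(Z)
        assert basis.lambdas.sum() == pytest.approx(n_feat, abs=1e-8)
        np.testing.assert_allclose(basis.P.T @ basis.P, np.eye(n_feat), atol=1e-8)
        assert (basis.lambdas >= 0).all()
        np.testing.assert_allclose(np.diag(basis.R), 1.0, atol=1e-12)


def _identity_transform(n_features, lo=-50.0, hi=50.0):
    t = NormalTransform()
    t.knots_ = [(np.array([lo, hi]), np.array([lo, hi]))] * n_features
    t.constant_ = np.zeros(n_features, dtype=bool)
    t.n_fitted_ = 2
    return t


def _manual_results(r=0.5):
    """Hand-built 2-feature model: identity transform, standard margins,
    both classes at the origin, correlation r."""
    lam = np.array([1 + r, 1 - r])
    P = np.column_stack([[1, 1], [1, -1]]) / np.sqrt(2)
    basis = WhitenedBasis(R=np.array([[1, r], [r, 1]]), lambdas=lam, P=P)
    ones, zeros = np.ones(2), np.zeros(2)
    return ImprovedNaiveBayesResults(
        transform=_identity_transform(2), basis=basis,
        class_means={0: zeros, 1: zeros}, class_sds={0: ones, 1: ones},
        overall_mean=zeros, overall_sd=ones, priors={0: 0.5, 1: 0.5},
        n_labeled=4, n_unlabeled=0)


class TestScoreEquations:
    def test_hand_computed_projection_and_L(self):
        res = _manual_results(r=0.5)
        sb = res.score_samples(np.array([[1.0, 1.0]]))
        np.testing.assert_allclose(sb.beta[0], [np.sqrt(2), 0.0], atol=1e-12)
        np.testing.assert_allclose(sb.gamma_by_class[1][0], sb.beta[0], atol=1e-12)
        assert sb.L_by_class[1][0] == pytest.approx(0.0, abs=1e-12)

    def test_sample_at_class_mean_maximizes_H(self):
        res = _manual_results()
        res.class_means = {0: np.array([2.0, 2.0]), 1: np.array([-1.0, -1.0])}
        sb = res.score_samples(np.array([[2.0, 2.0]]))
        # gamma_0 = 0, so H_0 = ln P(C0) - sum ln sigma_0 is the ceiling
        np.testing.assert_allclose(sb.gamma_by_class[0][0], 0.0, atol=1e-12)
        assert sb.H_by_class[0][0] == pytest.approx(np.log(0.5))
        assert sb.H_by_class[0][0] > sb.H_by_class[1][0]

    def test_identity_basis_reduces_to_gaussian_naive_bayes(self):
        # with R = I, ranking by H equals the independent-Gaussian
        # log-posterior ranking on every sample
        rng = np.random.default_rng(13)
        for trial in range(20):
            n, d = int(rng.integers(20, 200)), int(rng.integers(2, 6))
            X = rng.standard_normal((n, d)) + rng.normal(0, 2, size=d)
            y = rng.integers(0, 2, size=n)
            if min((y == 0).sum(), (y == 1).sum()) < 2:
                continue
            res = ImprovedNaiveBayes(y, X).fit()
            res.basis = WhitenedBasis(R=np.eye(d), lambdas=np.ones(d), P=np.eye(d))
            Z = res.transform.transform(X)
            # independent oracle: direct Gaussian log-likelihoods from numpy stats
            logpost = []
            for c in (0, 1):
                mu, sd = Z[y == c].mean(axis=0), Z[y == c].std(axis=0)
                ll = norm.logpdf(Z, mu, sd).sum(axis=1) + np.log((y == c).mean())
                logpost.append(ll)
            oracle = (logpost[1] > logpost[0]).astype(int)
            np.testing.assert_array_equal(res.predict(X), oracle)

    def test_feature_permutation_leaves_H_and_L_unchanged(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 3, size=(60, 6))
        y = rng.integers(0, 2, size=60)
        y[:4] = [0, 0, 1, 1]
        res = ImprovedNaiveBayes(y, X).fit()
        perm = rng.permutation(6)
        res_p = ImprovedNaiveBayes(y, X[:, perm]).fit()
        sb, sb_p = res.score_samples(X), res_p.score_samples(X[:, perm])
        for c in (0, 1):
            np.testing.assert_allclose(sb.H_by_class[c], sb_p.H_by_class[c], atol=1e-10)
            np.testing.assert_allclose(sb.L_by_class[c], sb_p.L_by_class[c], atol=1e-10)


class TestFitting:
    def test_pool_shrinks_correlation_error(self):
        # more unlabeled data -> R estimate closer to the population R
        rho = 0.5
        R_pop = np.full((4, 4), rho) + np.eye(4) * (1 - rho)
        C = np.linalg.cholesky(R_pop)
        err_no, err_pool = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            Xl = rng.standard_normal((30, 4)) @ C.T
            Xu = rng.standard_normal((400, 4)) @ C.T
            y = np.tile([0, 1], 15)
            r1 = ImprovedNaiveBayes(y, Xl).fit()
            r2 = ImprovedNaiveBayes(y, Xl, exog_unlabeled=Xu).fit()
            err_no.append(np.linalg.norm(r1.basis.R - R_pop))
            err_pool.append(np.linalg.norm(r2.basis.R - R_pop))
        assert np.mean(err_pool) < np.mean(err_no)

    def test_parameter_recovery_rmse_halves_when_n_quadruples(self):
        # class means in the transformed scale converge to their population
        # values (estimated once at very large n) at the root-n rate
        mu_true = {0: np.array([0.0, 0.0, 0.0]), 1: np.array([1.0, 0.5, -0.5])}

        def sample(n, rng):
            y = np.tile([0, 1], n // 2)
            X = np.vstack([rng.normal(mu_true[c], 1.0) for c in y])
            return X, y

        X_big, y_big = sample(40000, np.random.default_rng(999))
        ref = ImprovedNaiveBayes(y_big, X_big).fit()
        ref_means = ref.class_means
        rmse = {}
        for n in (100, 400):
            errs = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                X, y = sample(n, rng)
                res = ImprovedNaiveBayes(y, X).fit()
                for c in (0, 1):
                    errs.append(np.mean((res.class_means[c] - ref_means[c]) ** 2))
            rmse[n] = np.sqrt(np.mean(errs))
        assert rmse[400] < rmse[100]
        assert rmse[400] / rmse[100] == pytest.approx(0.5, abs=0.2)

    def test_class_with_one_sample_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            ImprovedNaiveBayes(np.array([0, 1, 1]), np.eye(3))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ImprovedNaiveBayes(np.array([]), np.empty((0, 2)))

    def test_json_round_trip_reproduces_scores(self):
        rng = np.random.default_rng(8)
        X = rng.integers(0, 3, size=(40, 5))
        y = np.tile([0, 1], 20)
        res = ImprovedNaiveBayes(y, X, exog_unlabeled=rng.integers(0, 3, (30, 5))).fit()
        back = ImprovedNaiveBayesResults.from_json(res.to_json())
        Xn = rng.integers(0, 3, size=(10, 5))
        for c in (0, 1):
            np.testing.assert_allclose(back.score_samples(Xn).H_by_class[c],
                                       res.score_samples(Xn).H_by_class[c], atol=1e-12)
        np.testing.assert_allclose(back.decision_scores(Xn), res.decision_scores(Xn),
                                   atol=1e-12)

    def test_summary_mentions_fit_dimensions(self):
        rng = np.random.default_rng(8)
        res = ImprovedNaiveBayes(np.tile([0, 1], 10),
                                 rng.integers(0, 2, (20, 3))).fit()
        text = res.summary()
        assert "20" in text and "3" in text and "P(C1)" in text


class TestPrediction:
    def test_equal_priors_pick_nearest_class_mean(self):
        res = _manual_results()
        res.class_means = {0: np.array([-1.0, -1.0]), 1: np.array([1.0, 1.0])}
        pred = res.predict(np.array([[1.0, 1.0], [-1.0, -1.0]]))
        np.testing.assert_array_equal(pred, [1, 0])

    def test_exact_tie_goes_to_non_effective(self):
        res = _manual_results()  # both classes identical -> H ties everywhere
        pred = res.predict(np.array([[0.3, -0.2]]))
        assert pred[0] == 0

    def test_extreme_prior_dominates(self):
        res = _manual_results()
        res.class_means = {0: np.array([-1.0, -1.0]), 1: np.array([1.0, 1.0])}
        res.priors = {0: 1 - 1e-12, 1: 1e-12}
        # even samples at class 1's mean flip to the overwhelming prior
        assert res.predict(np.array([[1.0, 1.0]]))[0] == 0


class TestThreshold:
    def test_separated_scores_give_perfect_operating_point(self):
        L = np.array([-3.0, -2.0, -1.0, 1.0, 2.0, 3.0])
        is_pos = L > 0
        t = choose_threshold(L, is_pos)
        assert ((L >= t) == is_pos).all()

    def test_translation_equivariance(self):
        rng = np.random.default_rng(4)
        L = rng.standard_normal(50)
        is_pos = rng.random(50) < 0.5
        is_pos[:2] = [True, False]
        t = choose_threshold(L, is_pos)
        assert choose_threshold(L + 7.5, is_pos) == pytest.approx(t + 7.5)

    def test_label_independent_scores_give_chance_auc(self):
        aucs = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            L = rng.standard_normal(100)
            y = rng.integers(0, 2, size=100)
            y[:2] = [0, 1]
            aucs.append(roc_auc(L, y).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_predict_by_threshold_uses_calibration(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(-1, 1, (40, 3)), rng.normal(1, 1, (40, 3))])
        y = np.repeat([0, 1], 40)
        res = ImprovedNaiveBayes(y, X).fit()
        labels, L = res.predict_by_threshold(X, calibration=(X, y))
        assert len(labels) == len(L) == 80
        assert (labels[y == 1] == 1).mean() > 0.7

    def test_single_class_calibration_rejected(self):
        with pytest.raises(ValueError):
            choose_threshold(np.array([1.0, 2.0]), np.array([True, True]))


class TestClassifierAdapter:
    def test_in_fold_selection_and_scores(self, small_study):
        ds = small_study.dataset
        clf = ImprovedNBClassifier(selector="ellipse", n_features=8,
                                   unlabeled=ds.X_unlabeled)
        clf.fit(ds.X_labeled, ds.y_labeled)
        assert len(clf.selected_) == 8
        assert clf.decision_function(ds.X_labeled).shape == (100,)
        acc = (clf.predict(ds.X_labeled) == ds.y_labeled).mean()
        assert acc > 0.6
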