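"""PLS-DA core: dummy coding, NIPALS decomposition, LDA on predictions."""

import numpy as np
import pandas as pd
import pytest

from aminofrail import PLSDiscriminantAnalysis, encode_classes
from aminofrail.plsda import (
    PLSDAError,
    PLSModel,
    classify,
    fit_canonical_discriminant,
    fit_pls,
    predict_response,
    truncate_pls,
)


def centered(X):
    return X - X.mean(axis=0)


class TestEncodeClasses:
    def test_three_class_rows(self):
        order = ("controls", "PF&S", "F-T2DM")
        dummy = encode_classes(["controls", "PF&S", "F-T2DM"], order)
        np.testing.assert_array_equal(
            dummy.Y, [[1, 0, 0], [0, 1, 0], [0, 0, 1]]
        )

    def test_two_class_single_column(self):
        dummy = encode_classes(["PF&S", "F-T2DM"], ("PF&S", "F-T2DM"))
        np.testing.assert_array_equal(dummy.Y, [[1.0], [0.0]])

    def test_constant_labels(self):
        dummy = encode_classes(["A", "A", "A"], ("A", "B"))
        np.testing.assert_array_equal(dummy.Y, [[1.0], [1.0], [1.0]])

    def test_unknown_label_named_in_error(self):
        with pytest.raises(PLSDAError, match="'C'"):
            encode_classes(["A", "C"], ("A", "B"))


class TestFitPLS:
    def test_single_informative_predictor_reproduces_response(self):
        rng = np.random.default_rng(0)
        y = np.repeat([1.0, 0.0], 10)
        X = centered(np.column_stack([2.0 * y + 1.0]))
        model = fit_pls(X, y - 0, 1)
        pred = predict_response(model, X)[:, 0]
        np.testing.assert_allclose(pred, y, atol=1e-8)

    def test_full_rank_equals_least_squares_oracle(self):
        # PLS at full rank coincides with OLS; oracle = normal equations
        rng = np.random.default_rng(42)
        for _ in range(100):
            n, p = 8, 3
            X = centered(rng.standard_normal((n, p)))
            labels = np.array(["A"] * 4 + ["B"] * 4)
            Y = encode_classes(labels, ("A", "B"))
            model = fit_pls(X, Y, p)
            pred = predict_response(model, X)
            Yc = Y.Y - Y.Y.mean(axis=0)
            beta = np.linalg.lstsq(X, Yc, rcond=None)[0]
            ols = Y.Y.mean(axis=0) + X @ beta
            np.testing.assert_allclose(pred, ols, atol=1e-8)

    def test_response_orthogonal_to_predictors_gives_mean_model(self):
        rng = np.random.default_rng(1)
        y = np.repeat([1.0, 0.0], 8)
        yc = y - y.mean()
        X = rng.standard_normal((16, 3))
        X = centered(X)
        # remove any covariance with the response
        X = X - np.outer(yc, yc @ X) / (yc @ yc)
        model = fit_pls(X, y[:, None], 2)
        assert model.n_lv == 0
        np.testing.assert_allclose(model.q, 0, atol=1e-10)
        pred = predict_response(model, X)
        np.testing.assert_allclose(pred, y.mean(), atol=1e-8)

    def test_scores_identity_and_orthogonality(self, replica_matrix):
        X, labels = replica_matrix
        res = PLSDiscriminantAnalysis(
            X, labels, class_order=("controls", "PF&S", "F-T2DM")
        ).fit(8)
        T, R = res.pls.T, res.pls.R
        Xs = res.model._Xs
        np.testing.assert_allclose(T, Xs @ R, atol=1e-8)
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_truncation_matches_fresh_fit(self, replica_matrix):
        X, labels = replica_matrix
        m = PLSDiscriminantAnalysis(X, labels).fit(6)
        fresh = PLSDiscriminantAnalysis(X, labels).fit(3)
        trunc = truncate_pls(m.pls, 3)
        np.testing.assert_allclose(trunc.T, fresh.pls.T, atol=1e-8)
        np.testing.assert_allclose(trunc.q, fresh.pls.q, atol=1e-8)

    def test_excessive_n_lv_rejected(self):
        X = centered(np.random.default_rng(0).standard_normal((6, 3)))
        y = np.array([1.0, 0, 1, 0, 1, 0])[:, None]
        with pytest.raises(PLSDAError, match="n_lv"):
            fit_pls(X, y, 4)

    def test_training_response_rss_non_increasing_in_n_lv(self, replica_matrix):
        # nesting: extra latent variables can only reduce the training
        # least-squares residual of the dummy response
        X, labels = replica_matrix
        model = PLSDiscriminantAnalysis(X, labels)
        Y = encode_classes(model.labels, model.class_order).Y
        prev = np.inf
        for a in range(1, 9):
            res = model.fit(a)
            rss = float(np.sum((res.fittedvalues - Y) ** 2))
            assert rss <= prev + 1e-10
            prev = rss


class TestPredictResponse:
    def test_fitted_values_consistent(self, replica_matrix):
        X, labels = replica_matrix
        res = PLSDiscriminantAnalysis(X, labels).fit(4)
        np.testing.assert_allclose(
            res.predict_response(X), res.fittedvalues, atol=1e-10
        )

    def test_zero_row_returns_intercept(self):
        rng = np.random.default_rng(3)
        X = centered(rng.standard_normal((10, 4)))
        labels = np.array(["A"] * 6 + ["B"] * 4)
        Y = encode_classes(labels, ("A", "B"))
        model = fit_pls(X, Y, 2)
        pred = predict_response(model, np.zeros((1, 4)))
        np.testing.assert_allclose(pred[0], Y.Y.mean(axis=0), atol=1e-12)

    def test_hand_set_model_product(self):
        R = np.array([[2.0], [1.0]])
        q = np.array([[3.0, -1.0]])
        model = PLSModel(R=R, T=np.zeros((1, 1)), P=R, W=R, q=q,
                         y_mean=np.array([0.5, 0.5]), n_lv=1)
        pred = predict_response(model, np.array([[1.0, 2.0]]))
        # score = 1*2 + 2*1 = 4; response = 0.5 + 4*(3, -1)
        np.testing.assert_allclose(pred, [[12.5, -3.5]])

    def test_column_mismatch_rejected(self, replica_matrix):
        X, labels = replica_matrix
        res = PLSDiscriminantAnalysis(X, labels).fit(2)
        with pytest.raises(PLSDAError, match="columns"):
            predict_response(res.pls, np.zeros((1, 5)))


class TestCanonicalDiscriminant:
    def test_three_classes_two_canonical_variates(self, replica_matrix):
        X, labels = replica_matrix
        res = PLSDiscriminantAnalysis(X, labels).fit(5)
        assert res.projection.n_cv == 2
        assert res.cv_weights.shape == (X.shape[1], 2)

    def test_two_classes_one_canonical_variate(self, replica_matrix):
        X, labels = replica_matrix
        mask = labels.isin(["PF&S", "F-T2DM"]).to_numpy()
        res = PLSDiscriminantAnalysis(
            X[mask], labels[mask], class_order=("PF&S", "F-T2DM")
        ).fit(4)
        assert res.projection.n_cv == 1

    def test_separated_1d_clouds_midpoint_boundary(self):
        # equal priors, equal variance: decision point = midpoint of means
        pred = np.array([0.0, 0.2, -0.2, 2.0, 1.8, 2.2])[:, None]
        labels = ["lo"] * 3 + ["hi"] * 3
        proj = fit_canonical_discriminant(pred, labels, ("lo", "hi"),
                                          priors="equal")
        scores = proj.discriminant_scores(np.array([[1.0 - 1e-6],
                                                    [1.0 + 1e-6]]))
        assert scores[0, 0] > scores[0, 1]   # just below midpoint -> lo
        assert scores[1, 1] > scores[1, 0]   # just above midpoint -> hi

    def test_tie_broken_by_class_order_precedence(self):
        pred = np.array([-1.0, -1.2, -0.8, 1.0, 1.2, 0.8])[:, None]
        labels = ["A"] * 3 + ["B"] * 3
        proj = fit_canonical_discriminant(pred, labels, ("A", "B"),
                                          priors="equal")
        model = PLSModel(R=np.eye(1), T=np.zeros((1, 1)), P=np.eye(1),
                         W=np.eye(1), q=np.eye(1), y_mean=np.zeros(1), n_lv=1)
        # the midpoint (0) is exactly equidistant from both class means
        assert classify(model, proj, np.array([[0.0]]))[0] == "A"
        proj_rev = fit_canonical_discriminant(pred, labels, ("B", "A"),
                                              priors="equal")
        assert classify(model, proj_rev, np.array([[0.0]]))[0] == "B"

    def test_agrees_with_reference_lda_on_predictions(self):
        # independent oracle: scikit-learn LDA fitted on the same predicted
        # responses must classify every sample identically
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(9)
        pred = np.vstack([
            rng.multivariate_normal([0, 0], [[1.0, 0.3], [0.3, 1.0]], 20),
            rng.multivariate_normal([1.5, 1.0], [[1.0, 0.3], [0.3, 1.0]], 20),
        ])
        labels = np.array(["A"] * 20 + ["B"] * 20)
        proj = fit_canonical_discriminant(pred, labels, ("A", "B"))
        ours = np.array([
            ("A", "B")[j] for j in
            np.argmax(proj.discriminant_scores(pred), axis=1)
        ])
        ref = LinearDiscriminantAnalysis().fit(pred, labels)
        np.testing.assert_array_equal(ours, ref.predict(pred))

    def test_ridge_warning_on_singular_scatter(self):
        # zero within-class variance along the span of the predictions
        pred = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        labels = ["A", "A", "B", "B"]
        with pytest.warns(UserWarning, match="singular within-class"):
            fit_canonical_discriminant(pred, labels, ("A", "B"))


class TestClassify:
    def test_training_rows_of_separable_fixture_all_correct(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.1, (10, 3)),
                       rng.normal(5, 0.1, (10, 3))])
        labels = ["A"] * 10 + ["B"] * 10
        res = PLSDiscriminantAnalysis(X, labels).fit(2)
        np.testing.assert_array_equal(res.classify(X), labels)

    def test_class_order_permutation_invariance(self, replica_matrix):
        X, labels = replica_matrix
        p1 = PLSDiscriminantAnalysis(
            X, labels, class_order=("controls", "PF&S", "F-T2DM")
        ).fit(5).classify(X)
        p2 = PLSDiscriminantAnalysis(
            X, labels, class_order=("F-T2DM", "controls", "PF&S")
        ).fit(5).classify(X)
        np.testing.assert_array_equal(p1, p2)

    def test_cv_weights_unit_norm_sign_convention(self, replica_matrix):
        X, labels = replica_matrix
        res = PLSDiscriminantAnalysis(X, labels).fit(5)
        W = res.cv_weights
        np.testing.assert_allclose(np.linalg.norm(W, axis=0), 1.0, atol=1e-10)
        for j in range(W.shape[1]):
            assert W[np.argmax(np.abs(W[:, j])), j] > 0
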