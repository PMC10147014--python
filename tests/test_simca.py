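"""SIMCA one-class models: combined distance, acceptance, figures of merit."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aminofrail import fit_simca, simca_evaluate
from aminofrail.simca import (
    SIMCAClassModel,
    SIMCAError,
    accept,
    distance_to_model,
    reduced_statistics,
    select_components_cv,
)


def hand_model(t2_p95=2.0, q_p95=9.0, p=3):
    """Single-component model with identity scaling: loadings = e1,
    unit score variance."""
    loadings = np.zeros((p, 1))
    loadings[0, 0] = 1.0
    return SIMCAClassModel(
        class_name="c", center=np.zeros(p), scale=np.ones(p),
        loadings=loadings, score_var=np.ones(1), n_components=1,
        t2_p95=t2_p95, q_p95=q_p95,
    )


class TestFitSimca:
    def test_rows_in_plane_have_zero_residual(self):
        rng = np.random.default_rng(0)
        scores = rng.standard_normal((12, 2))
        basis = np.linalg.qr(rng.standard_normal((4, 2)))[0]
        X = 5.0 + scores @ basis.T          # exactly rank 2 after centering
        model = fit_simca(X, 2, scale=False)
        np.testing.assert_allclose(model.train_q, 0, atol=1e-18)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        model = fit_simca(rng.standard_normal((30, 6)), 3)
        np.testing.assert_allclose(
            model.loadings.T @ model.loadings, np.eye(3), atol=1e-8
        )

    def test_t2_percentile_approximates_chi2_at_large_n(self):
        # isotropic Gaussian: T2 with estimated score variances is
        # asymptotically chi-squared with n_components dof
        rng = np.random.default_rng(2)
        model = fit_simca(rng.standard_normal((5000, 6)), 3)
        expected = stats.chi2.ppf(0.95, df=3)
        assert model.t2_p95 == pytest.approx(expected, rel=0.05)

    def test_about_five_percent_exceed_each_percentile(self):
        rng = np.random.default_rng(3)
        model = fit_simca(rng.standard_normal((2000, 5)), 2)
        assert 0.03 < np.mean(model.train_t2 > model.t2_p95) < 0.07
        assert 0.03 < np.mean(model.train_q > model.q_p95) < 0.07

    def test_reconstruction_error_non_increasing_in_components(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 8))
        prev = np.inf
        for a in range(1, 7):
            q_mean = fit_simca(X, a).train_q.mean()
            assert q_mean <= prev + 1e-10
            prev = q_mean

    def test_too_few_rows_rejected(self):
        with pytest.raises(SIMCAError, match="rows"):
            fit_simca(np.random.default_rng(0).standard_normal((4, 5)), 3)

    def test_components_beyond_rank_rejected(self):
        rng = np.random.default_rng(5)
        scores = rng.standard_normal((12, 2))
        basis = np.linalg.qr(rng.standard_normal((5, 2)))[0]
        X = scores @ basis.T
        with pytest.raises(SIMCAError, match="rank"):
            fit_simca(X, 4, scale=False)


class TestDistance:
    def test_center_in_span_has_zero_distance(self):
        rng = np.random.default_rng(6)
        X = np.exp(rng.normal(3.0, 0.3, size=(25, 4)))
        model = fit_simca(X, 2)
        d = distance_to_model(model, model.center[None, :])
        assert d[0] == pytest.approx(0.0, abs=1e-10)

    def test_unit_normalized_statistics_give_sqrt2(self):
        model = hand_model(t2_p95=4.0, q_p95=9.0)
        # x = (2, 3, 0): score 2 -> T2 = 4 = t2_p95; residual (0,3,0) -> Q = 9
        d = distance_to_model(model, np.array([[2.0, 3.0, 0.0]]))
        assert d[0] == pytest.approx(np.sqrt(2.0))

    def test_matches_brute_force_oracle(self):
        # independent step-by-step recomputation on a hand-set 5-variable
        # model: scale, project, residual, normalize, combine
        rng = np.random.default_rng(7)
        loadings = np.linalg.qr(rng.standard_normal((5, 2)))[0]
        model = SIMCAClassModel(
            class_name="c",
            center=rng.uniform(1, 5, 5),
            scale=rng.uniform(0.5, 2.0, 5),
            loadings=loadings,
            score_var=np.array([4.0, 1.5]),
            n_components=2,
            t2_p95=3.0,
            q_p95=0.8,
        )
        x = rng.uniform(0, 8, 5)
        z = (x - model.center) / model.scale
        t = loadings.T @ z
        t2 = t[0] ** 2 / 4.0 + t[1] ** 2 / 1.5
        resid = z - loadings @ t
        q = resid @ resid
        expected = np.sqrt((t2 / 3.0) ** 2 + (q / 0.8) ** 2)
        assert distance_to_model(model, x[None, :])[0] == pytest.approx(
            expected, abs=1e-12
        )

    def test_distance_decreases_when_normalizers_grow(self):
        x = np.array([[2.0, 3.0, 1.0]])
        d_small = distance_to_model(hand_model(2.0, 4.0), x)[0]
        d_large = distance_to_model(hand_model(4.0, 8.0), x)[0]
        assert d_large < d_small

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(SIMCAError, match="variables"):
            distance_to_model(hand_model(), np.ones((1, 5)))


class TestAccept:
    def test_zero_distance_accepted(self):
        model = hand_model()
        assert accept(model, np.zeros((1, 3)))[0]

    def test_exact_threshold_rejected(self):
        # x = (2, 0, 0) with t2_p95 = 2: T2 = 4, reduced exactly 2, Q = 0
        model = hand_model(t2_p95=2.0, q_p95=1.0)
        x = np.array([[2.0, 0.0, 0.0]])
        assert distance_to_model(model, x)[0] == 2.0
        assert not accept(model, x)[0]

    def test_just_inside_threshold_accepted(self):
        model = hand_model(t2_p95=2.0, q_p95=1.0)
        x = np.array([[1.99, 0.0, 0.0]])
        assert distance_to_model(model, x)[0] < 2.0
        assert accept(model, x)[0]


class TestEvaluate:
    @staticmethod
    def _three_separated_classes(seed=8, effect=3.0):
        rng = np.random.default_rng(seed)
        n, p = 30, 6
        base = np.log(40.0)
        X, labels = [], []
        for j, c in enumerate(("A", "B", "C")):
            mu = np.full(p, base)
            mu[2 * j: 2 * j + 2] += effect
            X.append(np.exp(mu + 0.35 * rng.standard_normal((n, p))))
            labels += [c] * n
        return np.vstack(X), np.array(labels)

    def test_accept_everything_degenerate_report(self):
        X, labels = self._three_separated_classes()
        models = {c: fit_simca(X[labels == c], 2, class_name=c)
                  for c in ("A", "B", "C")}
        report = simca_evaluate(models, X, labels, threshold=np.inf)
        for c in ("A", "B", "C"):
            assert report.sensitivity[c] == 100.0
            assert report.overall_specificity[c] == 0.0

    def test_well_separated_classes_recognized(self):
        X, labels = self._three_separated_classes()
        models = {c: fit_simca(X[labels == c], 2, class_name=c)
                  for c in ("A", "B", "C")}
        report = simca_evaluate(models, X, labels)
        for c in ("A", "B", "C"):
            assert report.sensitivity[c] >= 80.0
            for other, sp in report.specificity[c].items():
                assert sp >= 90.0

    def test_overall_specificity_is_weighted_mean(self, replica_matrix):
        X, labels = replica_matrix
        classes = ("controls", "PF&S", "F-T2DM")
        models = {c: fit_simca(X[(labels == c).to_numpy()], 3, class_name=c)
                  for c in classes}
        report = simca_evaluate(models, X, labels)
        for c in classes:
            others = [o for o in classes if o != c]
            weights = np.array([report.n_by_class[o] for o in others])
            pairwise = np.array([report.specificity[c][o] for o in others])
            expected = (weights * pairwise).sum() / weights.sum()
            assert report.overall_specificity[c] == pytest.approx(expected)

    def test_missing_model_rejected(self):
        X, labels = self._three_separated_classes()
        models = {"A": fit_simca(X[labels == "A"], 2)}
        with pytest.raises(SIMCAError, match="no model"):
            simca_evaluate(models, X, labels)


class TestComponentSelection:
    def test_selection_deterministic_and_in_range(self, replica_matrix):
        X, labels = replica_matrix
        a1 = select_components_cv(X, labels, "F-T2DM", max_components=6,
                                  seed=3)
        a2 = select_components_cv(X, labels, "F-T2DM", max_components=6,
                                  seed=3)
        assert a1 == a2
        assert 1 <= a1 <= 6
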