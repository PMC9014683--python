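import numpy as np
import pytest

from rosie.io_prep import ClassLabels
from rosie.sprm import (
    SprmConfig,
    fit_sprm,
    predict_sprm,
    sprm_outlier_scores,
)

from conftest import make_matrix


@pytest.fixture
def contaminated(two_class_separable):
    """Separable fixture with one sample shifted by +10 robust SDs on
    every feature."""
    X, y = two_class_separable
    vals = X.values.copy()
    mad = 1.4826 * np.median(np.abs(vals - np.median(vals, axis=0)), axis=0)
    vals[5] += 10 * mad
    return make_matrix(vals), y


class TestFit:
    def test_clean_fixture_selects_signal_feature(self, two_class_separable):
        X, y = two_class_separable
        model = fit_sprm(X, y, SprmConfig(n_components=1, eta=0.8))
        assert "F000" in model.selected_features
        # no clean sample is severely downweighted (Fair weights keep the
        # bulk of the mass; the product of residual and leverage factors
        # puts the typical clean weight near 0.5)
        assert model.case_weights.min() > 0.1
        assert np.median(model.case_weights) > 0.4

    def test_plain_pls_oracle(self, two_class_separable):
        """eta=0 with constant case weights reduces to ordinary PLS1 on
        the robustly standardized data and encoded response."""
        from sklearn.cross_decomposition import PLSRegression

        X, y = two_class_separable
        cfg = SprmConfig(n_components=2, eta=0.0, weight_function="unit")
        model = fit_sprm(X, y, cfg)

        Z = (X.values - model.center_) / model.scale_
        n1 = y.y.sum()
        v = np.where(y.y == 1, (len(y.y) - n1) / len(y.y), -n1 / len(y.y))
        pls = PLSRegression(n_components=2, scale=False).fit(Z, v)
        np.testing.assert_allclose(
            model.coefficients, np.ravel(pls.coef_), atol=1e-6
        )

    def test_gross_outlier_gets_minimum_case_weight(self, contaminated):
        X, y = contaminated
        model = fit_sprm(X, y, SprmConfig(n_components=1, eta=0.5))
        assert model.case_weights.argmin() == 5

    def test_requires_both_classes(self, two_class_separable):
        X, _ = two_class_separable
        with pytest.raises(ValueError, match="both classes"):
            fit_sprm(X, ClassLabels(np.zeros(40, dtype=int)))

    def test_too_many_components(self, two_class_separable):
        X, y = two_class_separable
        with pytest.raises(ValueError, match="n_components"):
            fit_sprm(X, y, SprmConfig(n_components=11))


class TestPredict:
    def test_training_data_classified_perfectly(self, two_class_separable):
        X, y = two_class_separable
        model = fit_sprm(X, y, SprmConfig(n_components=1, eta=0.5))
        assert (predict_sprm(model, X) == y.y).all()

    def test_midpoint_tie_goes_to_class_zero(self, two_class_separable):
        """A point exactly equidistant from both class centroids gets
        class 0 (documented tie rule); exact arithmetic by construction."""
        X, y = two_class_separable
        model = fit_sprm(X, y, SprmConfig(n_components=1, eta=0.5))
        model.center_ = np.zeros(X.n_features)
        model.scale_ = np.ones(X.n_features)
        model.rotation_ = np.eye(X.n_features, 1)
        model.score_center_ = np.zeros(1)
        model.class_centroids_ = np.array([[-1.0], [1.0]])
        mid = make_matrix(np.zeros((1, X.n_features)))
        assert predict_sprm(model, mid)[0] == 0

    def test_single_sample_predict(self, two_class_separable):
        X, y = two_class_separable
        model = fit_sprm(X, y, SprmConfig(n_components=1, eta=0.5))
        one = make_matrix(X.values[:1])
        assert predict_sprm(model, one).shape == (1,)

    def test_feature_mismatch_errors(self, two_class_separable):
        X, y = two_class_separable
        model = fit_sprm(X, y, SprmConfig(n_components=1))
        other = make_matrix(X.values, feature_prefix="G")
        with pytest.raises(ValueError, match="feature ids"):
            predict_sprm(model, other)


class TestOutlierScores:
    def test_scores_are_one_minus_weights(self, two_class_separable):
        X, y = two_class_separable
        model = fit_sprm(X, y, SprmConfig(n_components=1))
        np.testing.assert_allclose(
            sprm_outlier_scores(model), 1.0 - model.case_weights
        )

    def test_contaminated_sample_has_max_score(self, contaminated):
        X, y = contaminated
        model = fit_sprm(X, y, SprmConfig(n_components=1, eta=0.5))
        assert sprm_outlier_scores(model).argmax() == 5


class TestProperties:
    def test_sparsity_non_increasing_in_eta(self, two_class_separable):
        X, y = two_class_separable
        counts = []
        for eta in (0.0, 0.5, 0.9):
            model = fit_sprm(X, y, SprmConfig(n_components=1, eta=eta))
            counts.append(len(model.selected_features))
        assert counts[0] >= counts[1] >= counts[2]

    def test_scale_equivariance_of_predictions(self, two_class_separable):
        X, y = two_class_separable
        cfg = SprmConfig(n_components=1, eta=0.5)
        base = predict_sprm(fit_sprm(X, y, cfg), X)
        Xs = make_matrix(X.values * 7.5)
        scaled = predict_sprm(fit_sprm(Xs, y, cfg), Xs)
        np.testing.assert_array_equal(base, scaled)

    def test_m_weighting_limits_outlier_influence(self, two_class_separable):
        """Adding one gross outlier rotates the coefficient vector less
        under M-weighting than under constant weights."""
        X, y = two_class_separable
        vals = X.values.copy()
        vals[3] += 50.0
        Xc = make_matrix(vals)

        def angle(cfg):
            b_clean = fit_sprm(X, y, cfg).coefficients
            b_cont = fit_sprm(Xc, y, cfg).coefficients
            cosine = b_clean @ b_cont / (
                np.linalg.norm(b_clean) * np.linalg.norm(b_cont)
            )
            return np.arccos(np.clip(cosine, -1, 1))

        robust = angle(SprmConfig(n_components=1, eta=0.0))
        naive = angle(
            SprmConfig(n_components=1, eta=0.0, weight_function="unit")
        )
        assert robust < naive
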