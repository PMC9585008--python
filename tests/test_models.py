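"""Feature extraction, logistic regression, and the convolutional classifier."""

import numpy as np
import pandas as pd
import pytest

from oliguard.models import (
    ConvNetSpec,
    FEATURE_NAMES,
    LogisticWindowClassifier,
    ParallelConv1DClassifier,
    extract_features,
    feature_matrix,
    load_model,
    save_model,
)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class TestFeatures:
    def test_constant_window(self):
        f = dict(zip(FEATURE_NAMES, extract_features(np.full(12, 1.0), 0.9, 1.1, "60-69", "male")))
        assert f["uo_min"] == f["uo_max"] == f["uo_mean"] == f["uo_last"] == 1.0
        assert f["uo_slope"] == 0.0
        assert f["hours_below_0.5"] == 0 and f["sex_male"] == 1.0

    def test_exact_linear_slope(self):
        w = np.linspace(1.2, 0.1, 12)  # step -0.1 per hour
        f = dict(zip(FEATURE_NAMES, extract_features(w, 1.0, 1.0, "18-39", "female")))
        assert f["uo_slope"] == pytest.approx(-0.1)

    def test_all_zero_window(self):
        f = dict(zip(FEATURE_NAMES, extract_features(np.zeros(12), 1.0, 1.0, 0, "male")))
        assert f["hours_below_0.3"] == 12 and f["hours_below_0.5"] == 12

    def test_missing_covariate_rejected(self):
        with pytest.raises(ValueError, match="covariate"):
            extract_features(np.ones(12), np.nan, 1.0, 0, "male")

    def test_matrix_matches_scalar_path(self, rng):
        rows = []
        for i in range(20):
            rows.append(
                {
                    **{f"uo_h{j + 1}": v for j, v in enumerate(rng.uniform(0, 2, 12))},
                    "age_group": "70-79",
                    "sex": "female",
                    "scr_now": rng.uniform(0.5, 2),
                    "scr_ratio": rng.uniform(0.8, 3),
                }
            )
        df = pd.DataFrame(rows)
        M = feature_matrix(df)
        for i in range(20):
            w = df.iloc[i][[f"uo_h{j + 1}" for j in range(12)]].to_numpy(float)
            np.testing.assert_allclose(
                M[i],
                extract_features(w, df.scr_now[i], df.scr_ratio[i], "70-79", "female"),
            )


class TestLogistic:
    def test_null_data_gives_flat_coefficients_and_prevalence_intercept(self, rng):
        n = 40_000
        X = rng.normal(size=(n, 3))
        y = (rng.random(n) < 0.25).astype(int)
        m = LogisticWindowClassifier().fit(X, y)
        assert np.all(np.abs(m.coef_) < 0.05)
        assert m.intercept_ == pytest.approx(np.log(0.25 / 0.75), abs=0.08)

    def test_duplicated_dataset_leaves_fit_unchanged(self, rng):
        X = rng.normal(size=(300, 4))
        y = (X[:, 0] + rng.normal(size=300) > 0).astype(int)
        m1 = LogisticWindowClassifier().fit(X, y)
        m2 = LogisticWindowClassifier().fit(np.vstack([X, X]), np.concatenate([y, y]))
        np.testing.assert_allclose(m1.coef_, m2.coef_, atol=1e-4)

    def test_training_means_map_to_sigmoid_intercept(self, rng):
        X = rng.normal(2.0, 1.5, size=(500, 3))
        y = (X[:, 0] > 2.0).astype(int)
        y[rng.random(500) < 0.2] ^= 1  # keep it non-separable
        m = LogisticWindowClassifier().fit(X, y)
        p = m.predict_proba(X.mean(axis=0, keepdims=True))[0, 1]
        assert p == pytest.approx(_sigmoid(m.intercept_), abs=1e-9)

    def test_zero_score_gives_half(self, rng):
        X = rng.normal(size=(200, 2))
        y = (rng.random(200) < 0.5).astype(int)
        m = LogisticWindowClassifier().fit(X, y)
        z = m.decision_function(X)
        i = np.argmin(np.abs(z))
        assert m.predict_proba(X[i : i + 1])[0, 1] == pytest.approx(_sigmoid(z[i]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            LogisticWindowClassifier().fit(np.zeros((10, 2)), np.zeros(10))

    def test_perfect_separation_falls_back_with_warning(self):
        X = np.concatenate([np.full(50, -1.0), np.full(50, 1.0)])[:, None]
        y = (X[:, 0] > 0).astype(int)
        with pytest.warns(UserWarning, match="separation"):
            m = LogisticWindowClassifier().fit(X, y)
        assert np.isfinite(m.coef_).all()


def _toy_windows(rng, n_pos=150, n_neg=600):
    """Separable toy set: positives decline toward oliguria, negatives flat."""
    neg = rng.normal(1.4, 0.25, size=(n_neg, 12))
    ramp = np.linspace(1.2, 0.3, 12)
    pos = ramp + rng.normal(0, 0.2, size=(n_pos, 12))
    X = np.vstack([neg, pos])
    y = np.concatenate([np.zeros(n_neg), np.ones(n_pos)]).astype(int)
    return X, y


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.Generator(np.random.PCG64(5))
    X, y = _toy_windows(rng)
    spec = ConvNetSpec(epochs=25, seed=3)
    return ParallelConv1DClassifier(spec).fit(X, y), X, y


class TestConvNet:

    def test_separable_signal_learned(self, fitted):
        model, X, y = fitted
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(y, model.score_windows(X)) > 0.95

    def test_output_strictly_in_unit_interval(self, fitted, rng):
        model, _, _ = fitted
        p = model.score_windows(rng.uniform(0, 3, size=(40, 12)))
        assert np.all((p > 0) & (p < 1))

    def test_batch_equals_per_window_prediction(self, fitted, rng):
        model, X, _ = fitted
        batch = model.score_windows(X[:10])
        single = np.array([model.score_windows(X[i]) [0] for i in range(10)])
        np.testing.assert_allclose(batch, single, rtol=1e-12)

    def test_same_seed_reproduces_weights_and_predictions(self):
        rng = np.random.Generator(np.random.PCG64(8))
        X, y = _toy_windows(rng, n_pos=80, n_neg=200)
        spec = ConvNetSpec(epochs=8, seed=21)
        m1 = ParallelConv1DClassifier(spec).fit(X, y)
        m2 = ParallelConv1DClassifier(spec).fit(X, y)
        for a, b in zip(m1.params_, m2.params_):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(m1.score_windows(X), m2.score_windows(X))

    def test_positive_windows_score_above_negatives_on_average(self, fitted):
        model, X, y = fitted
        s = model.score_windows(X)
        assert s[y == 1].mean() > s[y == 0].mean()

    def test_wrong_window_length_rejected(self, fitted):
        with pytest.raises(ValueError, match="length"):
            fitted[0].score_windows(np.ones((3, 10)))

    def test_too_few_positive_windows_refused(self, rng):
        X, y = _toy_windows(rng, n_pos=20, n_neg=100)
        with pytest.raises(ValueError, match="positive windows"):
            ParallelConv1DClassifier(ConvNetSpec()).fit(X, y)


class TestPersistence:
    def test_logistic_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(300, len(FEATURE_NAMES)))
        y = (X[:, 0] + rng.normal(size=300) > 0).astype(int)
        m = LogisticWindowClassifier().fit(X, y)
        save_model(m, tmp_path / "lr.json")
        back = load_model(tmp_path / "lr.json")
        np.testing.assert_allclose(back.score_windows(X), m.score_windows(X), rtol=1e-12)

    def test_convnet_round_trip(self, tmp_path, rng):
        X, y = _toy_windows(rng, n_pos=80, n_neg=200)
        m = ParallelConv1DClassifier(ConvNetSpec(epochs=5, seed=2)).fit(X, y)
        save_model(m, tmp_path / "cnn.json")
        back = load_model(tmp_path / "cnn.json")
        np.testing.assert_allclose(back.score_windows(X), m.score_windows(X), rtol=1e-12)
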