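"""Feature assembly and the from-scratch backprop classifier."""
import numpy as np
import pandas as pd
import pytest

from oracles import finite_difference_grads
from specfx import bpnn as B
from specfx.binding import BindingSet
from specfx.errors import ConfigError, FitError, ValidationError
from specfx.gra import GraResult
from specfx.panel import INDICATORS
from specfx.pls import VipResult
from specfx.synthetic import SimConfig, simulate_dataset
from specfx.fingerprint import match_common_peaks, relative_content
from specfx.gra import gra_analysis
from specfx.pls import pls_analysis


def _toy_gra(peak_ids, value=0.5):
    grades = pd.DataFrame(
        np.full((4, len(peak_ids)), value), index=list(INDICATORS), columns=peak_ids
    )
    grades.iloc[0] = np.linspace(0.4, 0.9, len(peak_ids))
    return GraResult(grades=grades, coefficients={}, delta_min={}, delta_max={})


def _toy_vips(peak_ids):
    rng = np.random.default_rng(0)
    return {
        ind: VipResult(vip=rng.uniform(0.2, 2.0, len(peak_ids)), peak_ids=list(peak_ids))
        for ind in INDICATORS
    }


class TestAssembleFeatures:
    def test_shape_and_column_order(self):
        ids = list(range(1, 37))
        feats = B.assemble_features(
            _toy_gra(ids), _toy_vips(ids), BindingSet(frozenset({1, 5})),
            np.full(36, 1 / 36), peak_ids=ids,
        )
        assert feats.scaled.shape == (36, 10)
        assert tuple(feats.raw.columns) == B.FEATURE_COLUMNS
        assert feats.scaled.min() >= 0.0 and feats.scaled.max() <= 1.0

    def test_binding_flag_encoding(self):
        ids = [1, 2, 3, 4]
        feats = B.assemble_features(
            _toy_gra(ids), _toy_vips(ids), BindingSet(frozenset({2, 4})),
            np.full(4, 0.25), peak_ids=ids,
        )
        np.testing.assert_array_equal(feats.raw["binding"], [0, 1, 0, 1])

    def test_constant_column_scaled_to_zero_with_warning(self):
        ids = [1, 2, 3, 4]
        with pytest.warns(UserWarning, match="constant"):
            feats = B.assemble_features(
                _toy_gra(ids), _toy_vips(ids), BindingSet(frozenset()),
                np.full(4, 0.25), peak_ids=ids,
            )
        assert np.all(feats.scaled[:, B.FEATURE_COLUMNS.index("content")] == 0)
        assert np.all(feats.scaled[:, B.FEATURE_COLUMNS.index("binding")] == 0)

    def test_missing_peak_named_in_error(self):
        ids = [1, 2, 3]
        vips = _toy_vips([1, 2])
        with pytest.raises(ValidationError, match="3"):
            B.assemble_features(
                _toy_gra(ids), vips, BindingSet(frozenset()), np.full(3, 1 / 3),
                peak_ids=ids,
            )


def _separable_toy(n=20, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal([0.2, 0.2], 0.05, size=(n // 2, 2))
    b = rng.normal([0.8, 0.8], 0.05, size=(n // 2, 2))
    X = np.vstack([a, b])
    y = np.array([1] * (n // 2) + [0] * (n // 2))
    return X, y


class TestTrain:
    def test_gradient_check_against_finite_differences(self, rng):
        X = rng.normal(size=(7, 5))
        y = rng.integers(0, 2, size=7).astype(float)
        params = {
            "w1": rng.normal(scale=0.4, size=(5, 4)),
            "b1": rng.normal(scale=0.4, size=4),
            "w2": rng.normal(scale=0.4, size=4),
            "b2": np.asarray(rng.normal(scale=0.4)),
        }
        _loss, grads = B.loss_and_grads(params, X, y)
        num = finite_difference_grads(lambda p: B.loss_and_grads(p, X, y)[0], params)
        for key in params:
            # floor the denominator: tiny components are limited by
            # finite-difference rounding, not by the analytic gradient
            denom = np.maximum(np.abs(num[key]), 1e-4)
            rel = np.abs(grads[key] - num[key]) / denom
            assert np.max(rel) < 1e-6, key

    def test_separable_clusters_reach_perfect_training_accuracy(self):
        X, y = _separable_toy()
        model = B.train(X, y, B.BpnnConfig())
        assert B.evaluate(model, X, y).accuracy == 1.0

    def test_determinism_same_seed_same_weights(self):
        X, y = _separable_toy()
        cfg = B.BpnnConfig(epochs=500, seed=11)
        m1, m2 = B.train(X, y, cfg), B.train(X, y, cfg)
        np.testing.assert_array_equal(m1.w1, m2.w1)
        np.testing.assert_array_equal(m1.w2, m2.w2)
        np.testing.assert_array_equal(m1.loss_history, m2.loss_history)

    def test_xor_is_learnable_with_hidden_layer(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]] * 2)
        y = np.array([0, 1, 1, 0] * 2)
        model = B.train(X, y, B.BpnnConfig(hidden_units=4, epochs=20000,
                                           learning_rate=1.0, seed=0))
        assert B.evaluate(model, X, y).accuracy == 1.0

    def test_loss_decreases_over_first_epochs(self):
        X, y = _separable_toy()
        model = B.train(X, y, B.BpnnConfig(epochs=200))
        hist = model.loss_history[:10]
        assert np.all(np.diff(hist) < 0)

    def test_single_class_labels_rejected(self):
        X, _ = _separable_toy()
        with pytest.raises(ValidationError, match="class"):
            B.train(X, np.ones(X.shape[0]), B.BpnnConfig(epochs=10))

    def test_non_finite_features_raise_divergence_error(self):
        X, y = _separable_toy()
        X[0, 0] = np.nan
        with pytest.raises(FitError, match="learning_rate"):
            B.train(X, y, B.BpnnConfig(epochs=10))

    def test_config_validation(self):
        with pytest.raises(ConfigError, match="hidden_units"):
            B.BpnnConfig(hidden_units=0)
        with pytest.raises(ConfigError, match="learning_rate"):
            B.BpnnConfig(learning_rate=0.0)


class TestEvaluate:
    def test_perfect_predictions_diagonal(self):
        X, y = _separable_toy(10)
        model = B.train(X, y, B.BpnnConfig(epochs=3000))
        ev = B.evaluate(model, X, y)
        assert ev.matrix.loc["A", "A"] == 5 and ev.matrix.loc["B", "B"] == 5
        assert ev.matrix.loc["A", "B"] == 0 and ev.matrix.loc["B", "A"] == 0
        assert ev.accuracy == 1.0

    def test_all_predicted_one_class_gives_zero_recall_other(self):
        model = B.BpnnModel(
            w1=np.zeros((2, 2)), b1=np.zeros(2), w2=np.zeros(2), b2=10.0,
            loss_history=np.empty(0),
        )
        X = np.zeros((6, 2))
        y = [1, 1, 1, 0, 0, 0]
        ev = B.evaluate(model, X, y)
        assert ev.matrix["A"].sum() == 6
        assert ev.recall["B"] == 0.0

    def test_tie_at_half_goes_to_inactive(self):
        model = B.BpnnModel(
            w1=np.zeros((2, 2)), b1=np.zeros(2), w2=np.zeros(2), b2=0.0,
            loss_history=np.empty(0),
        )
        X = np.zeros((3, 2))
        assert np.all(B.predict_proba(model, X) == 0.5)
        assert list(B.predict_class(model, X)) == ["B", "B", "B"]


def test_leave_one_out_recovers_most_actives_under_low_noise():
    """LOO over all peaks: at least 6 of 7 planted actives classified active."""
    cfg = SimConfig(seed=3, noise_sd=30.0)
    tables, panel, binding, truth = simulate_dataset(cfg)
    matrix = match_common_peaks(tables)
    g = gra_analysis(matrix, panel)
    _m, vips = pls_analysis(matrix, panel)
    feats = B.assemble_features(g, vips, binding, relative_content(matrix),
                                peak_ids=matrix.peak_ids)
    labels = np.array([truth.labels()[j] for j in matrix.peak_ids], dtype=float)
    recovered = 0
    idx = np.arange(len(matrix.peak_ids))
    for k, j in enumerate(matrix.peak_ids):
        if j not in truth.active_peaks:
            continue
        keep = idx != k
        model = B.train(feats.scaled[keep], labels[keep],
                        B.BpnnConfig(epochs=4000, learning_rate=1.0, seed=0))
        pred = B.predict_class(model, feats.scaled[k][None, :])[0]
        recovered += pred == B.CLASS_A
    assert recovered >= 6
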