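import numpy as np
import pytest

from biodann.fusion import (
    FusionWeights,
    delta_fertility,
    evaluate_run,
    optimize_weights,
    pipgr,
    prediction_metrics,
    shannon_index,
    weighted_fusion,
)
from biodann.synthdata import generate_restoration_survey


def grid_search_weights(preds, truth, step=0.01):
    """Brute-force simplex search oracle for two-module fusion."""
    P = np.stack([np.asarray(p, float) for p in preds])
    best_w, best_mse = None, np.inf
    for w1 in np.arange(0.0, 1.0 + step / 2, step):
        w = np.array([w1, 1.0 - w1])
        mse = np.mean((w @ P - truth) ** 2)
        if mse < best_mse:
            best_w, best_mse = w, mse
    return best_w, best_mse


class TestWeightedFusion:
    def test_vertex_weight_returns_module_series(self, rng):
        y1, y2 = rng.normal(size=(2, 20))
        w = FusionWeights(labels=["a", "b"], w=np.array([1.0, 0.0]))
        np.testing.assert_array_equal(weighted_fusion([y1, y2], w), y1)

    def test_midpoint(self):
        w = FusionWeights(labels=["a", "b"], w=np.array([0.5, 0.5]))
        got = weighted_fusion([np.array([2.0]), np.array([4.0])], w)
        assert got[0] == 3.0

    def test_three_module_hand_sum(self, rng):
        preds = rng.normal(size=(3, 15))
        raw = rng.random(3)
        w = FusionWeights(labels=list("abc"), w=raw / raw.sum())
        expected = sum(wi * p for wi, p in zip(w.w, preds))
        np.testing.assert_allclose(weighted_fusion(list(preds), w), expected,
                                   atol=1e-12)

    def test_length_mismatch_rejected(self):
        w = FusionWeights(labels=["a", "b"], w=np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            weighted_fusion([np.zeros(3), np.zeros(4)], w)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            FusionWeights(labels=["a", "b"], w=np.array([0.7, 0.7]))
        with pytest.raises(ValueError):
            FusionWeights(labels=["a", "b"], w=np.array([1.5, -0.5]))


class TestOptimizeWeights:
    def test_perfect_module_dominates(self, rng):
        truth = rng.normal(size=200)
        noisy = truth + rng.normal(0, 1.0, 200)
        w = optimize_weights([truth, noisy], truth)
        assert w.w[0] >= 0.95

    def test_identical_modules_warn_uniform(self, rng):
        y = rng.normal(size=50)
        with pytest.warns(UserWarning):
            w = optimize_weights([y, y.copy()], y + 0.1)
        np.testing.assert_allclose(w.w, [0.5, 0.5])

    def test_constructed_mixture_recovered(self, rng):
        y1 = rng.normal(size=300)
        y2 = rng.normal(size=300)
        truth = 0.3 * y1 + 0.7 * y2
        w = optimize_weights([y1, y2], truth)
        np.testing.assert_allclose(w.w, [0.3, 0.7], atol=0.01)
        # agrees with the brute-force simplex oracle
        w_grid, _ = grid_search_weights([y1, y2], truth)
        np.testing.assert_allclose(w.w, w_grid, atol=0.011)

    def test_never_worse_than_any_single_module(self, rng):
        for trial in range(10):
            truth = rng.normal(size=100)
            preds = [truth + rng.normal(0, s, 100) for s in rng.uniform(0.1, 2, 3)]
            w = optimize_weights(preds, truth)
            fused_mse = np.mean((weighted_fusion(preds, w) - truth) ** 2)
            for p in preds:
                assert fused_mse <= np.mean((p - truth) ** 2) + 1e-12


class TestPredictionMetrics:
    def test_perfect_prediction(self, rng):
        y = rng.normal(size=30)
        m = prediction_metrics(y, y, epsilon=0.0)
        assert m.mse == 0.0 and m.rmse == 0.0 and m.accuracy == 1.0

    def test_hand_arithmetic(self):
        m = prediction_metrics([2.0, 4.0], [0.0, 0.0])
        assert m.mse == pytest.approx(10.0)
        assert m.rmse == pytest.approx(np.sqrt(10.0))

    def test_indicator_count(self):
        m = prediction_metrics([0.05, 0.2], [0.0, 0.0], epsilon=0.1)
        assert m.accuracy == 0.5

    def test_rmse_squares_to_mse(self, rng):
        m = prediction_metrics(rng.normal(size=50), rng.normal(size=50))
        assert m.rmse**2 == pytest.approx(m.mse, rel=1e-12)

    def test_accuracy_monotone_in_epsilon(self, rng):
        pred, truth = rng.normal(size=(2, 100))
        accs = [prediction_metrics(pred, truth, e).accuracy
                for e in (0.0, 0.1, 0.5, 2.0, np.inf)]
        assert all(a <= b for a, b in zip(accs, accs[1:]))
        assert accs[-1] == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            prediction_metrics([], [])


class TestRestorationIndicators:
    def test_delta_fertility(self):
        assert delta_fertility(0.85, 0.70) == pytest.approx(0.15)
        assert delta_fertility(0.5, 0.5) == 0.0

    def test_delta_fertility_linearity(self, rng):
        after = rng.random(20)
        before = rng.random(20)
        per_plot = delta_fertility(after, before)
        assert per_plot.mean() == pytest.approx(
            delta_fertility(after.mean(), before.mean())
        )

    @pytest.mark.parametrize(
        "after, before, expected", [(1.18, 1.0, 18.0), (1.0, 1.0, 0.0),
                                    (1.22, 1.0, 22.0)]
    )
    def test_pipgr(self, after, before, expected):
        assert pipgr(after, before) == pytest.approx(expected)

    def test_pipgr_rejects_nonpositive_baseline(self):
        with pytest.raises(ValueError):
            pipgr(1.0, 0.0)

    def test_shannon_single_species_zero(self):
        assert shannon_index([10]) == 0.0

    def test_shannon_uniform_is_log_s(self):
        assert shannon_index([5, 5, 5, 5]) == pytest.approx(np.log(4))

    def test_shannon_hand_value(self):
        assert shannon_index([2, 1, 1]) == pytest.approx(1.0397, abs=1e-4)

    def test_shannon_scale_invariant_and_bounded(self, rng):
        counts = rng.integers(1, 50, size=8)
        h = shannon_index(counts)
        assert h == pytest.approx(shannon_index(counts * 7), rel=1e-12)
        assert 0 <= h <= np.log(8)

    def test_shannon_zero_counts_dropped(self):
        assert shannon_index([3, 0, 3]) == pytest.approx(np.log(2))

    def test_shannon_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon_index([0, 0])


class TestEvaluateRun:
    def _preds(self, rng, n=60):
        truth = rng.normal(size=n)
        return {
            "biogeochem": truth + rng.normal(0, 0.1, n),
            "dnn": truth + rng.normal(0, 0.3, n),
        }, truth

    def test_single_module_fusion_is_identity(self, rng):
        preds, truth = self._preds(rng)
        report = evaluate_run(preds, truth, preds, truth,
                              enabled=["biogeochem"])
        assert report["weights"] == {"biogeochem": 1.0}
        expected_mse = float(np.mean((preds["biogeochem"] - truth) ** 2))
        assert report["mse"] == pytest.approx(expected_mse)

    def test_perfect_run_with_survey(self, rng):
        truth = rng.normal(size=40)
        preds = {"dnn": truth.copy()}
        survey = generate_restoration_survey(100, seed=0)
        report = evaluate_run(preds, truth, preds, truth, survey=survey)
        assert report["mse"] == 0.0 and report["accuracy"] == 1.0
        assert report["delta_F"] == pytest.approx(0.15, abs=0.01)
        assert report["shannon_before"] > 0

    def test_full_beats_every_ablation(self, rng):
        preds, truth = self._preds(rng, n=200)
        full = evaluate_run(preds, truth, preds, truth)
        for only in preds:
            ablated = evaluate_run(preds, truth, preds, truth, enabled=[only])
            assert full["validation_mse"] <= ablated["validation_mse"] + 1e-12

    def test_no_modules_rejected(self, rng):
        preds, truth = self._preds(rng)
        with pytest.raises(ValueError):
            evaluate_run(preds, truth, preds, truth, enabled=["nope"])
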