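"""Convex fusion of module predictions and evaluation metrics.

The final forecast is a weighted average y_hat(t) = sum_i w_i y_i(t) over
the enabled modules (mechanistic simulator, feed-forward net, attention
encoder) with nonnegative weights summing to 1, chosen to minimise
validation MSE over the probability simplex.  Because the simplex contains
its vertices, the optimised fusion can never do worse on the validation set
than the best single module.

Also provides prediction metrics (MSE, RMSE, tolerance-band accuracy) and
ecological-restoration indicators (soil-fertility change, percentage
increase in plant growth rate, Shannon diversity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "FusionWeights",
    "PredictionMetrics",
    "RestorationIndicators",
    "weighted_fusion",
    "optimize_weights",
    "prediction_metrics",
    "delta_fertility",
    "pipgr",
    "shannon_index",
    "evaluate_run",
]

DEFAULT_EPSILON = 0.1  # accuracy tolerance band, standardized units


@dataclass
class FusionWeights:
    """Convex coefficients over module predictions."""

    labels: list[str]
    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if len(self.labels) != self.w.size:
            raise ValueError("labels and weights must have equal length")
        if np.any(self.w < -1e-12):
            raise ValueError("weights must be nonnegative")
        if abs(self.w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        self.w = np.clip(self.w, 0.0, None)
        self.w = self.w / self.w.sum()

    def as_dict(self) -> dict[str, float]:
        return {lab: float(wi) for lab, wi in zip(self.labels, self.w)}


@dataclass
class PredictionMetrics:
    mse: float
    rmse: float
    accuracy: float
    epsilon: float


@dataclass
class RestorationIndicators:
    delta_F: float
    pipgr_percent: float
    shannon_before: float
    shannon_after: float


def _stack(preds: Mapping[str, np.ndarray] | Sequence[np.ndarray]):
    if isinstance(preds, Mapping):
        labels = list(preds)
        arrays = [np.asarray(preds[k], dtype=float) for k in labels]
    else:
        arrays = [np.asarray(a, dtype=float) for a in preds]
        labels = [f"module_{i + 1}" for i in range(len(arrays))]
    if not arrays:
        raise ValueError("need at least one module prediction")
    length = arrays[0].size
    if any(a.size != length for a in arrays):
        raise ValueError("module prediction series must have equal length")
    return labels, np.stack(arrays)  # (n_modules, length)


def weighted_fusion(
    preds: Mapping[str, np.ndarray] | Sequence[np.ndarray], weights: FusionWeights
) -> np.ndarray:
    """Elementwise convex combination of the module prediction series."""
    labels, P = _stack(preds)
    if labels != weights.labels and len(labels) != weights.w.size:
        raise ValueError("weights do not match the given modules")
    return weights.w @ P


def optimize_weights(
    preds: Mapping[str, np.ndarray] | Sequence[np.ndarray],
    truth: np.ndarray,
) -> FusionWeights:
    """Minimise validation MSE over the probability simplex.

    Solved as a small constrained quadratic programme (SLSQP with analytic
    gradient, uniform start); the result is compared against every vertex
    (single-module) weighting and the better of the two is returned, so the
    attained MSE is never above any single module's.  If all module
    predictions are identical the problem is degenerate and uniform weights
    are returned with a warning.
    """
    labels, P = _stack(preds)
    y = np.asarray(truth, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("need at least 2 validation points")
    if P.shape[1] != y.size:
        raise ValueError("predictions and truth must have equal length")
    n_mod = P.shape[0]
    if n_mod == 1:
        return FusionWeights(labels=labels, w=np.array([1.0]))
    if np.max(np.abs(P - P[0])) < 1e-12:
        warnings.warn(
            "all module predictions are identical; returning uniform weights"
        )
        return FusionWeights(labels=labels, w=np.full(n_mod, 1.0 / n_mod))

    N = y.size

    def objective(w):
        r = w @ P - y
        return float(r @ r) / N

    def gradient(w):
        return 2.0 * P @ (w @ P - y) / N

    res = minimize(
        objective,
        x0=np.full(n_mod, 1.0 / n_mod),
        jac=gradient,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n_mod,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones_like(w)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    w_opt = np.clip(res.x, 0.0, None)
    w_opt = w_opt / w_opt.sum()

    candidates = [w_opt] + [np.eye(n_mod)[i] for i in range(n_mod)]
    best = min(candidates, key=objective)
    return FusionWeights(labels=labels, w=best)


def prediction_metrics(
    pred: np.ndarray, truth: np.ndarray, epsilon: float = DEFAULT_EPSILON
) -> PredictionMetrics:
    """MSE, RMSE and tolerance-band accuracy.

    Accuracy is the fraction of points with ``|pred - truth| <= epsilon``:
    an exact-equality indicator is degenerate for continuous predictions,
    so a tolerance band is used and the band is always reported with it.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if pred.size == 0 or pred.size != truth.size:
        raise ValueError("pred and truth must be non-empty and equal length")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    err = pred - truth
    mse = float(np.mean(err**2))
    return PredictionMetrics(
        mse=mse,
        rmse=float(np.sqrt(mse)),
        accuracy=float(np.mean(np.abs(err) <= epsilon)),
        epsilon=epsilon,
    )


def delta_fertility(F_after, F_before):
    """Soil-fertility change ``F_after - F_before`` (scalar or elementwise)."""
    F_after = np.asarray(F_after, dtype=float)
    F_before = np.asarray(F_before, dtype=float)
    if not (np.all(np.isfinite(F_after)) and np.all(np.isfinite(F_before))):
        raise ValueError("fertility values must be finite")
    out = F_after - F_before
    return float(out) if out.ndim == 0 else out


def pipgr(growth_after: float, growth_before: float) -> float:
    """Percentage increase in plant growth rate."""
    if growth_before <= 0:
        raise ValueError("growth_before must be > 0")
    return 100.0 * (growth_after - growth_before) / growth_before


def shannon_index(counts) -> float:
    """Shannon diversity H' = -sum p_i ln p_i over species with count > 0."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be >= 0")
    total = counts.sum()
    if total == 0:
        raise ValueError("at least one species count must be positive")
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log(p)))


def evaluate_run(
    val_preds: Mapping[str, np.ndarray],
    val_truth: np.ndarray,
    test_preds: Mapping[str, np.ndarray],
    test_truth: np.ndarray,
    survey=None,
    epsilon: float = DEFAULT_EPSILON,
    enabled: Optional[Sequence[str]] = None,
) -> dict:
    """Fuse module predictions and assemble the full evaluation report.

    Weights are optimised on the validation series over the enabled modules
    (ablation = passing a subset via ``enabled``), then applied to the test
    series for the reported metrics.  If a restoration survey is supplied,
    its indicators (delta-F, PIPGR, Shannon before/after) are appended.
    """
    if enabled is None:
        enabled = list(val_preds)
    enabled = [m for m in enabled if m in val_preds]
    if not enabled:
        raise ValueError("no enabled modules")
    val_sel = {m: val_preds[m] for m in enabled}
    test_sel = {m: test_preds[m] for m in enabled}

    weights = optimize_weights(val_sel, val_truth)
    fused_val = weighted_fusion(val_sel, weights)
    fused_test = weighted_fusion(test_sel, weights)
    metrics = prediction_metrics(fused_test, test_truth, epsilon)

    report = {
        "modules": enabled,
        "weights": weights.as_dict(),
        "mse": metrics.mse,
        "rmse": metrics.rmse,
        "accuracy": metrics.accuracy,
        "epsilon": metrics.epsilon,
        "validation_mse": float(np.mean((fused_val - np.asarray(val_truth)) ** 2)),
        "per_module_test_mse": {
            m: float(np.mean((np.asarray(test_sel[m]) - np.asarray(test_truth)) ** 2))
            for m in enabled
        },
        "baseline_mse": float(np.var(np.asarray(test_truth, dtype=float))),
    }

    if survey is not None:
        dF = float(np.mean(delta_fertility(
            survey.plots["F_after"].to_numpy(), survey.plots["F_before"].to_numpy()
        )))
        growth_pct = pipgr(
            float(survey.plots["growth_after"].mean()),
            float(survey.plots["growth_before"].mean()),
        )
        indicators = RestorationIndicators(
            delta_F=dF,
            pipgr_percent=growth_pct,
            shannon_before=shannon_index(survey.abundance_totals("before")),
            shannon_after=shannon_index(survey.abundance_totals("after")),
        )
        report.update(
            delta_F=indicators.delta_F,
            pipgr_percent=indicators.pipgr_percent,
            shannon_before=indicators.shannon_before,
            shannon_after=indicators.shannon_after,
        )
    return report
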