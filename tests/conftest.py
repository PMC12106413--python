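import numpy as np
import pytest

from biodann.synthdata import ScenarioConfig


def constant_env_config(**overrides) -> ScenarioConfig:
    """Scenario with all environmental forcing switched off (modifier = 1)."""
    base = dict(
        duration_steps=200,
        temp_amplitude=0.0,
        temp_jitter_sd=0.0,
        moisture_amplitude=0.0,
        moisture_jitter_sd=0.0,
        ph_sd=0.0,
        obs_noise_sd=0.0,
        missing_rate=0.0,
        seed=0,
    )
    base.update(overrides)
    return ScenarioConfig(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def finite_difference_grads(model, X, y, h=1e-6):
    """Central-difference gradient of the model's batch loss, per parameter."""
    grads = []
    for p in model.parameters():
        g = np.zeros_like(p)
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p[idx]
            p[idx] = orig + h
            lp, _ = model.loss_and_grads(X, y)
            p[idx] = orig - h
            lm, _ = model.loss_and_grads(X, y)
            p[idx] = orig
            g[idx] = (lp - lm) / (2 * h)
        grads.append(g)
    return grads


def grad_relative_errors(model, X, y, h=1e-6):
    """Relative L2 error of analytic vs finite-difference gradients."""
    _, analytic = model.loss_and_grads(X, y)
    numeric = finite_difference_grads(model, X, y, h=h)
    errs = []
    for a, n in zip(analytic, numeric):
        denom = np.linalg.norm(n) + 1e-12
        errs.append(np.linalg.norm(a - n) / denom)
    return errs
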