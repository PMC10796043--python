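import numpy as np
import pytest

from hetforest import datagen
from hetforest.datagen import CovariateDef, DGPConfig, EffectDef, OutcomeDef


@pytest.fixture(scope="session")
def default_sample():
    """A modest default-world sample shared by read-only tests."""
    cfg = datagen.default_config(n_households=500)
    sample, truth = datagen.generate_sample(cfg, seed=7)
    return cfg, sample, truth


@pytest.fixture()
def simple_config():
    """Four binary covariates, one gaussian outcome, constant effect 1."""
    covs = [CovariateDef(f"x{i}", p=0.5) for i in range(4)]
    out = OutcomeDef("y", "gaussian", intercept=1.0, coefs={"x0": 1.0},
                     noise_scale=1.0, effect=EffectDef("constant", value=1.0))
    return DGPConfig(n_households=400, covariates=covs, outcomes=[out],
                     control_crossover=0.0)


def make_centered_toy(n, rng, tau_fn, p=1):
    """Noise-free pre-centered causal data: y = tau(x) * zc with e = 0.5."""
    X = rng.integers(0, 2, size=(n, p)).astype(float)
    treat = np.tile([0, 1], n // 2 + 1)[:n]
    zc = treat - 0.5
    tau = tau_fn(X)
    yc = tau * zc
    w = np.ones(n)
    return X, yc, zc, w, treat.astype(np.int64), tau
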