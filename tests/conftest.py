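import numpy as np
import pytest

import sccsp


@pytest.fixture(scope="session")
def small_mi_epochs() -> sccsp.EpochSet:
    """Small, well-separated two-class ERD dataset (fast fits)."""
    cfg = sccsp.MIGenConfig(n_trials_per_class=10, erd_depth=0.8, seed=42)
    return sccsp.generate_mi_epochs(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_spd(rng: np.random.Generator, p: int, trace_one: bool = True) -> np.ndarray:
    """Random symmetric positive-definite matrix (optionally trace-normalized)."""
    a = rng.standard_normal((p, 2 * p))
    c = a @ a.T / (2 * p) + 1e-3 * np.eye(p)
    return c / np.trace(c) if trace_one else c
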