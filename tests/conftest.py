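import numpy as np
import pandas as pd
import pytest

import pare


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_data(rng):
    """Random 30 x 8 feature matrix with a two-level batch and continuous age."""
    y = rng.normal(size=(30, 8))
    meta = pd.DataFrame(
        {
            "batch": ["A"] * 15 + ["B"] * 15,
            "age": rng.normal(size=30),
            "group": list(np.repeat(["g1", "g2", "g3"], 10)),
        },
        index=pd.Index([f"s{i}" for i in range(30)], name="sample_id"),
    )
    return y, meta


@pytest.fixture
def shifted_batches(rng):
    """Two batches with a pure additive shift on top of shared group structure."""
    def make(batch_effect: float, seed: int = 7):
        cfg = pare.SyntheticConfig(
            n_per_cell=8, n_groups=3, n_batches=2, n_features=10,
            group_effect=1.0, batch_effect=batch_effect, noise_sd=0.4, seed=seed,
        )
        return pare.generate(cfg)

    return make
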