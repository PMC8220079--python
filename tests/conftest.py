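import numpy as np
import pytest

import emgmotion as em


@pytest.fixture(scope="session")
def small_cfg():
    """Three-class, four-channel miniature protocol (shortened blocks keep
    unit tests fast; the full-protocol conditions are exercised in the
    acceptance tests)."""
    return em.SyntheticConfig(
        n_channels=4,
        fs=200.0,
        movement_classes=(1, 2, 3),
        movement_s=1.5,
        rest_s=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_recording(small_cfg):
    return em.generate_recording(small_cfg)


@pytest.fixture(scope="session")
def small_model(small_recording):
    """A classifier trained on the miniature recording's training split."""
    ws = em.segment(small_recording, 200, 100)
    train_ws, _ = em.split_by_repetition(ws, (1, 3, 4, 6), (2, 5))
    table = em.extract_features(train_ws, 1e-8)
    params = em.fit_standardizer(table)
    model = em.train(
        em.apply_standardizer(params, table), standardizer=params, epochs=25, seed=5
    )
    model.meta["threshold"] = 1e-8
    return model
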