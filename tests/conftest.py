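import numpy as np
import pytest

import neurofuse as nf


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_cohort():
    """12 noise-free phantoms (4 per class) on the reduced-resolution grid."""
    return nf.generate_cohort(nf.tiny_config(seed=11))


@pytest.fixture(scope="session")
def trained_tiny_model(tiny_cohort):
    """One full-variant model trained on the whole tiny cohort (no held-out
    patient); shared by the explanation/localization checks."""
    from neurofuse.training import _normalized, tiny_train_config, train_model

    samples = [_normalized(s) for s in tiny_cohort]
    return train_model(samples, nf.tiny_model_config("full"),
                       tiny_train_config(seed=7), seed=77)
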