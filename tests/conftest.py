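import numpy as np
import pytest

from clemq import DecayParams, GranuleAgeObservation


@pytest.fixture
def model2_params() -> DecayParams:
    """Lag-then-exponential truth used across fitting tests."""
    return DecayParams(model_id=2, a=0.027, delta=2.72, tau=2.85)


@pytest.fixture
def exact_obs(model2_params):
    """Noise-free observations on the model-2 curve at the cohort ages."""
    from clemq import eval_decay_model

    times = (0.27, 1.0, 2.0, 3.0, 4.0, 5.0)
    return [
        GranuleAgeObservation(
            t=t, y=float(eval_decay_model(model2_params, t)), sem=0.002, n_replicates=3
        )
        for t in times
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(42)
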