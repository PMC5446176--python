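import dataclasses

import pytest

from nexkin import default_truth
from nexkin.observe import ObservationParams


@pytest.fixture(scope="session")
def truth():
    """Default no-tetracycline ground truth."""
    return default_truth(0.0)


@pytest.fixture(scope="session")
def quiet_truth():
    """Ground truth rendered without any observation noise.

    Point noise, shot-to-shot rate jitter and titration concentration
    errors are all disabled, so generated traces are the deterministic
    observable of the underlying ODE model.
    """
    base = default_truth(0.0)
    obs = dataclasses.replace(
        base.observation, noise_sd=0.0, rate_jitter_cv=0.0, conc_error_cv=0.0
    )
    return dataclasses.replace(base, observation=obs)


@pytest.fixture(autouse=True)
def _quiet_pseudo_first_order_warnings():
    """The default association design intentionally includes points below
    the 10x pseudo-first-order margin; silence that advisory in tests."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*below 10 x.*", category=UserWarning
        )
        warnings.filterwarnings(
            "ignore", message=".*rate poorly.*", category=UserWarning
        )
        yield


def noiseless(truth):
    obs = dataclasses.replace(
        truth.observation, noise_sd=0.0, rate_jitter_cv=0.0, conc_error_cv=0.0
    )
    return dataclasses.replace(truth, observation=obs)
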