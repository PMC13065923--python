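import pytest

from scaffenum import make_toy_hypothesis, make_toy_library


@pytest.fixture(scope="session")
def toy_hypothesis():
    return make_toy_hypothesis()


@pytest.fixture(scope="session")
def small_library(toy_hypothesis):
    """40 zero-noise poses with planted ground truth, shared across tests."""
    return make_toy_library(40, hyp=toy_hypothesis, noise_sd=0.0, rng_seed=11)


@pytest.fixture(scope="session")
def recovery_library(toy_hypothesis):
    """The 200-pose zero-noise library used for scaffold-recovery checks."""
    return make_toy_library(200, hyp=toy_hypothesis, noise_sd=0.0, rng_seed=101)
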