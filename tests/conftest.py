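import numpy as np
import pytest

from stochsirs import ModelParams, load_fixture, make_builtin_incidence


@pytest.fixture(scope="session")
def examples():
    return {name: load_fixture(name) for name in
            ("example1", "example2", "example3", "example4", "example5")}


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_valid_params(rng, l=None, sigma_scale=0.8):
    """Random parameter draw satisfying all structural constraints."""
    l = l if l is not None else int(rng.integers(1, 4))
    return ModelParams(
        Lambda=float(rng.uniform(0.5, 5.0)),
        q=float(rng.uniform(0.0, 0.9)),
        p=float(rng.uniform(0.0, 1.0)),
        epsilon=float(rng.uniform(0.0, 1.5)),
        gamma=float(rng.uniform(0.0, 1.5)),
        beta=float(rng.uniform(0.0, 2.5)),
        dS=float(rng.uniform(0.05, 1.0)),
        dI=float(rng.uniform(0.05, 1.0)),
        dR=float(rng.uniform(0.05, 1.0)),
        sigma=rng.uniform(0.0, sigma_scale, size=(4, l)),
    )


def random_incidence(rng):
    return make_builtin_incidence(float(rng.uniform(0, 1.0)), float(rng.uniform(0, 3.0)))
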