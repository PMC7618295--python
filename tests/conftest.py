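"""Shared fixtures: one small synthetic subject and its measured data.

Session-scoped so the projector matrix and sinograms are built once."""

import numpy as np
import pytest

import pseudopet as pp


@pytest.fixture(scope="session")
def small_cfg():
    return pp.PhantomConfig(shape=(32, 32, 16))


@pytest.fixture(scope="session")
def subject(small_cfg):
    return pp.sample_subject(7, small_cfg)


@pytest.fixture(scope="session")
def system(subject):
    return pp.SystemModel.from_phantom(subject)


@pytest.fixture(scope="session")
def sino(system, subject):
    return pp.simulate_prompts(system, subject, 5e5, 0.3, seed=1, n_sub=7)


@pytest.fixture(scope="session")
def low_sino(sino):
    return pp.thin_counts(sino, 0.025, seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
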