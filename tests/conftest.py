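"""Shared fixtures: small synthetic recordings reused across test modules."""

import numpy as np
import pytest

import neuroload as nl


@pytest.fixture(scope="session")
def default_run():
    """Default-schedule synthetic recording (seed 7) with its events."""
    rec, events = nl.generate(seed=7)
    return rec, events


@pytest.fixture(scope="session")
def default_epochs(default_run):
    rec, events = default_run
    return nl.extract_epochs(nl.bandpass_fir(rec), events)


@pytest.fixture(scope="session")
def band_summary(default_epochs):
    return nl.band_energy_table(default_epochs)


@pytest.fixture(scope="session")
def entropy_result(default_epochs):
    return nl.entropy_table(default_epochs, channels=["T7", "T8"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
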