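from functools import lru_cache

import pytest
from hypothesis import HealthCheck, settings

from dynstab import fit_sliding
from dynstab.synth import figure1_dataset, make_focal_seizure_surrogate

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@lru_cache(maxsize=None)
def _surrogate_and_track(seed: int, ictal_seed: int | None = None):
    surrogate = make_focal_seizure_surrogate(seed=seed, ictal_seed=ictal_seed)
    track = fit_sliding(surrogate.recording)
    return surrogate, track


@pytest.fixture(scope="session")
def surrogate_track():
    """Factory returning (FocalSurrogate, ModelTrack), cached across tests."""
    return _surrogate_and_track


@lru_cache(maxsize=1)
def _figure1_and_track():
    rec = figure1_dataset()
    return rec, fit_sliding(rec)


@pytest.fixture(scope="session")
def figure1_track():
    return _figure1_and_track()
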