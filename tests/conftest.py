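import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def an_params():
    from bushylso.an import ANParams
    return ANParams()


@pytest.fixture(scope="session")
def spont_trains_20(an_params):
    """Twenty 20-second spontaneous AN trains (shared across tests)."""
    from bushylso.an import sample_an_train, silence
    spec = silence(20_000.0)
    return [sample_an_train(spec, an_params, (101, k)) for k in range(20)]


def pooled_sustained(trains_or_ensembles, window):
    """Pool spike times within a window across trains."""
    lo, hi = window
    parts = []
    for tr in trains_or_ensembles:
        t = tr.times
        parts.append(t[(t >= lo) & (t <= hi)])
    return np.concatenate(parts) if parts else np.empty(0)
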