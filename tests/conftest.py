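import numpy as np
import pytest

from fluxkin import synthetic


@pytest.fixture(scope="session")
def small_spec():
    """Reduced-rate study spec shared by fast tests (generation is costly)."""
    return synthetic.default_spec(event_rate=100.0, seed=1)


@pytest.fixture(scope="session")
def small_recording(small_spec):
    rec, labels = synthetic.assemble_recording(small_spec, "IgG+M", sample=0)
    return rec, labels


@pytest.fixture(scope="session")
def small_thresholds(small_spec):
    from fluxkin.pipeline import fmo_thresholds_for_sample

    return fmo_thresholds_for_sample(small_spec, sample=0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
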