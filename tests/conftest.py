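import numpy as np
import pytest

import proxispec as px


@pytest.fixture(scope="session")
def registry():
    return px.load_registry()


@pytest.fixture(scope="session")
def trial():
    """Default synthetic fertilizer trial (40 canopy samples), fixed seed."""
    collection, attributes, layout = px.generate_trial(px.TrialDesign(seed=11))
    return collection, attributes, layout


@pytest.fixture(scope="session")
def trial_with_outlier():
    """20 canopy samples (one treatment) plus a planted dry-leaf control."""
    design = px.TrialDesign(treatments=("140",), seed=5)
    return px.generate_trial(design, planted_outlier=True)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def flat_spectrum():
    wl = np.arange(400, 1001, dtype=float)
    return px.Spectrum("flat", wl, np.full(wl.size, 0.3))
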