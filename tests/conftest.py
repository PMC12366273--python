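import numpy as np
import pytest

import gradientchip as gc


@pytest.fixture(scope="session")
def factors():
    return gc.load_default_factors()


@pytest.fixture(scope="session")
def media():
    return gc.load_default_media()


@pytest.fixture(scope="session")
def full_analysis():
    """The default two-day single-loading distribution analysis (7 factors).

    Shared across design-metric and acceptance tests; runs once per session.
    """
    return gc.run_distribution_analysis()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
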