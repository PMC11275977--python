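import numpy as np
import pytest

import phenolatency as ph


@pytest.fixture(scope="session")
def semel_params():
    return ph.default_parameters(ph.SEMELPAROUS)


@pytest.fixture(scope="session")
def itero_params():
    return ph.default_parameters(ph.ITEROPAROUS)


@pytest.fixture(scope="session")
def semel_singular_points(semel_params):
    """Singular latency strategies of the baseline semelparous model
    (computed once; shared by the invasion, competition and acceptance
    tests)."""
    return ph.find_singular_strategies(semel_params)


@pytest.fixture(scope="session")
def itero_singular_points(itero_params):
    return ph.find_singular_strategies(itero_params)


def ess_values(points):
    return [p.tau for p in points if p.classification == "ESS-attractor"]


def repellor_values(points):
    return [p.tau for p in points if p.classification == "repellor"]
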