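"""Shared fixtures.

The two reduced-scale trained-network fixtures are expensive (about a
minute per replication) and session-scoped; every test that needs a
trained stack shares them.
"""

import numpy as np
import pytest

from selattn import study


@pytest.fixture(scope="session")
def reduced_baseline():
    """Two baseline replications at the reduced desk scale."""
    cfg = study.desk_scale_config("baseline", seed=20)
    nets, _ = study.train_replications(cfg)
    tests = study.make_test_sets(cfg)
    return cfg, nets, tests


@pytest.fixture(scope="session")
def reduced_two_locations():
    """Two replications of the two-corner control at the reduced desk scale."""
    cfg = study.desk_scale_config("two_locations", seed=21)
    nets, _ = study.train_replications(cfg)
    tests = study.make_test_sets(cfg)
    return cfg, nets, tests
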