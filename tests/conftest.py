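"""Shared fixtures.

The two trained networks are expensive (tens of seconds each on one CPU),
so they are session-scoped and reused across the unit, integration and
acceptance tests. All data is generated programmatically from fixed seeds.
"""
import pytest

from dugongtrails.synthbench import (train_synthetic_model1,
                                     train_synthetic_model2)


@pytest.fixture(scope="session")
def model1_training():
    """(trained Model_1, metrics log, held-out test tiles)."""
    return train_synthetic_model1(seed=0)


@pytest.fixture(scope="session")
def model2_training():
    """(trained Model_2, metrics log)."""
    return train_synthetic_model2(seed=1)
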