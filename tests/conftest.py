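import numpy as np
import pytest

from sskit.core import SS8_STATES, ProteinRecord
from sskit.synthetic import (
    ErrorProfile,
    GeneratorConfig,
    generate_predictions,
    generate_truth,
)


@pytest.fixture(scope="session")
def small_truth() -> list[ProteinRecord]:
    """40 short imbalanced chains (shared, read-only)."""
    cfg = GeneratorConfig(n_chains=40, length_min=30, length_max=80, length_mean=50, seed=11)
    return generate_truth(cfg)


@pytest.fixture(scope="session")
def medium_truth() -> list[ProteinRecord]:
    """200 chains at the default study conditions (shared, read-only)."""
    return generate_truth(GeneratorConfig(n_chains=200, seed=7))


@pytest.fixture()
def good_predictions(medium_truth):
    profile = ErrorProfile(recall={s: 0.9 for s in SS8_STATES})
    return generate_predictions(medium_truth, profile, seed=21)


@pytest.fixture()
def weak_predictions(medium_truth):
    profile = ErrorProfile(recall={s: 0.7 for s in SS8_STATES})
    return generate_predictions(medium_truth, profile, seed=22)
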