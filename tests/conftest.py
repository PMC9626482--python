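import numpy as np
import pytest

from plasmadose.damage_model import ModelConfig, evaluate_model, split_data, train_pgnn
from plasmadose.synthetic_data import (
    DoELevels,
    KineticsConfig,
    KineticsPredictor,
    generate_doe_dataset,
)


@pytest.fixture(scope="session")
def kinetics() -> KineticsConfig:
    return KineticsConfig()


@pytest.fixture(scope="session")
def ground_truth(kinetics) -> KineticsPredictor:
    return KineticsPredictor(kinetics)


@pytest.fixture(scope="session")
def default_doe(kinetics):
    return generate_doe_dataset(DoELevels(), kinetics, replicates=3, seed=1)


@pytest.fixture(scope="session")
def doe_split(default_doe):
    return split_data(default_doe, 0.75, seed=2)


@pytest.fixture(scope="session")
def trained_pgnn(doe_split):
    """One default-config PGNN fit shared by the slower tests."""
    train, _ = doe_split
    return train_pgnn(train, ModelConfig(seed=0))
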