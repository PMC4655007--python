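import numpy as np
import pytest

from bootsvm import (
    GeneratorSpec,
    LabeledDataset,
    OptimizerSettings,
    fixture_dataset_A,
    generate,
)


@pytest.fixture(scope="session")
def dataset_a() -> LabeledDataset:
    return fixture_dataset_A()


@pytest.fixture(scope="session")
def signal_dataset() -> LabeledDataset:
    """Small two-class set with strong, easily learnable separation."""
    return generate(
        GeneratorSpec(
            n_per_class=(8, 8),
            n_variables=25,
            n_informative=10,
            effect_size=3.0,
            seed=42,
        )
    )


@pytest.fixture(scope="session")
def null_dataset() -> LabeledDataset:
    """Two-class set with zero class signal (labels carry no information)."""
    return generate(
        GeneratorSpec(
            n_per_class=(8, 8),
            n_variables=20,
            n_informative=0,
            effect_size=0.0,
            seed=7,
        )
    )


@pytest.fixture
def tiny_settings() -> OptimizerSettings:
    """Scaled-down optimiser settings for fast unit-level pipeline runs."""
    return OptimizerSettings(n_boot=10, restarts=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
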