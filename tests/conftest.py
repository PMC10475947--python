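import pytest

from ntracer import (
    LabelingConfig,
    NoiseModel,
    StudyDesign,
    compute_indices_table,
    compute_uptake_table,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def labeling() -> LabelingConfig:
    return LabelingConfig()


@pytest.fixture(scope="session")
def zero_noise_dataset(labeling):
    """Default design simulated with every noise source at zero."""
    return simulate_dataset(StudyDesign(seed=11), noise=NoiseModel.zero(), config=labeling)


@pytest.fixture(scope="session")
def noisy_dataset(labeling):
    """Default design under the default noise model."""
    return simulate_dataset(StudyDesign(seed=23), config=labeling)


@pytest.fixture(scope="session")
def zero_noise_indices(zero_noise_dataset, labeling):
    ds = zero_noise_dataset
    uptake = compute_uptake_table(ds.plants, ds.soil, ds.quadrats, labeling)
    return compute_indices_table(uptake, ds.soil)
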