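import dataclasses

import pytest

from fameclass.synthetic_data import (GeneratorConfig, default_parameters,
                                      generate_dataset)


@pytest.fixture(scope="session")
def default_params():
    return default_parameters()


@pytest.fixture(scope="session")
def default_dataset():
    """Study-sized dataset (100 fish, 596 chromatograms) at seed 0."""
    return generate_dataset(default_parameters(), GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def small_dataset(default_params):
    """Reduced dataset (8 fish/group, 3 replicates) for expensive stages."""
    params = dataclasses.replace(
        default_params,
        samples_per_group={0: 8, 1: 8, 2: 8, 3: 8},
        replicates_per_sample=3)
    return generate_dataset(params, GeneratorConfig(seed=1, missing_instances=2))
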