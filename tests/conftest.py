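import numpy as np
import pytest

from dtiblocks import (DrugEncoderConfig, DTIModel, TargetEncoderConfig,
                       SyntheticSpec)
from dtiblocks.synthetic_data import generate_dataset


@pytest.fixture(scope="session")
def tiny_spec():
    return SyntheticSpec(n_drugs=24, n_targets=8, n_pairs=48,
                         min_len=30, max_len=60, seed=7)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    dataset, drugs, targets = generate_dataset(tiny_spec)
    return dataset, drugs, targets


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset):
    dataset, _, _ = tiny_dataset
    return DTIModel(dataset,
                    DrugEncoderConfig(channels=16, n_blocks=1, dropout=0.2),
                    TargetEncoderConfig(channels=16),
                    head_widths=(32, 16))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
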