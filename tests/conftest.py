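import pytest

from lincpipe.coding_potential import fit_coding_model
from lincpipe.synthetic_data import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def dataset():
    """Desk-scale synthetic dataset with ground truth, fixed seed."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def coding_model(dataset):
    """Coding-potential model trained on the synthetic training sets."""
    return fit_coding_model(
        list(dataset.train_coding.values()),
        list(dataset.train_noncoding.values()),
        seed=1,
    )
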