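import numpy as np
import pytest

from topobow import evaluation, phantoms

#: scaled-down study profile used by the heavier integration tests:
#: 50 phantoms per class at 112x112 under the two-class morphology gap.
PHANTOM_SIZE = 112
N_PER_CLASS = 50
DATASET_SEED = 1


@pytest.fixture(scope="session")
def phantom_dataset():
    """100 two-class phantoms at the scaled-down study conditions."""
    base = phantoms.PhantomConfig(image_size=PHANTOM_SIZE)
    records, manifest = phantoms.make_dataset(N_PER_CLASS, base,
                                              seed=DATASET_SEED)
    return records, manifest


@pytest.fixture(scope="session")
def phantom_features(phantom_dataset):
    """Per-image TDA blocks and descriptor sets, computed once."""
    records, _ = phantom_dataset
    tda_blocks, descriptor_sets = evaluation.extract_features(records)
    labels = np.array([r.label for r in records])
    return tda_blocks, descriptor_sets, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
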