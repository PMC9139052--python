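import numpy as np
import pytest

from ppidht.dht_features import feature_matrix
from ppidht.synthetic_data import SyntheticDatasetSpec, gen_ppi_dataset


def featurize(spec: SyntheticDatasetSpec):
    pssms, pairs = gen_ppi_dataset(spec)
    X = feature_matrix(pssms, zip(pairs["id_a"], pairs["id_b"]))
    y = pairs["label"].to_numpy()
    return X, y


@pytest.fixture(scope="session")
def planted_dataset():
    """Benchmark-scale planted-signal dataset: 500+500 pairs, shift 3, unit noise."""
    spec = SyntheticDatasetSpec(
        n_pos=500, n_neg=500, signal_strength=3.0, noise_sd=1.0, seed=1
    )
    return featurize(spec)


@pytest.fixture(scope="session")
def null_dataset():
    """Same conditions with the planted signal switched off (exchangeable classes)."""
    spec = SyntheticDatasetSpec(
        n_pos=500, n_neg=500, signal_strength=0.0, noise_sd=1.0, seed=1
    )
    return featurize(spec)


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted dataset for fast structural tests."""
    spec = SyntheticDatasetSpec(
        n_pos=40, n_neg=40, signal_strength=3.0, noise_sd=1.0, seed=7
    )
    return featurize(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
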