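import numpy as np
import pytest

import leafspec as ls


@pytest.fixture(scope="session")
def small_dataset():
    """A small but fully structured synthetic dataset (10 plants/group, 3 scans)."""
    cfg = ls.SyntheticConfig(seed=2024, n_samples_per_group=10, replicates_per_sample=3)
    scans, traits = ls.generate_dataset(cfg)
    return cfg, scans, traits


@pytest.fixture(scope="session")
def small_processed(small_dataset):
    """Replicate-averaged and preprocessed matrix for the small dataset."""
    _, scans, traits = small_dataset
    matrix = ls.average_replicates(scans)
    return ls.preprocess_matrix(matrix), traits


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture(scope="session")
def default_run():
    """Default synthetic study (150 plants/group), preprocessed and split 60/40."""
    from leafspec.synthetic import generate_matrix

    cfg = ls.SyntheticConfig(seed=123)
    matrix, traits = generate_matrix(cfg)
    processed = ls.preprocess_matrix(matrix)
    train_ids, test_ids = ls.train_test_split(processed.sample_ids, 0.6, seed=7)
    pos = {s: i for i, s in enumerate(processed.sample_ids)}
    tr = np.array([pos[s] for s in train_ids])
    te = np.array([pos[s] for s in test_ids])
    return processed, traits, train_ids, test_ids, tr, te
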