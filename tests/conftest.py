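import numpy as np
import pytest

import stackpep as sp


@pytest.fixture(scope="session")
def small_dataset():
    """Motif-implanted 40/160 dataset with split and folds assigned."""
    ds = sp.generate(sp.SyntheticSpec(n_pos=40, n_neg=160,
                                      motifs=[("WHKYW", 0.95)], seed=7))
    ds = sp.stratified_split(ds, test_fraction=0.2, seed=7)
    return sp.assign_folds(ds, n_folds=5, seed=7)


@pytest.fixture(scope="session")
def trained_pair(small_dataset):
    """Two trained single-feature models sharing one fold assignment."""
    m1 = sp.train_single(small_dataset, "AAC", "LR", seed=0)
    m2 = sp.train_single(small_dataset, "GAAC", "RF", seed=0)
    return m1, m2


@pytest.fixture(scope="session")
def prob_matrix(small_dataset, trained_pair):
    labels = small_dataset.train().labels
    return sp.build_probability_matrix(list(trained_pair), labels)


@pytest.fixture
def random_peptides():
    rng = np.random.default_rng(11)
    return ["".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                               size=rng.integers(9, 26)))
            for _ in range(100)]
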