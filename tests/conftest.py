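import numpy as np
import pytest

from seqppi import load_default_scale_set
from seqppi import rf_model as rm
from seqppi.synthetic import SyntheticConfig, generate_pair_dataset


@pytest.fixture(scope="session")
def scale_set():
    return load_default_scale_set()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, length):
    from seqppi.scales import STANDARD_AMINO_ACIDS

    return "".join(STANDARD_AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


@pytest.fixture(scope="session")
def small_dataset():
    """120 planted-signal pairs, short sequences: quick but learnable."""
    return generate_pair_dataset(
        SyntheticConfig(
            n_pos=60, n_neg=60, seed=5, length_range=(16, 32), test_fraction=0.25
        )
    )


@pytest.fixture(scope="session")
def small_rf(small_dataset, scale_set):
    return rm.train_rf(small_dataset, scale_set, rm.RFConfig(n_trees=80, seed=0))


# --- full-scale benchmark (shared by the acceptance suite) -----------------

BENCH_CONFIG = SyntheticConfig(
    n_pos=1250, n_neg=1250, seed=11, length_range=(16, 32), test_fraction=0.2
)


@pytest.fixture(scope="session")
def bench_dataset():
    """2000 train / 500 test pairs with a planted hydrophobicity-channel signal."""
    ds = generate_pair_dataset(BENCH_CONFIG)
    assert len(ds.train) == 2000 and len(ds.test) == 500
    return ds


@pytest.fixture(scope="session")
def bench_rf(bench_dataset, scale_set):
    return rm.train_rf(bench_dataset, scale_set, rm.RFConfig(n_trees=750, seed=0))


@pytest.fixture(scope="session")
def bench_gnn(bench_dataset, scale_set):
    from seqppi import gnn_model as gm

    cfg = gm.GNNConfig(epochs=200, refine_epochs=0, learning_rate=1e-3, seed=0)
    return gm.train_gnn(bench_dataset, cfg, scale_set)
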