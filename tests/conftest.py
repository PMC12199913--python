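import numpy as np
import pytest

from omsite import SequenceWindow, SyntheticConfig, assemble_dataset, generate
from omsite.sequence_io import ALPHABET, WINDOW_LENGTH


def random_window(rng: np.random.Generator, label=None) -> SequenceWindow:
    residues = "".join(rng.choice(list(ALPHABET), size=WINDOW_LENGTH))
    return SequenceWindow(residues, label=label)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def separable_dataset():
    """Small encoded dataset with strong downstream-G signal (60+60)."""
    windows = generate(SyntheticConfig(n_pos=60, n_neg=60, seed=11))
    table, labels = assemble_dataset(windows)
    return table, labels.astype(int).to_numpy()


@pytest.fixture(scope="session")
def null_dataset():
    """Encoded dataset with no class signal (p_enriched = background)."""
    windows = generate(SyntheticConfig(n_pos=60, n_neg=60, p_enriched=0.25, seed=12))
    table, labels = assemble_dataset(windows)
    return table, labels.astype(int).to_numpy()
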