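import numpy as np
import pytest

from planarian_triage.synthetic_data import SimConfig


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A small but fully featured simulation configuration."""
    return SimConfig(seed=11, n_transcripts=80, repeat_copies=20,
                     sc_cells_per_cluster=20)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20180824)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
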