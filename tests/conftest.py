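import numpy as np
import pytest
from hypothesis import settings

from ccsbimodal.synth import GroundTruthModel, SimulationConfig, make_dataset

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_truth() -> GroundTruthModel:
    return GroundTruthModel.default()


@pytest.fixture(scope="session")
def small_dataset(default_truth):
    """A modest synthetic cohort shared across read-only tests."""
    return make_dataset(SimulationConfig(n=3000), seed=0, truth=default_truth)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_sequences(rng, n, min_len=15, max_len=30, terminus="RK"):
    """Arbitrary alphabet-valid sequences ending in R/K (tryptic-like)."""
    from ccsbimodal.records import AMINO_ACIDS

    seqs = []
    for _ in range(n):
        length = int(rng.integers(min_len, max_len + 1))
        body = rng.choice(list(AMINO_ACIDS), size=length)
        body[-1] = terminus[int(rng.integers(0, len(terminus)))]
        seqs.append("".join(body))
    return seqs
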