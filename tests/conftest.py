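import numpy as np
import pytest

from twochain.model import HPSequence, ModelParameters
from twochain.sampler import SampleEnsemble


@pytest.fixture(scope="session")
def hp_params() -> ModelParameters:
    return ModelParameters(epsilon=1.0)


@pytest.fixture(scope="session")
def single_bead_pmf(hp_params):
    """Sampled PMF of two single H beads; the exact answer is the pair
    potential, which makes this the workhorse physics fixture."""
    from twochain.sampler import sample_two_chain_pmf

    seq = HPSequence("bead", "H")
    windows, pmf = sample_two_chain_pmf(
        seq, hp_params, n_sweeps=20_000, seed=11, r_max=5.0
    )
    return seq, windows, pmf


@pytest.fixture()
def random_ensemble() -> SampleEnsemble:
    """Small random two-chain ensemble (no physics, geometry only)."""
    rng = np.random.default_rng(7)
    states = rng.uniform(-2.0, 2.0, size=(40, 2, 5, 3))
    return SampleEnsemble(states=states, sequence=None, stride=1, seed=7)
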