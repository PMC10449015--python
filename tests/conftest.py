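import numpy as np
import pytest

from combatcor import (
    SimScenario,
    build_design,
    simulate_dataset,
    unbalanced_design,
)


@pytest.fixture(scope="session")
def unbal():
    """The 57-sample unbalanced five-batch design (11/0, 14/4, 0/4, 0/5, 15/4)."""
    return unbalanced_design()


@pytest.fixture
def toy22():
    """Smallest balanced 2-group x 2-batch design."""
    return build_design(["A", "A", "B", "B"], ["1", "2", "1", "2"])


@pytest.fixture(scope="session")
def smallsim(unbal):
    """A compact unbalanced small/small dataset for fast integration tests."""
    s = SimScenario(design=unbal, mean_level="small", var_level="small",
                    n_genes=2_000, de_spec=((2.0, 50), (1.0, 50), (-1.0, 50), (-2.0, 50)),
                    seed=11)
    return simulate_dataset(s)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
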