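import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from plastocompare.synthetic_data import generate_cohort, small_plan


def random_seq(rng: np.random.Generator, n: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=n))


@pytest.fixture(scope="session")
def small_cohort():
    """One shared 10 kb synthetic cohort (ancestor + 4 evolved taxa)."""
    plan = small_plan(42, taxa=4)
    genome, features, truth, taxa = generate_cohort(plan)
    return plan, genome, features, truth, taxa


@pytest.fixture()
def rng():
    return np.random.default_rng(20181537)
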