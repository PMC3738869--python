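import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from camkit.fixtures import load_paper_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return load_paper_fixtures()


@pytest.fixture()
def rng():
    return np.random.default_rng(20130315)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
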