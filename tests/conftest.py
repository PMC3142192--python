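import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from starpick.energy import ToyEngine


@pytest.fixture(scope="session")
def toy_engine():
    return ToyEngine()


@pytest.fixture()
def rng():
    return np.random.default_rng(20110722)


def random_rna(rng, n, p=None):
    return "".join(rng.choice(list("ACGU"), size=n, p=p))
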