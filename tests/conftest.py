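import numpy as np
import pytest
from hypothesis import settings

from ichtriage.expert import LogicTable
from ichtriage.synthetic import Templates
from ichtriage.text_extraction import Lexicon

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lexicon() -> Lexicon:
    return Lexicon.default()


@pytest.fixture(scope="session")
def table() -> LogicTable:
    return LogicTable.default()


@pytest.fixture(scope="session")
def templates() -> Templates:
    return Templates.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
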