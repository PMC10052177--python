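import sys
from pathlib import Path

import pytest

# make the sibling oracle helpers importable regardless of rootdir
sys.path.insert(0, str(Path(__file__).parent))

from rnaorder.system_model import AVOGADRO


@pytest.fixture(scope="session")
def one_mol() -> float:
    """Total unit count for one mole of units."""
    return AVOGADRO
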