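import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from psimpra import PseudouridylationPocket


@pytest.fixture
def pocket_10_10():
    """A pocket with 11-nt guides (supports the full 10/10 window)."""
    return PseudouridylationPocket("snoA", 1, "ACGTACGTACG", "CAGTCAGTCAG")


@pytest.fixture
def pocket_short():
    """Guides shorter than the 8/10-nt windows (forces truncation)."""
    return PseudouridylationPocket("snoB", 2, "ACGG", "CAGT")
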