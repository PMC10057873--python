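import random

import pytest

from oryzapep.proteolysis import default_rules
from oryzapep.sequences import load_fragment_list, rice_glutelin, rice_prolamin


@pytest.fixture(scope="session")
def prolamin_fragments():
    """Published hydrolysis fragment list of rice prolamin, in order."""
    return load_fragment_list("prolamin_fragments.txt")


@pytest.fixture(scope="session")
def glutelin_fragments():
    return load_fragment_list("glutelin_fragments.txt")


@pytest.fixture(scope="session")
def prolamin():
    return rice_prolamin()


@pytest.fixture(scope="session")
def glutelin():
    return rice_glutelin()


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture
def rng():
    return random.Random(20230440)


def brute_force_digest(sequence, rules):
    """Independent position-by-position digestion oracle.

    Walks every bond of the sequence and splits wherever any rule's P1/P1'
    condition holds; kept free of the engine's cut-site machinery.
    """
    pieces, current = [], sequence[0]
    for i in range(1, len(sequence)):
        prev, nxt = sequence[i - 1], sequence[i]
        if any(prev in r.cut_after and nxt not in r.not_before for r in rules):
            pieces.append(current)
            current = nxt
        else:
            current += nxt
    pieces.append(current)
    return pieces
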