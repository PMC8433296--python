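import random

import pytest

from dnastore import (
    PrimerConstraints,
    StorageConfig,
    ToolRegistry,
    generate_primer_library,
)


@pytest.fixture(scope="session")
def config():
    return StorageConfig()  # L_s=220, L_p=20, rotating codec


@pytest.fixture(scope="session")
def primer_pairs():
    """A library big enough for any small-corpus plan (8 pairs)."""
    return generate_primer_library(8, L_p=20, seed=42)


@pytest.fixture()
def registry():
    reg = ToolRegistry()
    reg.register(101, "deflate", blob=b"\x01" * 64)
    reg.register(102, "lzma", blob=b"\x02" * 64)
    return reg


@pytest.fixture()
def rng():
    return random.Random(1234)


@pytest.fixture(scope="session")
def loose_constraints():
    """Cheap constraints for tests that only need a valid library fast."""
    return PrimerConstraints(min_pairwise_distance=6)
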