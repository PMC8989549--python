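import numpy as np
import pytest

from ribodrop.library_design import HISTAMINE_ON_DESIGN, LibraryDesign


@pytest.fixture(scope="session")
def on_design() -> LibraryDesign:
    return HISTAMINE_ON_DESIGN


@pytest.fixture(scope="session")
def tiny_design() -> LibraryDesign:
    """A 20-variant design (lengths 1 and 2) with short, parseable flanks."""
    return LibraryDesign(
        name="tiny",
        upstream_constant="ACGTACGTAA",
        degenerate_lengths=frozenset({1, 2}),
        downstream_constant="CTGATCGGAT",
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
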