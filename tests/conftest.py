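import random

import pytest

from speclibkit import testkit
from speclibkit.cv import load_bundled_registry


@pytest.fixture(scope="session")
def registry():
    return load_bundled_registry()


@pytest.fixture(scope="session")
def fixture_spec():
    return testkit.FixtureSpec(
        n_spectra=4, peaks_per_spectrum=10, fraction_unidentified=0.25, seed=42
    )


@pytest.fixture(scope="session")
def fixture_library(fixture_spec):
    return testkit.generate_fixture(fixture_spec)


@pytest.fixture()
def rng():
    return random.Random(20240)
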