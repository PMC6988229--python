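import pytest

from alpform.motif_scan import MYRISTOYLATION_PATTERN, parse_pattern
from alpform.report import load_reference_bands, load_reference_masses
from alpform.seq_model import MassTable


@pytest.fixture(scope="session")
def mass_table():
    return MassTable()


@pytest.fixture(scope="session")
def myristoylation():
    return parse_pattern(MYRISTOYLATION_PATTERN, name="myristoylation")


@pytest.fixture(scope="session")
def reference_masses():
    """Per-homolog mass summary for Mace and Spitfire (packaged data)."""
    return load_reference_masses()


@pytest.fixture(scope="session")
def reference_bands():
    """The 59-row band/peak/identity transcription (packaged data)."""
    return load_reference_bands()
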