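import pytest

from parsalign import parse_blocked_msa
from parsalign.synthetic import FamilySpec, generate_blocked_family

TOY_TEXT = ">A\nMK--iv--MR\n>B\nMQ--w---MR\n"


@pytest.fixture
def toy_msa():
    """Two sequences, two aligned blocks around one unaligned region."""
    return parse_blocked_msa(TOY_TEXT)


@pytest.fixture(scope="session")
def small_family():
    """A 2-group kinase-like family reused across modules (read-only)."""
    return generate_blocked_family(
        FamilySpec(n_groups=2, seqs_per_group=8, seed=42)
    )
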