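import pytest

from primerscope import Primer, ScoringConfig


@pytest.fixture
def toy_primer():
    """4-mer forward primer with a 2-base 3' region for hand-checkable scores."""
    return Primer("toy", "ACGT", "forward", 1, 4)


@pytest.fixture
def toy_config():
    return ScoringConfig(three_prime_len=2)


@pytest.fixture
def default_config():
    return ScoringConfig()


def make_primer(seq, name="p", orientation="forward", start=1):
    return Primer(name, seq, orientation, start, start + len(seq) - 1)
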