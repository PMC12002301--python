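import pytest

from bombemine.synthetic import make_precursor, make_proteome


@pytest.fixture(scope="session")
def planted():
    """One planted precursor with its truth record."""
    return make_precursor(seed=11)


@pytest.fixture(scope="session")
def small_proteome():
    """Planted + decoy proteome used by discovery tests."""
    return make_proteome(seed=11, n_planted=10, n_decoys=100)
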