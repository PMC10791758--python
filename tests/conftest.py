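import pytest

from dairyfert.pedigree import Pedigree



@pytest.fixture
def trio() -> Pedigree:
    return Pedigree.from_triples([("C", "A", "B")])


@pytest.fixture
def fullsib_mating() -> Pedigree:
    """Offspring of a full-sib mating: F = 0.25."""
    return Pedigree.from_triples(
        [
            ("S", "GP", "GM"),
            ("D", "GP", "GM"),
            ("X", "S", "D"),
        ]
    )


@pytest.fixture(scope="session")
def small_fixture():
    from dairyfert.simulate import fixture_small

    return fixture_small()
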