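import pytest

from tiger.engine import KmerMatchEngine
from tiger.fixtures import FixtureSpec, IgeSpec, RefSpec, generate_fixture
from tiger.model import GeneClass


@pytest.fixture(scope="session")
def engine():
    return KmerMatchEngine()


@pytest.fixture(scope="session")
def simple_fixture():
    """One 8-kb planted element with a 45-bp DR, 3 clean references and one
    reference still carrying the element."""
    spec = FixtureSpec(
        seed=1, replicon_len=60_000,
        iges=[IgeSpec("A", 30_000, interior_len=8_000, dr_len=45,
                      target_klass=GeneClass.TRNA, target_name="Arg")],
        n_clean_refs=3, n_same_ige_refs=1,
    )
    return generate_fixture(spec)


@pytest.fixture(scope="session")
def tandem_fixture():
    """Two elements integrated in tandem at one attB, with references
    carrying each flank combination."""
    spec = FixtureSpec(
        seed=7, replicon_len=80_000,
        iges=[IgeSpec("A", 40_000, interior_len=7_000, dr_len=40),
              IgeSpec("B", 40_000, interior_len=6_000, dr_len=40)],
        refs=[RefSpec("none"), RefSpec("onlyA", frozenset({"A"})),
              RefSpec("onlyB", frozenset({"B"}))],
    )
    return generate_fixture(spec)


@pytest.fixture(scope="session")
def isolated_fixture():
    """The same element as in the tandem, isolated, with 3 clean refs —
    for comparing support values."""
    spec = FixtureSpec(
        seed=7, replicon_len=80_000,
        iges=[IgeSpec("A", 40_000, interior_len=7_000, dr_len=40)],
        n_clean_refs=3,
    )
    return generate_fixture(spec)
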