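import pytest

from edgestrand.fixtures import SheetSpec, make_structure
from edgestrand.pdbio import parse_structure


@pytest.fixture(scope="session")
def open_spec():
    return SheetSpec(sequence_plan=["mid", "high", "mid", "mid"], seed=7)


@pytest.fixture(scope="session")
def open_text(open_spec):
    return make_structure(open_spec)


@pytest.fixture(scope="session")
def open_structure(open_text):
    return parse_structure(open_text)


@pytest.fixture(scope="session")
def barrel_structure():
    spec = SheetSpec(barrel=True, sequence_plan=["mid", "high", "mid", "mid"], seed=7)
    return parse_structure(make_structure(spec))


@pytest.fixture(scope="session")
def knotted_spec():
    return SheetSpec(
        sequence_plan=["mid", "high", "mid", "mid"], knotted_loops=frozenset({2}), seed=7
    )


@pytest.fixture(scope="session")
def knotted_structure(knotted_spec):
    return parse_structure(make_structure(knotted_spec))
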