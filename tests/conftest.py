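import pytest

from babeldx.fixtures import CorpusSpec, gen_cases, gen_mini_ontologies
from babeldx.ontology import OntologyGraph, OntologyTerm, TermId


@pytest.fixture(scope="session")
def default_spec():
    return CorpusSpec(seed=42)


@pytest.fixture(scope="session")
def mini_onts(default_spec):
    return gen_mini_ontologies(default_spec)


@pytest.fixture(scope="session")
def mini_cases(default_spec, mini_onts):
    return gen_cases(default_spec, mini_onts)


@pytest.fixture
def chain_graph():
    """C is_a B is_a A."""
    a, b, c = TermId("X:A"), TermId("X:B"), TermId("X:C")
    return OntologyGraph(
        {
            a: OntologyTerm(id=a, label="A"),
            b: OntologyTerm(id=b, label="B", parents=[a]),
            c: OntologyTerm(id=c, label="C", parents=[b]),
        }
    )


@pytest.fixture
def diamond_graph():
    """D is_a B, D is_a C; B and C is_a A."""
    a, b, c, d = (TermId(f"X:{x}") for x in "ABCD")
    return OntologyGraph(
        {
            a: OntologyTerm(id=a, label="A"),
            b: OntologyTerm(id=b, label="B", parents=[a]),
            c: OntologyTerm(id=c, label="C", parents=[a]),
            d: OntologyTerm(id=d, label="D", parents=[b, c]),
        }
    )
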