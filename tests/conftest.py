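"""Shared fixtures: tiny hand-built ontologies and annotation maps."""

import pytest

from phosgo import GOTerm, OntologyDAG

BP = "biological_process"
MF = "molecular_function"


def term(tid, parents=(), namespace=BP, name="", obsolete=False):
    return GOTerm(id=tid, name=name or tid, namespace=namespace,
                  parents=list(parents), obsolete=obsolete)


@pytest.fixture
def chain_dag():
    """R <- M <- L (is_a chain)."""
    return OntologyDAG({
        "GO:0000001": term("GO:0000001"),
        "GO:0000002": term("GO:0000002", [("GO:0000001", "is_a")]),
        "GO:0000003": term("GO:0000003", [("GO:0000002", "is_a")]),
    })


@pytest.fixture
def diamond_dag():
    """Two paths from D to the root R: D->A->R (is_a) and D->B->R (part_of then is_a)."""
    return OntologyDAG({
        "GO:0000001": term("GO:0000001"),
        "GO:0000002": term("GO:0000002", [("GO:0000001", "is_a")]),
        "GO:0000003": term("GO:0000003", [("GO:0000001", "is_a")]),
        "GO:0000004": term("GO:0000004", [("GO:0000002", "is_a"),
                                          ("GO:0000003", "part_of")]),
    })


@pytest.fixture
def sibling_dag():
    """A and B both is_a R."""
    return OntologyDAG({
        "GO:0000001": term("GO:0000001"),
        "GO:0000002": term("GO:0000002", [("GO:0000001", "is_a")]),
        "GO:0000003": term("GO:0000003", [("GO:0000001", "is_a")]),
    })


TOY_OBO = """format-version: 1.2
ontology: go

[Term]
id: GO:0000001
name: root process
namespace: biological_process

[Term]
id: GO:0000002
name: child a
namespace: biological_process
alt_id: GO:0000099
is_a: GO:0000001 ! root process

[Term]
id: GO:0000003
name: child b
namespace: biological_process
relationship: part_of GO:0000002 ! child a
relationship: regulates GO:0000001 ! dropped on parse

[Term]
id: GO:0000004
name: gone
namespace: biological_process
is_obsolete: true

[Typedef]
id: part_of
name: part of
"""


@pytest.fixture
def toy_obo_text():
    return TOY_OBO
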