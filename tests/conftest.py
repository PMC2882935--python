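"""Shared fixtures: hand-built toy ontologies and generated scenarios."""

from __future__ import annotations

import io

import pytest

from funsimnet import synthetic_data
from funsimnet.ontology import AnnotationCorpus, compute_ic, parse_obo

CHAIN_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: a
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: b
namespace: biological_process
is_a: GO:0000002
"""

# diamond: leaf has two parents, both children of the root
DIAMOND_OBO = """\
format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: left parent
namespace: biological_process
is_a: GO:0000001

[Term]
id: GO:0000003
name: right parent
namespace: biological_process
relationship: part_of GO:0000001

[Term]
id: GO:0000004
name: leaf
namespace: biological_process
is_a: GO:0000002
is_a: GO:0000003
"""


@pytest.fixture(scope="session")
def chain_dag():
    return parse_obo(io.StringIO(CHAIN_OBO))


@pytest.fixture(scope="session")
def diamond_dag():
    return parse_obo(io.StringIO(DIAMOND_OBO))


@pytest.fixture(scope="session")
def diamond_corpus(diamond_dag):
    """Closed counts: leaf 2, left parent 3, right parent 4, root 10."""
    direct = {}
    # 2 proteins on the leaf (closure adds both parents and the root)
    for i in range(2):
        direct[f"leaf{i}"] = {"GO:0000004"}
    # 1 more on the left parent, 2 more on the right parent
    direct["left0"] = {"GO:0000002"}
    for i in range(2):
        direct[f"right{i}"] = {"GO:0000003"}
    # remaining proteins only at the root, bringing the root count to 10
    for i in range(5):
        direct[f"bg{i}"] = {"GO:0000001"}
    return AnnotationCorpus(dag=diamond_dag, direct=direct)


@pytest.fixture(scope="session")
def diamond_ic(diamond_dag, diamond_corpus):
    return compute_ic(diamond_dag, diamond_corpus,
                      require_all_namespaces=False)


@pytest.fixture(scope="session")
def smoke_data():
    return synthetic_data.generate_scenario(synthetic_data.smoke_scenario(7))


@pytest.fixture(scope="session")
def smoke_loaded(smoke_data):
    from funsimnet.ontology import read_gaf

    dag = parse_obo(io.StringIO(smoke_data.files["go.obo"]))
    corpus = AnnotationCorpus.from_pairs(
        dag, read_gaf(io.StringIO(smoke_data.files["annot.gaf"])))
    ic = compute_ic(dag, corpus, require_all_namespaces=False)
    return dag, corpus, ic


@pytest.fixture(scope="session")
def paper_shaped_data():
    return synthetic_data.generate_scenario(
        synthetic_data.paper_shaped_scenario(11))
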