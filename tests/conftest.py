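"""Shared fixtures: tiny hand-built ontologies and fast synthetic worlds."""

from __future__ import annotations

import textwrap

import networkx as nx
import pytest

from unicorn import (
    AnnotationSet,
    OntologyDAG,
    PipelineConfig,
    SearchParams,
    generate_world,
    propagate_annotations,
)


def make_dag(edges: list[tuple[str, str]], nodes: list[str] | None = None) -> OntologyDAG:
    """Ontology DAG from (child, parent) pairs."""
    g = nx.DiGraph()
    if nodes:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return OntologyDAG(graph=g, namespace="test")


def make_annotations(dag: OntologyDAG, direct: dict[str, set[str]]) -> AnnotationSet:
    return propagate_annotations(dag, direct)


@pytest.fixture
def chain_dag() -> OntologyDAG:
    """A <- B <- C chain (A is the root)."""
    return make_dag([("C", "B"), ("B", "A")])


@pytest.fixture
def diamond_dag() -> OntologyDAG:
    """A <- {B, C} <- D diamond."""
    return make_dag([("D", "B"), ("D", "C"), ("B", "A"), ("C", "A")])


@pytest.fixture
def chain_obo(tmp_path):
    """OBO file with a 3-term chain plus an obsolete term and another namespace."""
    text = textwrap.dedent(
        """\
        format-version: 1.2

        [Term]
        id: GO:0000001
        name: alpha
        namespace: main

        [Term]
        id: GO:0000002
        name: beta
        namespace: main
        alt_id: GO:0000099
        is_a: GO:0000001

        [Term]
        id: GO:0000003
        name: gamma
        namespace: main
        relationship: part_of GO:0000002

        [Term]
        id: GO:0000010
        name: elsewhere
        namespace: other

        [Term]
        id: GO:0000011
        name: gone
        namespace: main
        is_obsolete: true
        """
    )
    path = tmp_path / "chain.obo"
    path.write_text(text)
    return path


@pytest.fixture(scope="session")
def fast_config() -> PipelineConfig:
    """Reduced search effort for end-to-end tests that are not about search depth."""
    return PipelineConfig(
        seed=7,
        search=SearchParams(k=50, max_iterations=1000, restarts=2, seed=7),
        n_perm=30,
    )


@pytest.fixture(scope="session")
def small_world():
    """A 32-gene depth-4 binary-tree world: fast but non-degenerate."""
    return generate_world(n_genes=32, depth=4, branching=2, seed=7)
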