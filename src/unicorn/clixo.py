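"""Clique-based hierarchical DAG inference from a weighted network.

Starting from one singleton term per gene, a similarity threshold sweeps
down the distinct edge weights of the network.  At each threshold, edges
whose weight is within ``alpha`` of the threshold are considered present,
and groups of current top-level terms whose combined gene set is a
near-clique (edge density at least 1 - ``beta``) merge into a new term
that becomes the parent of each member.  Progressively loosening the
threshold grows a hierarchy in which every child gene set is a strict
subset of its parents' and every leaf is a single gene.

``alpha`` widens the edge-inclusion band to absorb noise in the weights;
``beta`` is the tolerated fraction of missing edges inside a term, letting
imperfect cliques form terms.  With alpha = beta = 0 on an ultrametric
network the procedure recovers the planted cluster hierarchy exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .netio import WeightedNetwork

__all__ = ["InferredDAG", "infer_dag", "export_dag", "read_dag"]


@dataclass
class InferredDAG:
    """DAG of candidate terms, each a gene set; links point child -> parent."""

    term_genes: dict[str, frozenset[str]]
    links: set[tuple[str, str]]
    alpha: float = 0.0
    beta: float = 0.5
    birth_threshold: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, parent in self.links:
            if not self.term_genes[child] < self.term_genes[parent]:
                raise ValueError(
                    f"child {child!r} gene set is not a strict subset of parent {parent!r}"
                )
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("inferred term links contain a cycle")

    @property
    def terms(self) -> set[str]:
        return set(self.term_genes)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self.term_genes.values():
            out |= gs
        return out

    def non_singleton_terms(self) -> set[str]:
        return {t for t, gs in self.term_genes.items() if len(gs) > 1}

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.term_genes)
        g.add_edges_from(self.links)
        return g

    def ancestors(self, term: str) -> set[str]:
        return nx.descendants(self.to_networkx(), term)

    def __len__(self) -> int:
        return len(self.term_genes)


def _density(graph: nx.Graph, genes: frozenset[str]) -> float:
    n = len(genes)
    if n < 2:
        return 1.0
    possible = n * (n - 1) / 2
    return graph.subgraph(genes).number_of_edges() / possible


def infer_dag(
    net: WeightedNetwork,
    alpha: float = 0.0,
    beta: float = 0.5,
    max_rounds_per_threshold: int = 100,
) -> InferredDAG:
    """Infer a term DAG from a weighted network by a descending-threshold sweep.

    The threshold grid is the sorted distinct edge weights.  At threshold
    t, edges with weight >= t - alpha are present; maximal groups of
    mutually compatible top-level terms (pairwise union density >=
    1 - beta) whose full union also reaches that density merge into a new
    parent term.  Terms duplicating an existing gene set are pruned.
    Deterministic: candidate groups are processed largest union first,
    ties broken lexicographically.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    if not 0 <= beta <= 1:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    genes = sorted(net.genes)
    if not genes:
        return InferredDAG({}, set(), alpha=alpha, beta=beta)

    term_genes: dict[str, frozenset[str]] = {}
    birth: dict[str, float] = {}
    links: set[tuple[str, str]] = set()
    by_geneset: dict[frozenset[str], str] = {}
    top: set[str] = set()
    for g in genes:
        tid = f"gene:{g}"
        term_genes[tid] = frozenset([g])
        by_geneset[frozenset([g])] = tid
        top.add(tid)
    counter = 0

    edges_desc = sorted(net.weights.items(), key=lambda kv: (-kv[1], kv[0]))
    thresholds = sorted({w for _, w in edges_desc}, reverse=True)
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    ptr = 0
    min_density = 1.0 - beta

    for t in thresholds:
        while ptr < len(edges_desc) and edges_desc[ptr][1] >= t - alpha:
            (a, b), _ = edges_desc[ptr]
            graph.add_edge(a, b)
            ptr += 1
        for _ in range(max_rounds_per_threshold):
            if len(top) < 2:
                break
            # meta-graph: top-level terms compatible pairwise
            tops = sorted(top)
            meta = nx.Graph()
            meta.add_nodes_from(tops)
            for i, u in enumerate(tops):
                gu = term_genes[u]
                for v in tops[i + 1 :]:
                    union = gu | term_genes[v]
                    if _density(graph, union) >= min_density:
                        meta.add_edge(u, v)
            candidates = [c for c in nx.find_cliques(meta) if len(c) > 1]
            if not candidates:
                break
            merged_any = False
            # largest union first, then lexicographic, for determinism
            def key(c: list[str]):
                union = frozenset().union(*(term_genes[m] for m in c))
                return (-len(union), tuple(sorted(c)))

            for clique in sorted(candidates, key=key):
                members = [m for m in clique if m in top]
                if len(members) < 2:
                    continue
                union = frozenset().union(*(term_genes[m] for m in members))
                if _density(graph, union) < min_density:
                    continue
                existing = by_geneset.get(union)
                if existing is not None:
                    # duplicate gene set: attach members under the existing
                    # term instead of creating a copy
                    for m in members:
                        if m != existing and (m, existing) not in links:
                            links.add((m, existing))
                            top.discard(m)
                            merged_any = True
                    continue
                counter += 1
                tid = f"term_{counter:04d}"
                term_genes[tid] = union
                by_geneset[union] = tid
                birth[tid] = t
                for m in members:
                    links.add((m, tid))
                    top.discard(m)
                top.add(tid)
                merged_any = True
            if not merged_any:
                break
        if len(top) < 2:
            break

    return InferredDAG(
        term_genes=term_genes,
        links=links,
        alpha=alpha,
        beta=beta,
        birth_threshold=birth,
    )


def export_dag(dag: InferredDAG, path: str | Path) -> None:
    """Write the DAG as two tab-separated tables.

    ``<path>.relations.tsv`` holds (child, parent, relation) rows and
    ``<path>.annotations.tsv`` holds (term, gene) rows; together they
    round-trip through :func:`read_dag`.
    """
    path = Path(path)
    with open(f"{path}.relations.tsv", "w") as fh:
        fh.write("child\tparent\trelation\n")
        for child, parent in sorted(dag.links):
            fh.write(f"{child}\t{parent}\tis_a\n")
    with open(f"{path}.annotations.tsv", "w") as fh:
        fh.write("term\tgene\n")
        for term in sorted(dag.term_genes):
            for gene in sorted(dag.term_genes[term]):
                fh.write(f"{term}\t{gene}\n")


def read_dag(path: str | Path) -> InferredDAG:
    """Read a DAG written by :func:`export_dag`."""
    path = Path(path)
    term_genes: dict[str, set[str]] = {}
    with open(f"{path}.annotations.tsv") as fh:
        next(fh)
        for line in fh:
            term, gene = line.rstrip("\n").split("\t")
            term_genes.setdefault(term, set()).add(gene)
    links: set[tuple[str, str]] = set()
    with open(f"{path}.relations.tsv") as fh:
        next(fh)
        for line in fh:
            child, parent, _rel = line.rstrip("\n").split("\t")
            links.add((child, parent))
    return InferredDAG(
        term_genes={t: frozenset(g) for t, g in term_genes.items()}, links=links
    )
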