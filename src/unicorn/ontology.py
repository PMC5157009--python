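"""Reference-ontology handling: parsing, annotation propagation, training
sub-tree selection and semantic similarity.

The ontology is a rooted DAG of terms (multiple parents allowed).  A gene
annotated to a term is implicitly annotated to every ancestor of that term,
so annotation sets are stored both as given (``direct``) and after upward
closure (``propagated``).

Gene-gene similarity uses a simplified Resnik measure: the information
content of the most informative common ancestor of the two genes, computed
from annotation counts within a chosen training sub-tree and normalised to
[0, 1] by its maximum attainable value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyDAG",
    "AnnotationSet",
    "TrainingSet",
    "load_ontology",
    "read_annotations",
    "propagate_annotations",
    "select_training_subtrees",
    "resnik_similarity",
    "training_pair_similarities",
]


def _pair(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered gene pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class OntologyDAG:
    """A single-namespace ontology DAG.

    ``graph`` is a :class:`networkx.DiGraph` whose edges point from child
    term to parent term; ontological ancestors of a term are therefore the
    nodes reachable *from* it.
    """

    graph: nx.DiGraph
    namespace: str = ""
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("parent relation graph contains a cycle")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def ancestors(self, term: str) -> set[str]:
        """Proper ontological ancestors (parents, grandparents, ...)."""
        return nx.descendants(self.graph, term)

    def descendants(self, term: str) -> set[str]:
        """Proper ontological descendants."""
        return nx.ancestors(self.graph, term)

    def subtree_terms(self, root: str) -> set[str]:
        """``root`` together with every descendant term."""
        if root not in self.graph:
            raise KeyError(f"unknown term {root!r}")
        return {root} | self.descendants(root)

    def levels(self) -> dict[str, int]:
        """Term level: shortest directed path to a root, root at level 1."""
        rev = self.graph.reverse(copy=False)  # parent -> child
        lvl: dict[str, int] = {}
        for root in self.roots:
            for t, d in nx.single_source_shortest_path_length(rev, root).items():
                cur = lvl.get(t)
                if cur is None or d + 1 < cur:
                    lvl[t] = d + 1
        return lvl

    def resolve(self, term: str) -> str:
        """Map an alternative term id to its primary id (identity otherwise)."""
        return self.alt_ids.get(term, term)


@dataclass
class AnnotationSet:
    """Gene-to-term annotations, direct and after ancestor closure."""

    direct: dict[str, frozenset[str]]
    propagated: dict[str, frozenset[str]]
    skipped_records: int = 0

    @property
    def genes(self) -> set[str]:
        return set(self.propagated)

    def genes_annotated_to(self, terms: Iterable[str]) -> set[str]:
        """Genes annotated (after propagation) to at least one of ``terms``."""
        terms = set(terms)
        return {g for g, ts in self.propagated.items() if ts & terms}

    def term_gene_counts(self, genes: Iterable[str] | None = None) -> dict[str, int]:
        """Number of annotated genes per term, optionally over a gene subset."""
        pool = self.propagated if genes is None else {
            g: self.propagated[g] for g in genes if g in self.propagated
        }
        counts: dict[str, int] = {}
        for ts in pool.values():
            for t in ts:
                counts[t] = counts.get(t, 0) + 1
        return counts


@dataclass
class TrainingSet:
    """All unordered pairs of training genes with normalised similarities."""

    pairs: list[tuple[str, str]]
    similarity: dict[tuple[str, str], float]
    t_s: float = 0.3
    root: str | None = None

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair ({a}, {b}) in training set")
        bad = [p for p, s in self.similarity.items() if not 0.0 <= s <= 1.0 + 1e-12]
        if bad:
            raise ValueError(f"similarity outside [0, 1] for pairs {bad[:3]}")

    @property
    def genes(self) -> set[str]:
        return {g for p in self.pairs for g in p}

    @property
    def similar_pairs(self) -> set[tuple[str, str]]:
        """Pairs deemed semantically similar (similarity >= t_s)."""
        return {p for p in self.pairs if self.similarity[p] >= self.t_s}

    def is_similar(self, a: str, b: str) -> bool:
        return self.similarity[_pair(a, b)] >= self.t_s

    def __len__(self) -> int:
        return len(self.pairs)


def load_ontology(path: str | Path, namespace: str) -> OntologyDAG:
    """Parse an OBO file and return the DAG of one namespace.

    Keeps ``is_a`` and ``part_of`` links, drops obsolete terms, and records
    alternative ids so that annotations can be resolved to primary ids.

    Raises ``ValueError`` on an unknown namespace (naming the available
    ones) or if the links form a cycle.
    """
    multi = obonet.read_obo(path, ignore_obsolete=True)
    namespaces = {d.get("namespace", "") for _, d in multi.nodes(data=True)}
    if namespace not in namespaces:
        raise ValueError(
            f"namespace {namespace!r} not in file; available: {sorted(namespaces)}"
        )
    keep = {t for t, d in multi.nodes(data=True) if d.get("namespace", "") == namespace}
    g = nx.DiGraph()
    g.add_nodes_from(
        (t, {"name": multi.nodes[t].get("name", t)}) for t in keep
    )
    for child, parent, rel in multi.edges(keys=True):
        if rel in ("is_a", "part_of") and child in keep and parent in keep:
            g.add_edge(child, parent, relation=rel)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"ontology links form a cycle: {cycle}")
    alt: dict[str, str] = {}
    for t in keep:
        for a in multi.nodes[t].get("alt_id", []):
            alt[a] = t
    return OntologyDAG(graph=g, namespace=namespace, alt_ids=alt)


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column (gene, term) tab-separated annotation file.

    Extra columns (GAF-style) are tolerated: the first column is taken as
    the gene id and the first ``XX:``-prefixed column as the term id; plain
    two-column files use columns 1 and 2 directly.  Comment lines start
    with ``!`` or ``#``.
    """
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("!", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                continue
            gene = parts[0]
            term = next((p for p in parts[1:] if ":" in p), parts[1])
            direct.setdefault(gene, set()).add(term)
    return direct


def propagate_annotations(
    dag: OntologyDAG, direct: Mapping[str, Iterable[str]]
) -> AnnotationSet:
    """Close each gene's direct annotations over the ancestor relation.

    Annotations to unknown terms are skipped with a warning; the number of
    skipped records is kept on the result.  Alternative ids are resolved to
    primary ids first.
    """
    anc_cache: dict[str, set[str]] = {}
    out_direct: dict[str, frozenset[str]] = {}
    out_prop: dict[str, frozenset[str]] = {}
    skipped = 0
    for gene, terms in direct.items():
        kept: set[str] = set()
        prop: set[str] = set()
        for t in terms:
            t = dag.resolve(t)
            if t not in dag:
                skipped += 1
                continue
            kept.add(t)
            if t not in anc_cache:
                anc_cache[t] = dag.ancestors(t)
            prop |= anc_cache[t] | {t}
        if kept:
            out_direct[gene] = frozenset(kept)
            out_prop[gene] = frozenset(prop)
    if skipped:
        logger.warning("skipped %d annotation records to unknown terms", skipped)
    return AnnotationSet(direct=out_direct, propagated=out_prop, skipped_records=skipped)


def select_training_subtrees(
    dag: OntologyDAG, min_level: int = 2, max_level: int = 5
) -> list[str]:
    """Terms whose level lies in [min_level, max_level].

    Each returned term identifies a candidate training sub-tree: the term
    plus all of its descendants.  Level is the shortest directed path to
    the namespace root, with the root at level 1.
    """
    levels = dag.levels()
    return sorted(t for t, l in levels.items() if min_level <= l <= max_level)


def resnik_similarity(
    annotations: AnnotationSet,
    g_a: str,
    g_b: str,
    terms: set[str] | None = None,
) -> float:
    """Normalised simplified-Resnik similarity of two genes.

    ``annotations`` must be restricted to (or interpreted within) the
    training part; ``terms``, if given, limits common ancestors to the
    training sub-tree.  The score is

        -log(|G_LCA| / |G_tot|) / -log(1 / |G_tot|)

    where G_LCA is the gene set of the common-ancestor term with the
    largest information content and G_tot the full training gene set.
    Genes with no common ancestor score 0.
    """
    if g_a == g_b:
        raise ValueError("similarity is defined for two distinct genes")
    for g in (g_a, g_b):
        if g not in annotations.propagated:
            raise KeyError(f"gene {g!r} has no annotation in the training part")
    genes = annotations.genes
    n_tot = len(genes)
    if n_tot < 2:
        raise ValueError("need at least 2 annotated genes")
    common = set(annotations.propagated[g_a]) & set(annotations.propagated[g_b])
    if terms is not None:
        common &= terms
    if not common:
        return 0.0
    counts = annotations.term_gene_counts()
    n_lca = min(counts[t] for t in common)
    return math.log(n_tot / n_lca) / math.log(n_tot)


def training_pair_similarities(
    dag: OntologyDAG,
    training_root: str,
    annotations: AnnotationSet,
    t_s: float = 0.3,
) -> TrainingSet:
    """Similarity of every unordered pair of training genes.

    Training genes are the genes annotated to any term of the sub-tree
    rooted at ``training_root``.  Scores use annotation counts restricted
    to the training genes and common ancestors restricted to the sub-tree.
    """
    subtree = dag.subtree_terms(training_root)
    train_genes = sorted(annotations.genes_annotated_to(subtree))
    n_tot = len(train_genes)
    if n_tot < 2:
        raise ValueError(
            f"training sub-tree {training_root!r} has {n_tot} annotated genes; need >= 2"
        )
    # per-term counts over training genes, within the sub-tree
    counts: dict[str, int] = {}
    prop_sub: dict[str, frozenset[str]] = {}
    for g in train_genes:
        ts = frozenset(annotations.propagated[g] & subtree)
        prop_sub[g] = ts
        for t in ts:
            counts[t] = counts.get(t, 0) + 1
    log_tot = math.log(n_tot)
    pairs: list[tuple[str, str]] = []
    sim: dict[tuple[str, str], float] = {}
    for g_a, g_b in combinations(train_genes, 2):
        common = prop_sub[g_a] & prop_sub[g_b]
        if common:
            n_lca = min(counts[t] for t in common)
            score = math.log(n_tot / n_lca) / log_tot
        else:
            score = 0.0
        p = _pair(g_a, g_b)
        pairs.append(p)
        sim[p] = score
    return TrainingSet(pairs=pairs, similarity=sim, t_s=t_s, root=training_root)
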