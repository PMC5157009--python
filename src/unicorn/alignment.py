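"""Ontology alignment and held-out evaluation.

Terms of an inferred DAG are matched to terms of a reference ontology
using only their *intrinsic* similarity — the Jaccard overlap of the gene
sets they annotate — never their position in the hierarchy.  Matching is
greedy in descending score under two constraints: each term joins at most
one pair (one-to-one), and no two pairs may crisscross (the ancestor /
descendant order of the matched terms must not invert between the two
DAGs).  A score cutoff realizing a target false discovery rate is
calibrated against matchings of gene-label-permuted copies of the first
DAG.

Evaluation counts inferred terms aligned to reference terms outside the
training sub-tree, excluding inferred terms attributable to the training
part, yielding Hit, precision, recall and F-measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .clixo import InferredDAG
from .ontology import AnnotationSet, OntologyDAG

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetDAG",
    "AlignmentResult",
    "EvalMetrics",
    "term_similarity",
    "align",
    "flag_training_derived",
    "evaluate",
]


def term_similarity(genes_a: Iterable[str], genes_b: Iterable[str]) -> float:
    """Jaccard index of two term gene sets."""
    a, b = set(genes_a), set(genes_b)
    if not a or not b:
        raise ValueError("term gene sets must be non-empty")
    return len(a & b) / len(a | b)


@dataclass
class GeneSetDAG:
    """Uniform alignment view of a DAG: term gene sets plus hierarchy."""

    term_genes: dict[str, frozenset[str]]
    graph: nx.DiGraph  # edges child -> parent

    @classmethod
    def from_inferred(
        cls, dag: InferredDAG, include_singletons: bool = False
    ) -> "GeneSetDAG":
        keep = dag.terms if include_singletons else dag.non_singleton_terms()
        g = nx.DiGraph()
        g.add_nodes_from(keep)
        # contract links through dropped singletons
        full = dag.to_networkx()
        for t in keep:
            for anc in nx.descendants(full, t):
                if anc in keep:
                    g.add_edge(t, anc)
        return cls({t: dag.term_genes[t] for t in keep}, g)

    @classmethod
    def from_ontology(
        cls,
        dag: OntologyDAG,
        annotations: AnnotationSet,
        terms: Iterable[str] | None = None,
        min_genes: int = 2,
    ) -> "GeneSetDAG":
        """Reference-side view: each term's propagated gene set.

        Terms annotating fewer than ``min_genes`` genes are dropped (a
        term of a single gene carries no grouping information).
        """
        pool = set(terms) if terms is not None else dag.terms
        per_term: dict[str, set[str]] = {}
        for gene, ts in annotations.propagated.items():
            for t in ts & pool:
                per_term.setdefault(t, set()).add(gene)
        keep = {t for t, gs in per_term.items() if len(gs) >= min_genes}
        g = nx.DiGraph()
        g.add_nodes_from(keep)
        for t in keep:
            for anc in dag.ancestors(t):
                if anc in keep:
                    g.add_edge(t, anc)
        return cls({t: frozenset(per_term[t]) for t in keep}, g)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self.term_genes.values():
            out |= gs
        return out

    def ancestor_sets(self) -> dict[str, frozenset[str]]:
        return {
            t: frozenset(nx.descendants(self.graph, t)) for t in self.graph.nodes
        }

    def relabeled(self, mapping: Mapping[str, str]) -> "GeneSetDAG":
        """Apply a gene-label bijection to every term gene set."""
        return GeneSetDAG(
            {
                t: frozenset(mapping.get(g, g) for g in gs)
                for t, gs in self.term_genes.items()
            },
            self.graph,
        )


@dataclass
class AlignmentResult:
    """Constraint-respecting matched term pairs above the FDR cutoff."""

    pairs: list[tuple[str, str, float]]
    fdr_threshold: float
    matched_unfiltered: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def x_terms(self) -> set[str]:
        return {a for a, _, _ in self.pairs}

    @property
    def y_terms(self) -> set[str]:
        return {b for _, b, _ in self.pairs}

    def report(self) -> str:
        lines = ["inferred_term\treference_term\tscore"]
        for a, b, s in self.pairs:
            lines.append(f"{a}\t{b}\t{s:.4f}")
        return "\n".join(lines)


def _greedy_match(
    dag_x: GeneSetDAG,
    dag_y: GeneSetDAG,
    anc_x: dict[str, frozenset[str]],
    anc_y: dict[str, frozenset[str]],
    min_score: float = 0.0,
) -> list[tuple[str, str, float]]:
    """Greedy descending-score matching under the two constraints.

    Because matching proceeds in descending score, the accepted pairs with
    score >= c never depend on candidates below c; ``min_score`` may thus
    prune the candidate list without changing the high-scoring matches.
    """
    xs = sorted(dag_x.term_genes)
    ys = sorted(dag_y.term_genes)
    if not xs or not ys:
        return []
    universe = sorted(dag_x.genes | dag_y.genes)
    gidx = {g: i for i, g in enumerate(universe)}
    ax = np.zeros((len(xs), len(universe)), dtype=bool)
    ay = np.zeros((len(ys), len(universe)), dtype=bool)
    for i, t in enumerate(xs):
        ax[i, [gidx[g] for g in dag_x.term_genes[t]]] = True
    for j, t in enumerate(ys):
        ay[j, [gidx[g] for g in dag_y.term_genes[t]]] = True
    inter = ax.astype(np.int32) @ ay.T.astype(np.int32)
    sx = ax.sum(axis=1)[:, None]
    sy = ay.sum(axis=1)[None, :]
    jac = inter / (sx + sy - inter)

    ii, jj = np.nonzero(jac >= max(min_score, 1e-12))
    order = sorted(
        range(len(ii)),
        key=lambda k: (
            -jac[ii[k], jj[k]],
            len(dag_x.term_genes[xs[ii[k]]]),
            xs[ii[k]],
            ys[jj[k]],
        ),
    )
    used_x: set[str] = set()
    used_y: set[str] = set()
    accepted: list[tuple[str, str, float]] = []
    desc_x: dict[str, set[str]] = {}
    for k in order:
        a, b = xs[ii[k]], ys[jj[k]]
        if a in used_x or b in used_y:
            continue
        ok = True
        for a2, b2, _ in accepted:
            cross1 = a in anc_x[a2] and b2 in anc_y[b]
            cross2 = a2 in anc_x[a] and b in anc_y[b2]
            if cross1 or cross2:
                ok = False
                break
        if ok:
            accepted.append((a, b, float(jac[ii[k], jj[k]])))
            used_x.add(a)
            used_y.add(b)
    return accepted


def align(
    dag_x: GeneSetDAG | InferredDAG,
    dag_y: GeneSetDAG | InferredDAG,
    fdr: float = 0.05,
    n_perm: int = 100,
    seed: int = 0,
) -> AlignmentResult:
    """Align two DAGs by intrinsic similarity with FDR control.

    The null distribution of match scores comes from ``n_perm`` random
    gene-label permutations of ``dag_x``; the retained score cutoff is the
    smallest observed match score c with
    (mean null matches >= c) / (observed matches >= c) <= ``fdr``.
    Deterministic given ``seed``.
    """
    if isinstance(dag_x, InferredDAG):
        dag_x = GeneSetDAG.from_inferred(dag_x)
    if isinstance(dag_y, InferredDAG):
        dag_y = GeneSetDAG.from_inferred(dag_y)
    if not (dag_x.genes & dag_y.genes):
        logger.warning("gene universes do not intersect; empty alignment")
        return AlignmentResult(pairs=[], fdr_threshold=float("inf"))
    anc_x = dag_x.ancestor_sets()
    anc_y = dag_y.ancestor_sets()
    observed = _greedy_match(dag_x, dag_y, anc_x, anc_y)
    if not observed:
        return AlignmentResult(pairs=[], fdr_threshold=float("inf"))

    obs_scores = np.array(sorted((s for _, _, s in observed), reverse=True))
    min_obs = float(obs_scores[-1])
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x_genes = sorted(dag_x.genes)
    null_scores: list[float] = []
    for _ in range(n_perm):
        perm = rng.permutation(len(x_genes))
        mapping = {g: x_genes[perm[i]] for i, g in enumerate(x_genes)}
        null = _greedy_match(
            dag_x.relabeled(mapping), dag_y, anc_x, anc_y, min_score=min_obs
        )
        null_scores.extend(s for _, _, s in null)
    null_arr = np.array(null_scores) if null_scores else np.array([])

    threshold = float("inf")
    for c in np.unique(obs_scores):  # ascending: first satisfying c is smallest
        n_obs = int((obs_scores >= c).sum())
        n_null = float((null_arr >= c).sum()) / n_perm if null_arr.size else 0.0
        if n_obs > 0 and n_null / n_obs <= fdr:
            threshold = float(c)
            break
    pairs = [(a, b, s) for a, b, s in observed if s >= threshold]
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    return AlignmentResult(
        pairs=pairs, fdr_threshold=threshold, matched_unfiltered=observed
    )


def flag_training_derived(alignment_to_training: AlignmentResult) -> set[str]:
    """Inferred terms attributable to the training part.

    Given the alignment of the all-genes inferred DAG to the DAG inferred
    from the training genes alone, any aligned inferred term is considered
    derived from training information and excluded from evaluation.
    """
    return alignment_to_training.x_terms


@dataclass
class EvalMetrics:
    """Held-out evaluation of an inferred ontology."""

    hit: int
    precision: float
    recall: float
    f_measure: float

    def report_row(self, prefix: str = "") -> str:
        head = f"{prefix}\t" if prefix else ""
        return (
            f"{head}{self.hit}\t{self.precision:.4f}\t"
            f"{self.recall:.4f}\t{self.f_measure:.4f}"
        )


def evaluate(
    align_g: AlignmentResult,
    o_g_terms: Iterable[str],
    o_t_terms: Iterable[str],
    training_derived: set[str],
    inferred_term_count: int,
) -> EvalMetrics:
    """Hit / precision / recall / F over the held-out part of the reference.

    hit counts aligned pairs whose reference term lies outside the
    training sub-tree and whose inferred term is not training-derived;
    precision divides by the non-training-derived inferred terms, recall
    by the reference terms outside the training sub-tree.
    """
    o_g_terms = set(o_g_terms)
    o_t_terms = set(o_t_terms)
    held_out = o_g_terms - o_t_terms
    if not held_out:
        raise ValueError("no reference terms outside the training part; recall undefined")
    hit = sum(
        1
        for (t_inf, t_ref, _) in align_g.pairs
        if t_ref not in o_t_terms and t_inf not in training_derived
    )
    denom_p = inferred_term_count - len(training_derived)
    precision = hit / denom_p if denom_p > 0 else 0.0
    recall = hit / len(held_out)
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return EvalMetrics(hit=hit, precision=precision, recall=recall, f_measure=f)
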