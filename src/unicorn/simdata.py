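"""Synthetic worlds with known ground truth.

A planted rooted DAG (a complete ``branching``-ary tree of the requested
depth plus a configurable fraction of extra parent links) annotates genes
at its leaves.  Each synthetic network derives its edge weights from the
true ontological similarity of the gene pair through a per-network
monotone transform — identity, square, exponential rescale, or a binary
threshold — plus additive Gaussian noise and uniform edge dropout, so the
networks are heterogeneous in weight distribution yet all carry (noisy)
signal about the same hierarchy.  Everything is reproducible from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .netio import WeightedNetwork, write_network
from .ontology import (
    AnnotationSet,
    OntologyDAG,
    TrainingSet,
    propagate_annotations,
    training_pair_similarities,
)

__all__ = [
    "NetworkSpec",
    "SyntheticWorld",
    "generate_ontology",
    "generate_networks",
    "generate_world",
    "write_world",
]

NAMESPACE = "synthetic_process"

_TRANSFORMS = {
    "identity": lambda s: s,
    "square": lambda s: s**2,
    "exp": lambda s: (np.exp(s) - 1.0) / (math.e - 1.0),
}


@dataclass
class NetworkSpec:
    """Recipe for one synthetic network."""

    name: str
    transform: str = "identity"  # identity | square | exp | binary
    noise: float = 0.3
    dropout: float = 0.3
    binary_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.transform not in (*_TRANSFORMS, "binary"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.noise < 0 or not 0 <= self.dropout < 1:
            raise ValueError("noise must be >= 0 and dropout in [0, 1)")


# The default networks differ in transform (weight-distribution shape) and
# in noise (informativeness about the planted hierarchy), emulating how
# real heterogeneous networks are unequally useful for a given
# sub-ontology; equal-importance integration is then genuinely suboptimal.
DEFAULT_SPECS = (
    NetworkSpec("coexpr", "identity", noise=0.45),
    NetworkSpec("funcnet", "square", noise=0.2),
    NetworkSpec("physical", "binary", noise=0.3),
)


@dataclass
class SyntheticWorld:
    """A planted ontology, its annotations, and derived noisy networks."""

    dag: OntologyDAG
    annotations: AnnotationSet
    networks: list[WeightedNetwork]
    specs: list[NetworkSpec]
    true_similarity: TrainingSet
    seed: int
    root: str = ""

    @property
    def genes(self) -> set[str]:
        return self.annotations.genes


def generate_ontology(
    n_genes: int,
    depth: int,
    branching: int,
    seed: int = 0,
    extra_parent_frac: float = 0.0,
) -> tuple[OntologyDAG, AnnotationSet]:
    """Plant a rooted DAG and annotate genes at its leaves.

    The backbone is a complete ``branching``-ary tree with ``depth``
    levels (root at level 1); ``extra_parent_frac`` of the terms at level
    3 or deeper gain one extra parent from the level above, making the
    result a proper DAG.  Genes are spread round-robin over the leaves and
    annotations propagated upward.
    """
    if depth < 2 or branching < 1 or n_genes < 1:
        raise ValueError("need depth >= 2, branching >= 1, n_genes >= 1")
    n_leaves = branching ** (depth - 1)
    if n_genes < n_leaves:
        raise ValueError(
            f"{n_genes} genes cannot cover {n_leaves} leaf terms; "
            "increase n_genes or shrink the tree"
        )
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    g = nx.DiGraph()
    levels: list[list[str]] = []
    counter = 0

    def new_term() -> str:
        nonlocal counter
        counter += 1
        return f"S:{counter:07d}"

    root = new_term()
    g.add_node(root, name="root")
    levels.append([root])
    for lvl in range(2, depth + 1):
        this: list[str] = []
        for parent in levels[-1]:
            for _ in range(branching):
                t = new_term()
                g.add_node(t, name=f"level{lvl}")
                g.add_edge(t, parent, relation="is_a")
                this.append(t)
        levels.append(this)
    if extra_parent_frac > 0:
        for lvl in range(3, depth + 1):
            for t in levels[lvl - 1]:
                if rng.random() < extra_parent_frac:
                    choices = [
                        c for c in levels[lvl - 2] if not g.has_edge(t, c)
                    ]
                    if choices:
                        extra = choices[int(rng.integers(len(choices)))]
                        g.add_edge(t, extra, relation="part_of")
    dag = OntologyDAG(graph=g, namespace=NAMESPACE)
    leaves = levels[-1]
    genes = [f"g{i:03d}" for i in range(1, n_genes + 1)]
    direct = {gene: {leaves[i % len(leaves)]} for i, gene in enumerate(genes)}
    annotations = propagate_annotations(dag, direct)
    return dag, annotations


def generate_networks(
    dag: OntologyDAG,
    annotations: AnnotationSet,
    specs: list[NetworkSpec],
    seed: int = 0,
) -> tuple[list[WeightedNetwork], TrainingSet]:
    """Derive noisy networks from the true ontological similarities.

    Returns the networks and the ground-truth similarity over all
    annotated gene pairs (computed over the whole planted DAG).
    """
    (root,) = dag.roots
    truth = training_pair_similarities(dag, root, annotations)
    pairs = truth.pairs
    s = np.array([truth.similarity[p] for p in pairs])
    nets: list[WeightedNetwork] = []
    ss = np.random.SeedSequence(seed)
    for spec, child in zip(specs, ss.spawn(len(specs))):
        rng = np.random.default_rng(child)
        keep = rng.random(len(pairs)) >= spec.dropout
        if spec.transform == "binary":
            signal = s + rng.normal(0.0, spec.noise, len(pairs))
            present = keep & (signal >= spec.binary_threshold)
            weights = {p: 1.0 for p, on in zip(pairs, present) if on}
        else:
            base = _TRANSFORMS[spec.transform](s)
            noisy = base + rng.normal(0.0, spec.noise, len(pairs))
            noisy = np.clip(noisy, 0.0, 1.0)
            weights = {p: float(w) for p, w, on in zip(pairs, noisy, keep) if on}
        nets.append(WeightedNetwork(weights, name=spec.name))
    return nets, truth


def generate_world(
    n_genes: int = 60,
    depth: int = 4,
    branching: int = 3,
    seed: int = 0,
    specs: list[NetworkSpec] | None = None,
    extra_parent_frac: float = 0.0,
) -> SyntheticWorld:
    """One-call synthetic study system with the default three networks."""
    specs = list(specs) if specs is not None else list(DEFAULT_SPECS)
    ss = np.random.SeedSequence(seed)
    s_onto, s_net = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    dag, annotations = generate_ontology(
        n_genes, depth, branching, seed=s_onto, extra_parent_frac=extra_parent_frac
    )
    nets, truth = generate_networks(dag, annotations, specs, seed=s_net)
    (root,) = dag.roots
    return SyntheticWorld(
        dag=dag,
        annotations=annotations,
        networks=nets,
        specs=specs,
        true_similarity=truth,
        seed=seed,
        root=root,
    )


def write_world(world: SyntheticWorld, outdir: str | Path) -> dict[str, Path]:
    """Write the world in the same formats the pipeline reads.

    Produces an OBO file, a two-column annotation table and one edge list
    per network; returns the paths keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    obo = outdir / "ontology.obo"
    with open(obo, "w") as fh:
        fh.write("format-version: 1.2\n")
        for t in sorted(world.dag.terms):
            fh.write(f"\n[Term]\nid: {t}\n")
            fh.write(f"name: {world.dag.graph.nodes[t].get('name', t)}\n")
            fh.write(f"namespace: {world.dag.namespace}\n")
            for _, parent, data in world.dag.graph.out_edges(t, data=True):
                rel = data.get("relation", "is_a")
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: {rel} {parent}\n")
    paths["ontology"] = obo

    ann = outdir / "annotations.tsv"
    with open(ann, "w") as fh:
        for gene in sorted(world.annotations.direct):
            for term in sorted(world.annotations.direct[gene]):
                fh.write(f"{gene}\t{term}\n")
    paths["annotations"] = ann

    for net in world.networks:
        p = outdir / f"network_{net.name}.tsv"
        write_network(net, p)
        paths[f"network:{net.name}"] = p
    return paths
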