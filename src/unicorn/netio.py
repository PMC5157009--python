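"""Weighted gene networks: reading, writing and diffusion-kernel weighting.

Networks are undirected gene graphs with one finite real weight per
unordered gene pair and no self-loops.  A binary interaction network
(all weights 1) can be turned into a weighted one with a graph diffusion
kernel, which scores gene pairs by how directly or indirectly connected
they are.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import numpy as np
from scipy.linalg import expm

logger = logging.getLogger(__name__)

__all__ = ["WeightedNetwork", "read_network", "write_network", "diffusion_kernel"]


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class WeightedNetwork:
    """Undirected weighted gene graph, keyed by canonical unordered pairs."""

    weights: dict[tuple[str, str], float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        clean: dict[tuple[str, str], float] = {}
        for (a, b), w in self.weights.items():
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if not np.isfinite(w):
                raise ValueError(f"non-finite weight for ({a}, {b})")
            clean[_pair(a, b)] = float(w)
        self.weights = clean

    @property
    def genes(self) -> set[str]:
        return {g for p in self.weights for g in p}

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.weights)

    def weight(self, a: str, b: str) -> float | None:
        return self.weights.get(_pair(a, b))

    def has_edge(self, a: str, b: str) -> bool:
        return _pair(a, b) in self.weights

    def __len__(self) -> int:
        return len(self.weights)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.weights)

    def subset_weights(self, min_weight: float) -> "WeightedNetwork":
        """Edges with weight >= min_weight."""
        return WeightedNetwork(
            {p: w for p, w in self.weights.items() if w >= min_weight},
            name=self.name,
        )

    def subset_genes(self, genes: Iterable[str]) -> "WeightedNetwork":
        """Induced sub-network on a gene subset."""
        genes = set(genes)
        return WeightedNetwork(
            {(a, b): w for (a, b), w in self.weights.items() if a in genes and b in genes},
            name=self.name,
        )

    def rescaled(self) -> "WeightedNetwork":
        """Min-max rescale weights to [0, 1] (all-equal weights map to 1)."""
        if not self.weights:
            return WeightedNetwork({}, name=self.name)
        vals = np.fromiter(self.weights.values(), dtype=float)
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            return WeightedNetwork({p: 1.0 for p in self.weights}, name=self.name)
        return WeightedNetwork(
            {p: (w - lo) / (hi - lo) for p, w in self.weights.items()}, name=self.name
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for (a, b), w in self.weights.items():
            g.add_edge(a, b, weight=w)
        return g


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_network(
    path: str | Path,
    gene_universe: Iterable[str] | None = None,
    name: str = "",
    columns: tuple[int, int, int] = (0, 1, 2),
    type_column: int | None = None,
    keep_types: Iterable[str] | None = None,
) -> WeightedNetwork:
    """Read a tab-separated edge list (geneA, geneB, weight).

    Edges are restricted to ``gene_universe`` when given (dropped edges are
    counted and logged), duplicate pair entries collapse to their maximum
    weight, and self-loops are dropped.  ``columns`` maps (geneA, geneB,
    weight) onto column indices for files with extra columns; a missing
    weight column means a binary network (weight 1).  ``type_column`` with
    ``keep_types`` retains only rows whose interaction type matches.
    """
    universe = set(gene_universe) if gene_universe is not None else None
    keep_types = set(keep_types) if keep_types is not None else None
    ia, ib, iw = columns
    weights: dict[tuple[str, str], float] = {}
    dropped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            a, b = parts[ia], parts[ib]
            if type_column is not None and keep_types is not None:
                if parts[type_column] not in keep_types:
                    continue
            if iw < len(parts):
                try:
                    w = float(parts[iw])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: non-numeric weight {parts[iw]!r} on line {lineno}"
                    ) from exc
            else:
                w = 1.0
            if a == b:
                continue
            if universe is not None and (a not in universe or b not in universe):
                dropped += 1
                continue
            p = _pair(a, b)
            if p not in weights or w > weights[p]:
                weights[p] = w
    if dropped:
        logger.info("%s: dropped %d edges outside the gene universe", path, dropped)
    return WeightedNetwork(weights, name=name or Path(path).stem)


def write_network(net: WeightedNetwork, path: str | Path) -> None:
    """Write a network as a sorted 3-column tab-separated edge list."""
    with open(path, "w") as fh:
        for (a, b) in sorted(net.weights):
            fh.write(f"{a}\t{b}\t{net.weights[(a, b)]:.10g}\n")


def diffusion_kernel(
    binary_net: WeightedNetwork,
    tau: float = 1.0,
    min_weight: float = 1e-6,
) -> WeightedNetwork:
    """Weight a binary network by a graph diffusion kernel.

    Computes exp(-tau * L) on each connected component, with L the
    normalised graph Laplacian, then rescales off-diagonal entries by their
    maximum so weights land in (0, 1].  Gene pairs in different components
    get no edge; entries below ``min_weight`` (after rescaling) are dropped
    to keep the result sparse.  Larger weights mean more direct/indirect
    connectivity.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    bad = [w for w in binary_net.weights.values() if w != 1.0]
    if bad:
        raise ValueError("diffusion kernel expects a binary network (all weights 1)")
    g = binary_net.to_networkx()
    raw: dict[tuple[str, str], float] = {}
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        if len(nodes) < 2:
            continue
        sub = g.subgraph(nodes)
        lap = nx.normalized_laplacian_matrix(sub, nodelist=nodes).toarray()
        kern = expm(-tau * lap)
        n = len(nodes)
        for i in range(n):
            for j in range(i + 1, n):
                raw[_pair(nodes[i], nodes[j])] = kern[i, j]
    if not raw:
        return WeightedNetwork({}, name=binary_net.name)
    top = max(raw.values())
    out = {p: v / top for p, v in raw.items() if v / top >= min_weight}
    return WeightedNetwork(out, name=binary_net.name)
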