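"""Linear integration of discretized networks.

The training pairs and the pooled discrete levels of all networks form a
design matrix M (|T| rows, one column per merged level of each network);
entry (i, j) is pair i's discretized weight if its edge in the column's
network occupies that level, else 0.  Integration finds the coefficient
vector a maximizing the Pearson correlation of M a with the ontological
similarity vector s — a single-response special case of canonical
correlation analysis whose closed form is ordinary least squares on the
centred columns.  The fitted coefficients then score every edge of every
network, producing one integrated network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .discretizer import DiscretizationMap
from .netio import WeightedNetwork
from .ontology import TrainingSet

__all__ = [
    "DesignMatrix",
    "CoefficientVector",
    "build_design_matrix",
    "fit_integration",
    "fit_integration_monotone",
    "integrate_networks",
]


@dataclass
class DesignMatrix:
    """Training pairs x pooled discrete levels."""

    matrix: np.ndarray
    pairs: list[tuple[str, str]]
    network_names: list[str]
    level_counts: list[int]

    @property
    def n_columns(self) -> int:
        return int(self.matrix.shape[1])

    def column_slice(self, net_index: int) -> slice:
        start = sum(self.level_counts[:net_index])
        return slice(start, start + self.level_counts[net_index])


@dataclass
class CoefficientVector:
    """Unit-norm integration coefficients and the correlation they achieve."""

    a: np.ndarray
    achieved_pcc: float
    network_names: list[str]
    level_counts: list[int]

    def report(self) -> str:
        lines = ["network\tlevel\tcoefficient"]
        i = 0
        for name, k in zip(self.network_names, self.level_counts):
            for l in range(k):
                lines.append(f"{name}\t{l}\t{self.a[i]:.6g}")
                i += 1
        lines.append(f"# achieved_pcc\t{self.achieved_pcc:.6f}")
        return "\n".join(lines)


def build_design_matrix(
    discretized_nets: Sequence[tuple[WeightedNetwork, DiscretizationMap]],
    training: TrainingSet,
) -> DesignMatrix:
    """Assemble M from the filtered networks and their discretizations.

    ``discretized_nets`` pairs each filtered network (original weights)
    with the merged discretization learned on it.  A training pair with no
    edge in a network contributes 0 to all that network's columns; a pair
    with no edge anywhere yields an all-zero row (kept).
    """
    pairs = list(training.pairs)
    idx = {p: i for i, p in enumerate(pairs)}
    level_counts = [dmap.n_levels for _, dmap in discretized_nets]
    names = [net.name for net, _ in discretized_nets]
    m = np.zeros((len(pairs), sum(level_counts)))
    offset = 0
    for (net, dmap) in discretized_nets:
        lw = dmap.level_weight
        lvl_of = dmap.level_of
        for p in pairs:
            if net.has_edge(*p):
                l = lvl_of.get(p)
                if l is None:
                    l = int(dmap.level_of_weight(net.weights[p]))
                m[idx[p], offset + l] = lw[l]
        offset += dmap.n_levels
    return DesignMatrix(matrix=m, pairs=pairs, network_names=names, level_counts=level_counts)


def fit_integration(
    design: DesignMatrix, s: np.ndarray, ridge: float = 1e-8
) -> CoefficientVector:
    """Coefficients maximizing Pearson correlation of M a with s.

    Solved in closed form: the least-squares fit of the centred s on the
    centred columns maximizes the correlation; rank-deficient designs fall
    back to a small ridge on the normal equations.  The result has unit
    Euclidean norm and sign chosen so the achieved correlation is >= 0.
    """
    m = np.asarray(design.matrix, dtype=float)
    s = np.asarray(s, dtype=float)
    if m.shape[0] != len(s):
        raise ValueError("design and similarity vector have different lengths")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 training pairs")
    if np.ptp(s) == 0:
        raise ValueError("similarity vector is constant; correlation undefined")
    if not np.any(m):
        raise ValueError("design matrix is all zero; correlation undefined")
    mc = m - m.mean(axis=0)
    sc = s - s.mean()
    a, *_ = np.linalg.lstsq(mc, sc, rcond=None)
    combined = m @ a
    if np.ptp(combined) == 0:
        gram = mc.T @ mc
        gram[np.diag_indices_from(gram)] += ridge
        a = np.linalg.solve(gram, mc.T @ sc)
        combined = m @ a
    norm = np.linalg.norm(a)
    if norm == 0:
        raise ValueError("degenerate fit: zero coefficient vector")
    a = a / norm
    pcc = float(np.corrcoef(m @ a, s)[0, 1])
    if pcc < 0:
        a, pcc = -a, -pcc
    return CoefficientVector(
        a=a,
        achieved_pcc=pcc,
        network_names=design.network_names,
        level_counts=design.level_counts,
    )


def fit_integration_monotone(
    design: DesignMatrix,
    s: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> CoefficientVector:
    """Correlation-maximizing coefficients with order-preserving products.

    The unconstrained fit assigns each level a free coefficient, so the
    per-level products a_j * w_j — the effective integrated contribution
    of a level — need not increase with the level, which can invert the
    weight order that the discretization step guarantees.  This solver
    constrains each network's products to be nondecreasing in the level,
    fitting them by backfitting with isotonic regression (an additive
    isotonic model).  With ample training data it approaches the
    unconstrained optimum; with little data it is a stabilizer.
    """
    from sklearn.isotonic import IsotonicRegression

    m = np.asarray(design.matrix, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.ptp(s) == 0:
        raise ValueError("similarity vector is constant; correlation undefined")
    if not np.any(m):
        raise ValueError("design matrix is all zero; correlation undefined")
    n_nets = len(design.level_counts)
    # per pair and network: occupied level index, or -1 when no edge
    lev_idx = np.full((m.shape[0], n_nets), -1)
    col_value: list[np.ndarray] = []
    for k in range(n_nets):
        block = m[:, design.column_slice(k)]
        rows, cols = np.nonzero(block)
        lev_idx[rows, k] = cols
        vals = np.zeros(block.shape[1])
        vals[cols] = block[rows, cols]
        col_value.append(vals)
    f = [np.zeros(c) for c in design.level_counts]

    def predict() -> np.ndarray:
        out = np.zeros(m.shape[0])
        for k in range(n_nets):
            mask = lev_idx[:, k] >= 0
            out[mask] += f[k][lev_idx[mask, k]]
        return out

    prev_rss = np.inf
    for _ in range(max_iter):
        for k in range(n_nets):
            mask = lev_idx[:, k] >= 0
            if not mask.any():
                continue
            resid = s - predict()
            resid[mask] += f[k][lev_idx[mask, k]]
            iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
            iso.fit(lev_idx[mask, k], resid[mask])
            f[k] = iso.predict(np.arange(design.level_counts[k]))
        rss = float(((s - predict()) ** 2).sum())
        if prev_rss - rss < tol:
            break
        prev_rss = rss
    # express as coefficients on the level columns: a_j = f_j / column value
    a = np.concatenate(
        [np.divide(f[k], col_value[k], out=np.zeros_like(f[k]),
                   where=col_value[k] != 0) for k in range(n_nets)]
    )
    norm = np.linalg.norm(a)
    if norm == 0:
        raise ValueError("degenerate fit: zero coefficient vector")
    a = a / norm
    pcc = float(np.corrcoef(m @ a, s)[0, 1])
    if pcc < 0:
        a, pcc = -a, -pcc
    return CoefficientVector(
        a=a,
        achieved_pcc=pcc,
        network_names=design.network_names,
        level_counts=design.level_counts,
    )


def integrate_networks(
    discretized_nets: Sequence[tuple[WeightedNetwork, DiscretizationMap]],
    coef: CoefficientVector,
    rescale: bool = True,
) -> WeightedNetwork:
    """Combine all networks into one using the fitted coefficients.

    Every gene pair with an edge in at least one network gets weight
    sum over networks of a[column of its level] * discretized weight;
    absent edges contribute 0.  With ``rescale`` the result is min-max
    scaled to [0, 1] (the expected input scale of the DAG inference step).
    """
    combined: dict[tuple[str, str], float] = {}
    offset = 0
    for (net, dmap) in discretized_nets:
        lw = dmap.level_weight
        lvl_of = dmap.level_of
        for p, w in net.weights.items():
            l = lvl_of.get(p)
            if l is None:
                l = int(dmap.level_of_weight(w))
            combined[p] = combined.get(p, 0.0) + float(coef.a[offset + l] * lw[l])
        offset += dmap.n_levels
    out = WeightedNetwork(combined, name="integrated")
    return out.rescaled() if rescale else out
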