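"""Order-preserving discretization of edge weights into levels.

Heterogeneous networks carry edge weights on incomparable scales.  To make
them integrable, each network's weights are mapped to a small number of
ordered levels such that the ranking of training gene pairs by level agrees
as much as possible with their ranking by ontological similarity.  The
objective is the *discordance*: the number of unordered pairs of training
pairs whose order by level differs from their order by similarity, where
order is the three-valued direction function d(x, y) in {-1, 0, 1}.

The constraint is order preservation: a pair with a larger original weight
can never sit in a lower level, and pairs with equal weights must share a
level.  An order-preserving discretization is therefore a partition of the
weight-sorted training pairs into contiguous segments that never split a
group of equal weights.

The search starts from a random partition into k levels and repeatedly
moves a few pairs at the top or bottom of a level into the adjacent level,
accepting worse moves with a small probability that decays over time
(an annealing-style schedule), keeping the best partition ever seen.
Afterwards neighbouring levels are merged down to a small count to avoid
over-fitting the integration step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .netio import WeightedNetwork
from .ontology import TrainingSet

__all__ = [
    "DiscretizationMap",
    "SearchParams",
    "discordance",
    "search_discretization",
    "merge_levels",
    "apply_discretization",
]


@dataclass
class SearchParams:
    """Knobs of the stochastic discretization search."""

    k: int = 200
    max_iterations: int = 10_000
    restarts: int = 5
    seed: int = 0
    max_block: int = 5  # most pairs moved in one step

    def __post_init__(self) -> None:
        if min(self.k, self.max_iterations, self.restarts, self.max_block) < 1:
            raise ValueError("all search parameters must be positive")

    def acceptance_probability(self, iteration: int) -> float:
        """Chance of keeping a non-improving move at 1-based ``iteration``."""
        return min(0.1 / iteration, 0.001)


@dataclass
class DiscretizationMap:
    """An ordered partition of training-pair weights into levels.

    Pairs are stored sorted by ascending original weight; ``item_level``
    assigns each its level index (0 = lowest).  Level representative
    weights are the means of member original weights; level boundaries are
    the minimum member weight of each level, used to bin non-training
    edges with half-open intervals.
    """

    pairs: list[tuple[str, str]]
    weights: np.ndarray
    similarities: np.ndarray
    item_level: np.ndarray
    k_initial: int
    objective_value: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.similarities = np.asarray(self.similarities, dtype=float)
        self.item_level = np.asarray(self.item_level, dtype=np.int64)
        if np.any(np.diff(self.weights) < 0):
            raise ValueError("pairs must be sorted by ascending weight")
        dif = np.diff(self.item_level)
        if np.any(dif < 0) or np.any(dif > 1):
            raise ValueError("levels must be contiguous and nondecreasing")
        same_w = np.diff(self.weights) == 0
        if np.any(same_w & (dif != 0)):
            raise ValueError("equal weights must share a level")

    @property
    def n_levels(self) -> int:
        return int(self.item_level[-1]) + 1 if len(self.item_level) else 0

    @property
    def level_weight(self) -> np.ndarray:
        """Mean original weight per level (strictly increasing)."""
        return np.array(
            [self.weights[self.item_level == l].mean() for l in range(self.n_levels)]
        )

    @property
    def level_boundaries(self) -> np.ndarray:
        """Lower weight bound of each level (ascending)."""
        return np.array(
            [self.weights[self.item_level == l].min() for l in range(self.n_levels)]
        )

    @property
    def level_of(self) -> dict[tuple[str, str], int]:
        return {p: int(l) for p, l in zip(self.pairs, self.item_level)}

    def level_of_weight(self, w: float | np.ndarray) -> np.ndarray:
        """Level index for arbitrary edge weights (half-open intervals)."""
        idx = np.searchsorted(self.level_boundaries, w, side="right") - 1
        return np.clip(idx, 0, self.n_levels - 1)

    def report(self) -> str:
        """Tab-separated per-level summary."""
        lw, lb = self.level_weight, self.level_boundaries
        lines = ["level\tlower_bound\tmean_weight\tn_pairs"]
        for l in range(self.n_levels):
            n = int((self.item_level == l).sum())
            lines.append(f"{l}\t{lb[l]:.6g}\t{lw[l]:.6g}\t{n}")
        lines.append(f"# objective\t{self.objective_value}")
        return "\n".join(lines)


def _direction_matrix(values: np.ndarray) -> np.ndarray:
    """Pairwise direction d(v_i, v_j) in {-1, 0, 1} as int8."""
    return np.sign(values[:, None] - values[None, :]).astype(np.int8)


def _discordance_arrays(levels: np.ndarray, sims: np.ndarray) -> int:
    d_l = _direction_matrix(levels.astype(float))
    d_s = _direction_matrix(sims)
    mism = d_l != d_s
    return int(np.triu(mism, k=1).sum())


def discordance(dmap: DiscretizationMap, training: TrainingSet | None = None) -> int:
    """Discordance of a discretization with the similarity ranking.

    Counts unordered pairs {p, q} of training pairs whose direction by
    level differs from their direction by similarity.  ``training`` may be
    passed to re-derive similarities instead of using the stored ones.
    """
    if training is not None:
        sims = np.array([training.similarity[p] for p in dmap.pairs])
    else:
        sims = dmap.similarities
    return _discordance_arrays(dmap.item_level, sims)


class _Partition:
    """Search state: blocks of equal-weight pairs split into levels by cuts.

    ``cuts`` is a strictly increasing list of block positions; level l is
    the block range [cuts[l-1], cuts[l]).  Moving top/bottom pairs between
    adjacent levels is a shift of one cut.
    """

    def __init__(self, weights: np.ndarray, sims: np.ndarray):
        # weights ascending
        self.n = len(weights)
        boundaries = np.flatnonzero(np.diff(weights) != 0) + 1
        self.block_start = np.concatenate(([0], boundaries))
        self.block_end = np.concatenate((boundaries, [self.n]))
        self.n_blocks = len(self.block_start)
        self.d_s = _direction_matrix(sims)
        self.cuts: list[int] = []
        self.item_level = np.zeros(self.n, dtype=np.int64)

    def random_init(self, k: int, rng: np.random.Generator) -> None:
        n_cuts = min(k - 1, self.n_blocks - 1)
        if n_cuts > 0:
            self.cuts = sorted(
                rng.choice(np.arange(1, self.n_blocks), size=n_cuts, replace=False)
            )
        else:
            self.cuts = []
        self._refresh_levels()

    def _refresh_levels(self) -> None:
        edges = [0, *self.cuts, self.n_blocks]
        for l in range(len(edges) - 1):
            lo = self.block_start[edges[l]] if edges[l] < self.n_blocks else self.n
            hi = self.block_start[edges[l + 1]] if edges[l + 1] < self.n_blocks else self.n
            self.item_level[lo:hi] = l

    @property
    def n_levels(self) -> int:
        return len(self.cuts) + 1

    def objective(self) -> int:
        d_l = _direction_matrix(self.item_level.astype(float))
        return int(np.triu(d_l != self.d_s, k=1).sum())

    def level_block_range(self, level: int) -> tuple[int, int]:
        lo = self.cuts[level - 1] if level > 0 else 0
        hi = self.cuts[level] if level < len(self.cuts) else self.n_blocks
        return lo, hi

    def propose(self, rng: np.random.Generator, max_block: int):
        """One random move, or None if the draw is invalid.

        Returns (new_cut_position_info, moved_item_indices, delta).
        """
        L = self.n_levels
        level = int(rng.integers(L))
        up = bool(rng.integers(2))
        if (up and level == L - 1) or (not up and level == 0):
            return None
        lo, hi = self.level_block_range(level)
        sizes = self.block_end[lo:hi] - self.block_start[lo:hi]
        total = int(sizes.sum())
        c = int(rng.integers(1, min(max_block, total) + 1))
        # take whole blocks from the chosen end summing exactly to c
        if up:
            csum = np.cumsum(sizes[::-1])
        else:
            csum = np.cumsum(sizes)
        hit = np.flatnonzero(csum == c)
        if len(hit) == 0:
            return None  # would split an equal-weight group
        r = int(hit[0]) + 1  # number of blocks moved
        if up:
            items = np.arange(self.block_start[hi - r], self.block_end[hi - 1])
            cut_idx, new_pos = level, hi - r
            target = self.item_level[items[0]] + 1
        else:
            items = np.arange(self.block_start[lo], self.block_end[lo + r - 1])
            cut_idx, new_pos = level - 1, lo + r
            target = self.item_level[items[0]] - 1
        delta = self._delta(items, int(target))
        return (cut_idx, new_pos, lo, hi), items, delta

    def _delta(self, items: np.ndarray, target: int) -> int:
        """Objective change from moving ``items`` to level ``target``."""
        lev = self.item_level.astype(float)
        mask = np.ones(self.n, dtype=bool)
        mask[items] = False
        src = float(self.item_level[items[0]])
        d_old = np.sign(src - lev).astype(np.int8)
        d_new = np.sign(float(target) - lev).astype(np.int8)
        delta = 0
        for m in items:
            row = self.d_s[m]
            delta += int(((d_new != row) & mask).sum()) - int(
                ((d_old != row) & mask).sum()
            )
        return delta

    def apply(self, move: tuple[int, int, int, int]) -> None:
        cut_idx, new_pos, lo, hi = move
        if new_pos == lo or new_pos == hi:
            # source level emptied: the cut collapses onto a neighbour
            del self.cuts[cut_idx]
        else:
            self.cuts[cut_idx] = new_pos
        self._refresh_levels()


def _build_map(
    pairs: Sequence[tuple[str, str]],
    weights: np.ndarray,
    sims: np.ndarray,
    item_level: np.ndarray,
    k_initial: int,
) -> DiscretizationMap:
    obj = _discordance_arrays(item_level, sims)
    return DiscretizationMap(
        pairs=list(pairs),
        weights=weights,
        similarities=sims,
        item_level=item_level,
        k_initial=k_initial,
        objective_value=obj,
    )


def search_discretization(
    weights: Mapping[tuple[str, str], float],
    training: TrainingSet,
    params: SearchParams | None = None,
) -> DiscretizationMap:
    """Search for a low-discordance order-preserving discretization.

    ``weights`` maps training pairs (those with an edge in the network at
    hand) to their edge weights.  Deterministic given ``params.seed``; the
    best partition over all restarts and iterations is returned.
    """
    params = params or SearchParams()
    items = sorted(weights, key=lambda p: (weights[p], p))
    if len(items) < 2:
        raise ValueError("need at least 2 training pairs with an edge")
    w = np.array([weights[p] for p in items])
    s = np.array([training.similarity[p] for p in items])

    if np.all(w == w[0]):  # degenerate: one level forced
        lev = np.zeros(len(items), dtype=np.int64)
        return _build_map(items, w, s, lev, params.k)

    part = _Partition(w, s)
    best_lev: np.ndarray | None = None
    best_obj = np.inf
    ss = np.random.SeedSequence(params.seed)
    for child in ss.spawn(params.restarts):
        rng = np.random.default_rng(child)
        part.random_init(params.k, rng)
        cur_obj = part.objective()
        if cur_obj < best_obj:
            best_obj, best_lev = cur_obj, part.item_level.copy()
        for it in range(1, params.max_iterations + 1):
            prop = None
            for _ in range(10):  # re-propose invalid draws
                prop = part.propose(rng, params.max_block)
                if prop is not None:
                    break
            if prop is None:
                continue
            move, _, delta = prop
            if delta < 0 or rng.random() < params.acceptance_probability(it):
                part.apply(move)
                cur_obj += delta
                if cur_obj < best_obj:
                    best_obj, best_lev = cur_obj, part.item_level.copy()
    assert best_lev is not None
    # renumber levels contiguously (empty levels may have vanished)
    _, dense = np.unique(best_lev, return_inverse=True)
    return _build_map(items, w, s, dense.astype(np.int64), params.k)


def merge_levels(
    dmap: DiscretizationMap, target_min: int = 10, target_max: int = 20
) -> DiscretizationMap:
    """Merge adjacent levels down to ``target_max`` levels at most.

    A map already within the target is returned unchanged.  Merging is
    greedy: at each step the adjacent level pair whose merge increases the
    discordance least is combined (ties: the smaller combined size, then
    the lower pair).  Order preservation is maintained by construction.
    """
    if dmap.n_levels <= target_max:
        return dmap
    lev = dmap.item_level.copy()
    d_s = _direction_matrix(dmap.similarities)

    def merge_delta(a: int) -> int:
        ia = np.flatnonzero(lev == a)
        ib = np.flatnonzero(lev == a + 1)
        sub = d_s[np.ix_(ia, ib)]
        return int((sub != 0).sum() - (sub != -1).sum())

    n_lev = dmap.n_levels
    deltas = [merge_delta(a) for a in range(n_lev - 1)]
    sizes = [int((lev == l).sum()) for l in range(n_lev)]
    while n_lev > target_max:
        keyed = [
            (deltas[a], sizes[a] + sizes[a + 1], a) for a in range(n_lev - 1)
        ]
        _, _, a = min(keyed)
        lev[lev > a] -= 1
        sizes[a] += sizes[a + 1]
        del sizes[a + 1]
        n_lev -= 1
        del deltas[a]
        if a > 0:
            deltas[a - 1] = merge_delta(a - 1)
        if a < n_lev - 1:
            deltas[a] = merge_delta(a)
    out = _build_map(dmap.pairs, dmap.weights, dmap.similarities, lev, dmap.k_initial)
    assert out.n_levels >= min(target_min, dmap.n_levels)
    return out


def apply_discretization(
    dmap: DiscretizationMap, net: WeightedNetwork
) -> WeightedNetwork:
    """Replace every edge weight by its level's representative weight.

    Training edges land in their own level; other edges are binned by the
    half-open weight intervals anchored at training-edge weights, with
    out-of-range weights clamped to the extreme levels.
    """
    if not net.weights:
        return WeightedNetwork({}, name=net.name)
    pairs = list(net.weights)
    w = np.array([net.weights[p] for p in pairs])
    levels = dmap.level_of_weight(w)
    lw = dmap.level_weight
    return WeightedNetwork(
        {p: float(lw[l]) for p, l in zip(pairs, levels)}, name=net.name
    )
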