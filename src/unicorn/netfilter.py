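"""Training-guided edge filtering.

Each network gets its own weight threshold t_w, learned so that at least
half of the retained training-pair edges are semantically similar
(similarity >= t_s).  Candidate thresholds are the distinct weights of the
training-pair edges, scanned from the largest downwards; the smallest
satisfying weight is kept so that as many relevant edges as possible
survive.  If the similar fraction stops improving for a run of consecutive
reductions before any threshold satisfies the requirement, the scan stops
and the weight in effect before that run is used as a fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netio import WeightedNetwork
from .ontology import TrainingSet

__all__ = ["FilterResult", "learn_threshold"]


@dataclass
class FilterResult:
    """Learned threshold and the filtered network."""

    t_w: float
    retained_network: WeightedNetwork
    training_fraction_similar: float
    fallback_used: bool
    n_edges_before: int = 0
    n_edges_after: int = 0

    def report_row(self) -> str:
        return "\t".join(
            [
                self.retained_network.name,
                f"{self.t_w:.6g}",
                str(self.n_edges_before),
                str(self.n_edges_after),
                f"{self.training_fraction_similar:.4f}",
                str(int(self.fallback_used)),
            ]
        )


def learn_threshold(
    net: WeightedNetwork,
    training: TrainingSet,
    patience: int = 5,
) -> FilterResult:
    """Learn t_w from the training pairs and filter ``net`` by it.

    f(w) = fraction of training-pair edges with weight >= w whose
    similarity is >= t_s.  The returned t_w is the smallest scanned w with
    f(w) >= 0.5.  Early stop: if f has not increased for ``patience``
    consecutive reductions and no satisfying w has been found, scanning
    stops and t_w falls back to the w in effect before those reductions.
    Only training-pair edges vote; the threshold then filters every edge.
    """
    tr_edges = [
        (w, training.similarity[p] >= training.t_s)
        for p, w in ((p, net.weights.get(p)) for p in training.pairs)
        if w is not None
    ]
    if not tr_edges:
        raise ValueError(
            f"network {net.name!r} has no edges between training genes; "
            "threshold unlearnable"
        )
    weights = np.array([w for w, _ in tr_edges])
    similar = np.array([s for _, s in tr_edges], dtype=bool)
    candidates = np.unique(weights)[::-1]  # descending distinct weights

    best_w: float | None = None  # smallest satisfying w seen so far
    best_f = 0.0
    prev_f = -1.0
    stalled = 0
    fallback_w = candidates[0]
    fallback_f = 0.0
    for i, w in enumerate(candidates):
        retained = weights >= w
        f = float(similar[retained].mean())
        if f >= 0.5:
            best_w, best_f = float(w), f
        if f > prev_f:
            stalled = 0
        else:
            stalled += 1
        if stalled == 0 or i == 0:
            # w still "in effect": the last candidate before the stall run
            fallback_w, fallback_f = float(w), f
        prev_f = f
        if stalled >= patience and best_w is None:
            break

    if best_w is not None:
        t_w, frac, fallback = best_w, best_f, False
    else:
        # scan exhausted or stalled without ever reaching 50%: keep the
        # weight in effect before the stall run (the largest weight when
        # f never increased at all)
        t_w, frac, fallback = fallback_w, fallback_f, True
    retained_net = net.subset_weights(t_w)
    return FilterResult(
        t_w=t_w,
        retained_network=retained_net,
        training_fraction_similar=frac,
        fallback_used=fallback,
        n_edges_before=len(net),
        n_edges_after=len(retained_net),
    )
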