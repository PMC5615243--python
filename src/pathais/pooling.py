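"""Pool a weighted sample ensemble into substructure confidences.

The confidence of a substructure s is the weighted fraction of sampled
networks containing it:

    C(s) = sum_k w_k I(s in N_k) / sum_k w_k

computed stably from log-weights.  Confidence is invariant to rescaling
all weights, lies in [0, 1], and is 1 for the empty substructure.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidInputError
from .model import PathwayNetwork, PPIGraph, SampleEnsemble, Substructure

__all__ = [
    "contains",
    "confidence",
    "edge_confidence_map",
    "best_structure",
    "single_edge_substructures",
    "linear_ordering_substructures",
]


def contains(n: PathwayNetwork, s: Substructure) -> bool:
    """True iff the network satisfies every constraint of the substructure.

    Required edges must be present exactly; required orderings (u, v) need
    only a directed path u -> ... -> v (ancestry).
    """
    for g in s.gene_names():
        if g not in n.genes:
            raise InvalidInputError(f"substructure gene {g!r} not in network")
    if not s.required_edges <= n.directed_edges:
        return False
    if s.required_orderings:
        desc = n.descendant_masks()
        idx = n.genes.index
        for u, v in s.required_orderings:
            if not (desc[idx(u)] >> idx(v) & 1):
                return False
    return True


def _normalized_weights(e: SampleEnsemble) -> np.ndarray:
    lw = e.log_weights()
    w = np.exp(lw - lw.max())
    return w / w.sum()


def confidence(e: SampleEnsemble, s: Substructure) -> float:
    """Weighted fraction of ensemble networks containing s."""
    w = _normalized_weights(e)
    mask = np.array([contains(smp.network, s) for smp in e.samples])
    return float(w[mask].sum())


def edge_confidence_map(e: SampleEnsemble) -> dict[tuple[str, str], float]:
    """Confidence of every orientation of every scaffold edge.

    For each unordered scaffold pair {a, b} the returned probabilities for
    a->b and b->a, together with the implicit absence probability, sum to 1.
    """
    w = _normalized_weights(e)
    out: dict[tuple[str, str], float] = {}
    for a, b in e.scaffold.sorted_edges():
        for u, v in ((a, b), (b, a)):
            mask = np.array([(u, v) in smp.network.directed_edges for smp in e.samples])
            out[(u, v)] = float(w[mask].sum())
    return out


def best_structure(
    e: SampleEnsemble, candidates: Sequence[Substructure]
) -> tuple[Substructure, float]:
    """The candidate with maximal confidence; ties go to the first listed."""
    if not candidates:
        raise InvalidInputError("candidate list must be non-empty")
    best_s, best_c = candidates[0], confidence(e, candidates[0])
    for s in candidates[1:]:
        c = confidence(e, s)
        if c > best_c:
            best_s, best_c = s, c
    return best_s, best_c


def single_edge_substructures(ppi: PPIGraph) -> list[Substructure]:
    """One single-edge substructure per orientation of each scaffold edge."""
    out = []
    for a, b in ppi.sorted_edges():
        out.append(Substructure(required_edges=[(a, b)]))
        out.append(Substructure(required_edges=[(b, a)]))
    return out


def linear_ordering_substructures(genes: Iterable[str]) -> list[Substructure]:
    """All linear orderings of a small gene subset as ancestry substructures.

    An ordering (g1, ..., gk) demands g_i be an ancestor of g_{i+1} for all
    consecutive pairs (ancestry is transitive, so consecutive constraints
    pin the full order).  Capped at 7 genes: orderings grow factorially.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise InvalidInputError("need at least two genes to order")
    if len(genes) > 7:
        raise InvalidInputError("orderings limited to subsets of size <= 7")
    out = []
    for perm in itertools.permutations(genes):
        out.append(Substructure(required_orderings=list(zip(perm, perm[1:]))))
    return out
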