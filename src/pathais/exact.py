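"""Exact posterior inference by exhaustive enumeration on tiny scaffolds.

Every acyclic directed subgraph of the scaffold is enumerated (3 states
per scaffold edge: absent / forward / backward, cyclic combinations
dropped) and its unnormalized log posterior computed from the pair-score
table.  Practical only up to roughly 10 scaffold edges; used as the exact
reference the annealed importance sampler is expected to converge to.
"""

from __future__ import annotations

import itertools

import numpy as np

from .errors import InvalidInputError
from .model import PairScoreTable, PathwayNetwork, PPIGraph, Substructure
from .pooling import contains
from .scoring import log_global_score

__all__ = [
    "enumerate_networks",
    "exact_log_posterior",
    "exact_confidence",
    "exact_edge_confidence_map",
]

_MAX_EDGES = 12


def enumerate_networks(ppi: PPIGraph) -> list[PathwayNetwork]:
    """All acyclic directed subgraphs of the scaffold."""
    edges = ppi.sorted_edges()
    if len(edges) > _MAX_EDGES:
        raise InvalidInputError(
            f"enumeration limited to {_MAX_EDGES} scaffold edges, got {len(edges)}"
        )
    out = []
    for states in itertools.product((0, 1, 2), repeat=len(edges)):
        directed = []
        for (a, b), s in zip(edges, states):
            if s == 1:
                directed.append((a, b))
            elif s == 2:
                directed.append((b, a))
        try:
            out.append(PathwayNetwork(ppi.genes, directed))
        except InvalidInputError:
            continue  # cyclic combination
    return out


def exact_log_posterior(
    ppi: PPIGraph, table: PairScoreTable
) -> tuple[list[PathwayNetwork], np.ndarray]:
    """All networks with their normalized posterior probabilities."""
    networks = enumerate_networks(ppi)
    logf = np.array([log_global_score(n, table) for n in networks])
    logf -= logf.max()
    p = np.exp(logf)
    return networks, p / p.sum()


def exact_confidence(ppi: PPIGraph, table: PairScoreTable, s: Substructure) -> float:
    networks, p = exact_log_posterior(ppi, table)
    return float(sum(pi for n, pi in zip(networks, p) if contains(n, s)))


def exact_edge_confidence_map(
    ppi: PPIGraph, table: PairScoreTable
) -> dict[tuple[str, str], float]:
    networks, p = exact_log_posterior(ppi, table)
    out: dict[tuple[str, str], float] = {}
    for a, b in ppi.sorted_edges():
        for u, v in ((a, b), (b, a)):
            out[(u, v)] = float(
                sum(pi for n, pi in zip(networks, p) if (u, v) in n.directed_edges)
            )
    return out
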