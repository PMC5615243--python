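"""Pair-topology scores and the global network score.

For every unordered gene pair (x, y) four local structures are possible:
x fully epistatic/downstream, y fully epistatic/downstream, parallel
pathways, or unlinked.  Each predicts a double-mutant fitness — the
downstream gene's single-mutant fitness under full epistasis, the neutral
expectation E(x, y) otherwise — and is scored by the Gaussian log-density
of the observed double-mutant fitness at that prediction, plus the log of
the structure's prior.

A candidate DAG induces exactly one of the four kinds for each pair
(classification goes by ancestry, not adjacency: a directed path suffices
for epistasis).  The global log-score of a network is the sum of the
induced pair scores; its exponential is the unnormalized posterior f(N).
No per-edge terms enter the score — edge existence is already guaranteed
by the protein-interaction scaffold.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .errors import InvalidInputError, MissingDataError
from .model import (
    FitnessData,
    PairScoreTable,
    PathwayNetwork,
    Topology,
    TopologyKind,
    default_topologies,
)

__all__ = [
    "neutral_expectation",
    "topology_log_score",
    "build_pair_score_table",
    "induced_topology",
    "log_global_score",
]

_LOG_2PI = math.log(2.0 * math.pi)


def neutral_expectation(s_x: float, s_y: float, mode: str = "multiplicative") -> float:
    """Neutral double-mutant expectation E(x, y) from single-mutant fitnesses.

    ``multiplicative`` uses the product s_x * s_y (the standard neutral
    model for fitness); ``minimum`` uses min(s_x, s_y).
    """
    if s_x < 0 or s_y < 0:
        raise InvalidInputError("single-mutant fitness must be non-negative")
    if mode == "multiplicative":
        return s_x * s_y
    if mode == "minimum":
        return min(s_x, s_y)
    raise InvalidInputError(f"unknown neutral-expectation mode {mode!r}")


def topology_log_score(d: float, mu: float, sigma2: float, prior: float) -> float:
    """ln p_t + ln N(d; mu, sigma2) — one pair's score under one topology."""
    if sigma2 <= 0:
        raise InvalidInputError(f"sigma2 must be positive, got {sigma2}")
    if not 0.0 < prior <= 1.0:
        raise InvalidInputError(f"prior must be in (0, 1], got {prior}")
    return math.log(prior) - 0.5 * (_LOG_2PI + math.log(sigma2)) - (d - mu) ** 2 / (
        2.0 * sigma2
    )


def build_pair_score_table(
    fd: FitnessData,
    topologies: Sequence[Topology] | None = None,
) -> PairScoreTable:
    """Precompute the four topology scores for every unordered gene pair.

    Every pair of the gene set must have an observed (or imputed)
    double-mutant fitness; a missing entry raises :class:`MissingDataError`
    pointing the caller to ``preprocess.impute_missing``.
    """
    if topologies is None:
        topologies = default_topologies()
    if {t.kind for t in topologies} != set(TopologyKind):
        raise InvalidInputError("topologies must cover all four kinds exactly once")
    by_kind = {t.kind: t for t in topologies}

    n = len(fd.genes)
    scores = np.full((n, n, 4), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            d = fd.D[i, j]
            if not np.isfinite(d):
                raise MissingDataError(
                    f"D({fd.genes[i]}, {fd.genes[j]}) is missing; run "
                    "preprocess.impute_missing first"
                )
            s_x, s_y, e_xy = fd.S[i], fd.S[j], fd.E[i, j]
            sig2 = fd.sigma2_for(i, j)
            for kind in TopologyKind:
                t = by_kind[kind]
                mu = t.predicted_mean(s_x, s_y, e_xy)
                val = topology_log_score(float(d), mu, sig2, t.prior)
                scores[i, j, kind.value] = val
                scores[j, i, kind.value] = val  # stored w.r.t. smaller index
    return PairScoreTable(fd.genes, scores)


def induced_topology(n: PathwayNetwork, x: str, y: str) -> TopologyKind:
    """The pair topology a candidate DAG induces for (x, y).

    Ancestry, not adjacency, drives the classification: any directed path
    y -> ... -> x makes x the downstream (fully epistatic) gene.
    """
    if x == y:
        raise InvalidInputError("pair genes must differ")
    ix, iy = n.genes.index(x), n.genes.index(y)
    desc = n.descendant_masks()
    if desc[iy] >> ix & 1:
        return TopologyKind.X_DOWNSTREAM
    if desc[ix] >> iy & 1:
        return TopologyKind.Y_DOWNSTREAM
    comp = n.component_labels()
    if comp[ix] == comp[iy]:
        return TopologyKind.PARALLEL
    return TopologyKind.UNLINKED


def log_global_score(n: PathwayNetwork, table: PairScoreTable) -> float:
    """Sum of induced pair scores; exp of this is the posterior weight f(N)."""
    if table.genes.genes != n.genes.genes:
        raise MissingDataError("score table does not cover the network's gene set")
    ng = len(n.genes)
    desc = n.descendant_masks()
    comp = n.component_labels()
    scores = table.scores
    total = 0.0
    for i in range(ng):
        di = desc[i]
        ci = comp[i]
        for j in range(i + 1, ng):
            if desc[j] >> i & 1:
                k = 0  # X_DOWNSTREAM: j is ancestor of i, i (=x) downstream
            elif di >> j & 1:
                k = 1  # Y_DOWNSTREAM
            elif ci == comp[j]:
                k = 2  # PARALLEL
            else:
                k = 3  # UNLINKED
            val = scores[i, j, k]
            if not np.isfinite(val):
                raise MissingDataError(
                    f"pair ({n.genes[i]}, {n.genes[j]}) missing from score table"
                )
            total += val
    return total
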