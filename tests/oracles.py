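"""Independent brute-force oracles used to check the implementation.

Everything here is written directly from first principles — literal
evaluation of the Gaussian pair-score densities (via scipy.stats.norm),
pair classification via networkx reachability, and exhaustive enumeration
of acyclic orientation-subsets — deliberately sharing no code with the
package under test.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
from scipy import stats


def brute_force_networks(genes, scaffold_edges):
    """All acyclic edge-orientation assignments of the scaffold, as DiGraphs."""
    out = []
    for states in itertools.product((0, 1, 2), repeat=len(scaffold_edges)):
        g = nx.DiGraph()
        g.add_nodes_from(genes)
        for (a, b), s in zip(scaffold_edges, states):
            if s == 1:
                g.add_edge(a, b)
            elif s == 2:
                g.add_edge(b, a)
        if nx.is_directed_acyclic_graph(g):
            out.append(g)
    return out


def literal_pair_score(d, mu, sigma2, prior):
    """ln(prior * Normal(d; mu, sigma2)) via scipy's density."""
    return math.log(prior) + stats.norm.logpdf(d, loc=mu, scale=math.sqrt(sigma2))


def classify_pair(g: nx.DiGraph, x, y):
    """Pair topology by networkx reachability: 0 x-downstream, 1 y-downstream,
    2 parallel (same weak component), 3 unlinked."""
    if nx.has_path(g, y, x):
        return 0
    if nx.has_path(g, x, y):
        return 1
    und = g.to_undirected()
    if nx.has_path(und, x, y):
        return 2
    return 3


def literal_log_f(g: nx.DiGraph, genes, pair_scores):
    """Literal global score: sum over unordered pairs of the induced entry.

    ``pair_scores[(x, y)]`` is a length-4 sequence in the classification
    order above, stored for x, y in ``genes`` order.
    """
    total = 0.0
    for i, x in enumerate(genes):
        for y in genes[i + 1 :]:
            total += pair_scores[(x, y)][classify_pair(g, x, y)]
    return total


def exact_network_posterior(genes, scaffold_edges, pair_scores):
    """Enumerate networks and normalize exp(log f) into probabilities."""
    nets = brute_force_networks(genes, scaffold_edges)
    logf = np.array([literal_log_f(g, genes, pair_scores) for g in nets])
    p = np.exp(logf - logf.max())
    return nets, p / p.sum()


def exact_edge_probability(genes, scaffold_edges, pair_scores, u, v):
    nets, p = exact_network_posterior(genes, scaffold_edges, pair_scores)
    return float(sum(pi for g, pi in zip(nets, p) if g.has_edge(u, v)))
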