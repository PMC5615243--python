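"""Ground-truth pathway simulation for end-to-end testing and benchmarks.

The generator is the exact probabilistic inverse of the scoring model: a
known pathway DAG fixes each gene pair's topology, the topology fixes the
predicted double-mutant fitness (downstream single-mutant fitness under
full epistasis, neutral expectation otherwise), and replicate noise is
Gaussian.  The protein-interaction scaffold handed to the sampler is the
true skeleton plus decoy edges, mimicking the redundancy of real PPI
networks.

Defaults model a typical yeast E-MAP setting: single-mutant fitnesses
uniform in (0.3, 0.9) — far enough from 0 and 1 that linear-topology
means separate from neutral products — and replicate standard deviation
0.05 fitness units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .model import FitnessData, GeneSet, PathwayNetwork, PPIGraph, Substructure
from .pooling import (
    best_structure,
    edge_confidence_map,
    linear_ordering_substructures,
)
from .sampler import make_schedule, run_ensemble
from .scoring import build_pair_score_table, induced_topology, neutral_expectation
from .model import TopologyKind

__all__ = ["SyntheticTruth", "generate_truth", "simulate_fitness", "recovery_experiment"]

DEFAULT_FITNESS_RANGE = (0.3, 0.9)
DEFAULT_SIGMA = 0.05

_SHAPES = ("chain", "tree", "two_parallel_chains", "random_dag")


@dataclass(frozen=True)
class SyntheticTruth:
    """A ground-truth pathway DAG with its (decoy-padded) scaffold."""

    truth: PathwayNetwork
    scaffold: PPIGraph
    sigma2: float
    fitness_range: tuple[float, float]
    decoy_edges: int

    def __post_init__(self) -> None:
        if not self.truth.in_scaffold(self.scaffold):
            raise InvalidInputError("truth skeleton must be contained in scaffold")


def generate_truth(
    n_genes: int,
    shape: str = "chain",
    decoy_edges: int = 0,
    rng: np.random.Generator | None = None,
    sigma: float = DEFAULT_SIGMA,
    fitness_range: tuple[float, float] = DEFAULT_FITNESS_RANGE,
    edge_prob: float = 0.3,
) -> SyntheticTruth:
    """Draw a ground-truth DAG of the requested shape plus decoy scaffold edges.

    Shapes: ``chain`` (linear pathway over a random gene order), ``tree``
    (random arborescence), ``two_parallel_chains`` (two disjoint linear
    pathways), ``random_dag`` (each forward pair wired with ``edge_prob``).
    """
    if n_genes < 2:
        raise InvalidInputError(f"need at least 2 genes, got {n_genes}")
    if decoy_edges < 0:
        raise InvalidInputError("decoy_edges must be >= 0")
    if shape not in _SHAPES:
        raise InvalidInputError(f"unknown shape {shape!r}; choose from {_SHAPES}")
    if rng is None:
        rng = np.random.default_rng()
    genes = GeneSet(f"g{i}" for i in range(n_genes))
    order = [genes[i] for i in rng.permutation(n_genes)]

    edges: list[tuple[str, str]] = []
    if shape == "chain":
        edges = list(zip(order, order[1:]))
    elif shape == "tree":
        for i in range(1, n_genes):
            parent = order[int(rng.integers(0, i))]
            edges.append((parent, order[i]))
    elif shape == "two_parallel_chains":
        half = n_genes // 2
        edges = list(zip(order[:half], order[1:half]))
        edges += list(zip(order[half:], order[half + 1 :]))
    elif shape == "random_dag":
        for i in range(n_genes):
            for j in range(i + 1, n_genes):
                if rng.random() < edge_prob:
                    edges.append((order[i], order[j]))
    truth = PathwayNetwork(genes, edges)

    skeleton = truth.skeleton()
    non_edges = [
        (genes[i], genes[j])
        for i in range(n_genes)
        for j in range(i + 1, n_genes)
        if (genes[i], genes[j]) not in skeleton
    ]
    if decoy_edges > len(non_edges):
        raise InvalidInputError(
            f"requested {decoy_edges} decoy edges but only {len(non_edges)} "
            "non-adjacent pairs exist"
        )
    chosen = [non_edges[k] for k in rng.choice(len(non_edges), decoy_edges, replace=False)] if decoy_edges else []
    scaffold = PPIGraph(genes, list(skeleton) + chosen)
    return SyntheticTruth(truth, scaffold, sigma**2, fitness_range, decoy_edges)


def simulate_fitness(
    t: SyntheticTruth,
    rng: np.random.Generator | None = None,
    e_mode: str = "multiplicative",
) -> FitnessData:
    """Simulate single- and double-mutant fitness under the true pathway.

    D(x, y) is the pair's topology-predicted mean plus N(0, sigma2) noise,
    truncated at 0 (fitness cannot be negative); E holds the neutral
    expectation.  With sigma = 0 the data are exactly the model means.
    """
    if rng is None:
        rng = np.random.default_rng()
    genes = t.truth.genes
    n = len(genes)
    lo, hi = t.fitness_range
    S = rng.uniform(lo, hi, size=n)
    D = np.full((n, n), np.nan)
    E = np.full((n, n), np.nan)
    sigma = float(np.sqrt(t.sigma2))
    for i in range(n):
        for j in range(i + 1, n):
            x, y = genes[i], genes[j]
            e_xy = neutral_expectation(S[i], S[j], e_mode)
            kind = induced_topology(t.truth, x, y)
            if kind is TopologyKind.X_DOWNSTREAM:
                mu = S[i]
            elif kind is TopologyKind.Y_DOWNSTREAM:
                mu = S[j]
            else:
                mu = e_xy
            d = mu + (sigma * rng.standard_normal() if sigma > 0 else 0.0)
            D[i, j] = D[j, i] = max(d, 0.0)
            E[i, j] = E[j, i] = e_xy
    # score-side variance must stay positive even for noiseless data
    sigma2_model = t.sigma2 if t.sigma2 > 0 else 1e-4
    return FitnessData(genes, S, D, E, sigma2_model)


def recovery_experiment(
    n_genes: int,
    shape: str,
    sigma: float,
    K: int,
    m: int,
    seeds: list[int],
    decoy_edges: int = 3,
    steps_per_level: int = 1,
) -> float:
    """Fraction of simulations in which the true structure is recovered.

    For each seed: generate a truth, simulate fitness, score, run the
    annealed importance sampler, and pool.  A chain counts as recovered
    when the true gene ordering is the maximal-confidence linear ordering;
    any other shape counts when, for every scaffold pair, the maximal-
    confidence state (forward / backward / absent) matches the truth.
    """
    if not seeds:
        raise InvalidInputError("need at least one seed")
    successes = 0
    for seed in seeds:
        rng = np.random.default_rng(seed)
        t = generate_truth(
            n_genes, shape, decoy_edges, rng, sigma=sigma
        )
        fd = simulate_fitness(t, rng)
        table = build_pair_score_table(fd)
        schedule = make_schedule(m)
        ensemble = run_ensemble(
            table, t.scaffold, schedule, K, steps_per_level, base_seed=seed
        )
        if shape == "chain":
            true_order = _chain_order(t.truth)
            candidates = linear_ordering_substructures(t.truth.genes)
            best, _ = best_structure(ensemble, candidates)
            want = Substructure(
                required_orderings=list(zip(true_order, true_order[1:]))
            )
            ok = best == want
        else:
            conf = edge_confidence_map(ensemble)
            ok = True
            for a, b in t.scaffold.sorted_edges():
                states = {
                    (a, b): conf[(a, b)],
                    (b, a): conf[(b, a)],
                    None: 1.0 - conf[(a, b)] - conf[(b, a)],
                }
                arg = max(states, key=states.get)
                if (a, b) in t.truth.directed_edges or (b, a) in t.truth.directed_edges:
                    true_state = (a, b) if (a, b) in t.truth.directed_edges else (b, a)
                else:
                    true_state = None
                if arg != true_state:
                    ok = False
                    break
        successes += ok
    return successes / len(seeds)


def _chain_order(truth: PathwayNetwork) -> list[str]:
    children = dict(truth.directed_edges)
    heads = set(children) - set(children.values())
    if len(heads) != 1:
        raise InvalidInputError("network is not a single chain")
    order = [heads.pop()]
    while order[-1] in children:
        order.append(children[order[-1]])
    return order
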