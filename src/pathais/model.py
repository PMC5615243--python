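"""Core domain types for pathway-network inference.

A *pathway network* is a directed acyclic graph over gene-activity nodes
whose skeleton is contained in an undirected protein-interaction scaffold.
Quantitative genetic-interaction data (single- and double-mutant fitness)
score candidate networks; an annealed importance sampler draws weighted
networks; pooling turns the weighted ensemble into substructure confidences.

All log-scores in the package are natural-log (nats).  Double-mutant
fitness matrices use ``nan`` as the explicit missing marker — 0 is a valid
(lethal) fitness and never means "missing".
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

from .errors import CyclicNetworkError, InvalidInputError

__all__ = [
    "GeneSet",
    "FitnessData",
    "PPIGraph",
    "TopologyKind",
    "Topology",
    "default_topologies",
    "PairScoreTable",
    "PathwayNetwork",
    "AnnealingSchedule",
    "WeightedSample",
    "SampleEnsemble",
    "Substructure",
    "validate",
]


@dataclass(frozen=True)
class GeneSet:
    """Ordered collection of unique gene identifiers.

    The order is load-bearing: every matrix in the package is indexed by
    this order, so joins between fitness tables and edge lists are stable.
    """

    genes: tuple[str, ...]

    def __init__(self, genes: Iterable[str]):
        genes = tuple(genes)
        if not genes:
            raise InvalidInputError("GeneSet must be non-empty")
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise InvalidInputError(f"duplicate gene identifiers: {dupes}")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(genes)})

    def index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise InvalidInputError(f"unknown gene {gene!r}") from None

    def __contains__(self, gene: object) -> bool:
        return gene in self._index

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.genes)

    def __getitem__(self, i: int) -> str:
        return self.genes[i]

    def pairs(self) -> Iterator[tuple[str, str]]:
        """Unordered gene pairs in index order (i < j)."""
        n = len(self.genes)
        for i in range(n):
            for j in range(i + 1, n):
                yield self.genes[i], self.genes[j]


@dataclass
class FitnessData:
    """Single- and double-mutant fitness measurements for a gene set.

    Attributes
    ----------
    genes
        Gene universe; all matrices are indexed in this order.
    S
        Single-mutant fitness, one per gene (unitless, typically in (0, 1]).
    D
        Symmetric double-mutant fitness matrix; ``nan`` marks a missing
        measurement; the diagonal is ignored.
    E
        Symmetric matrix of the neutral ("typical") double-mutant
        expectation, same units as ``D``.
    sigma2
        Replicate variance of the fitness measurements (fitness²): a scalar
        applied to all pairs, or a per-pair symmetric matrix.
    """

    genes: GeneSet
    S: np.ndarray
    D: np.ndarray
    E: np.ndarray
    sigma2: float | np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.D = np.asarray(self.D, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        if not np.isscalar(self.sigma2):
            self.sigma2 = np.asarray(self.sigma2, dtype=float)

    def sigma2_for(self, i: int, j: int) -> float:
        if np.isscalar(self.sigma2):
            return float(self.sigma2)
        return float(self.sigma2[i, j])

    def n_genes(self) -> int:
        return len(self.genes)

    def observed(self, i: int, j: int) -> bool:
        return bool(np.isfinite(self.D[i, j]))


@dataclass(frozen=True)
class PPIGraph:
    """Undirected protein-interaction scaffold of allowed pathway edges."""

    genes: GeneSet
    edges: frozenset[tuple[str, str]]

    def __init__(self, genes: GeneSet, edges: Iterable[tuple[str, str]]):
        # Membership of endpoints is checked by validate(), not here, so a
        # mis-joined edge list can be loaded and reported rather than crash.
        canon = set()
        for a, b in edges:
            if a == b:
                raise InvalidInputError(f"self-loop on gene {a!r}")
            if a in genes and b in genes:
                first = genes.index(a) < genes.index(b)
            else:
                first = a < b
            canon.add((a, b) if first else (b, a))
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "edges", frozenset(canon))

    def has_edge(self, a: str, b: str) -> bool:
        ia, ib = self.genes.index(a), self.genes.index(b)
        pair = (a, b) if ia < ib else (b, a)
        return pair in self.edges

    def sorted_edges(self) -> list[tuple[str, str]]:
        idx = self.genes.index
        return sorted(self.edges, key=lambda e: (idx(e[0]), idx(e[1])))

    def __len__(self) -> int:
        return len(self.edges)


class TopologyKind(enum.Enum):
    """The four local pair topologies a candidate DAG can induce.

    For an unordered pair (x, y):

    * ``X_DOWNSTREAM`` — y is an ancestor of x (possibly indirect): x is the
      downstream, fully epistatic gene and the double-mutant fitness is
      predicted by S(x) alone.
    * ``Y_DOWNSTREAM`` — the mirror case; prediction S(y).
    * ``PARALLEL`` — neither gene is an ancestor of the other but they share
      a weakly connected component; prediction is the neutral expectation.
    * ``UNLINKED`` — different components; prediction is also the neutral
      expectation (the kinds differ only by their prior).
    """

    X_DOWNSTREAM = 0
    Y_DOWNSTREAM = 1
    PARALLEL = 2
    UNLINKED = 3


def _mean_x(s_x: float, s_y: float, e_xy: float) -> float:
    return s_x


def _mean_y(s_x: float, s_y: float, e_xy: float) -> float:
    return s_y


def _mean_e(s_x: float, s_y: float, e_xy: float) -> float:
    return e_xy


_PREDICTED_MEANS: dict[TopologyKind, Callable[[float, float, float], float]] = {
    TopologyKind.X_DOWNSTREAM: _mean_x,
    TopologyKind.Y_DOWNSTREAM: _mean_y,
    TopologyKind.PARALLEL: _mean_e,
    TopologyKind.UNLINKED: _mean_e,
}


@dataclass(frozen=True)
class Topology:
    """A topology kind together with its prior probability."""

    kind: TopologyKind
    prior: float

    def __post_init__(self) -> None:
        if not 0.0 < self.prior <= 1.0:
            raise InvalidInputError(f"prior must be in (0, 1], got {self.prior}")

    def predicted_mean(self, s_x: float, s_y: float, e_xy: float) -> float:
        """Predicted double-mutant fitness under this pair topology."""
        return _PREDICTED_MEANS[self.kind](s_x, s_y, e_xy)


def default_topologies(
    priors: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> tuple[Topology, ...]:
    """The four topologies in enum order with the given priors (sum to 1)."""
    if len(priors) != 4:
        raise InvalidInputError("need exactly four priors")
    if abs(sum(priors) - 1.0) > 1e-12:
        raise InvalidInputError(f"priors must sum to 1, got {sum(priors)}")
    return tuple(Topology(kind, p) for kind, p in zip(TopologyKind, priors))


class PairScoreTable:
    """Precomputed log-scores Score_t(x, y) for every unordered pair.

    Scores are stored in a dense (n, n, 4) array in nats.  The third axis
    is ordered by :class:`TopologyKind`; the X/Y-downstream entries are
    stored with respect to the gene with the *smaller* index named x, and
    :meth:`get` swaps them transparently when queried the other way round.
    """

    def __init__(self, genes: GeneSet, scores: np.ndarray):
        scores = np.asarray(scores, dtype=float)
        n = len(genes)
        if scores.shape != (n, n, 4):
            raise InvalidInputError(f"scores must have shape {(n, n, 4)}")
        self.genes = genes
        self.scores = scores

    def get(self, x: str, y: str, kind: TopologyKind) -> float:
        i, j = self.genes.index(x), self.genes.index(y)
        if i == j:
            raise InvalidInputError("pair genes must differ")
        if i > j:
            i, j = j, i
            if kind is TopologyKind.X_DOWNSTREAM:
                kind = TopologyKind.Y_DOWNSTREAM
            elif kind is TopologyKind.Y_DOWNSTREAM:
                kind = TopologyKind.X_DOWNSTREAM
        return float(self.scores[i, j, kind.value])

    def pair_scores(self, i: int, j: int) -> np.ndarray:
        """The four scores for pair (i, j), i < j, in TopologyKind order."""
        return self.scores[i, j]


def _toposort(n_nodes: int, children: list[list[int]]) -> list[int] | None:
    """Kahn's algorithm; returns None on a cycle."""
    indeg = [0] * n_nodes
    for u in range(n_nodes):
        for v in children[u]:
            indeg[v] += 1
    stack = [u for u in range(n_nodes) if indeg[u] == 0]
    order = []
    while stack:
        u = stack.pop()
        order.append(u)
        for v in children[u]:
            indeg[v] -= 1
            if indeg[v] == 0:
                stack.append(v)
    return order if len(order) == n_nodes else None


@dataclass(frozen=True)
class PathwayNetwork:
    """One candidate pathway: a DAG over gene-activity nodes.

    Acyclicity is enforced at construction.  Containment of the skeleton in
    a scaffold is checked where the scaffold is known (sampler, validate).
    """

    genes: GeneSet
    directed_edges: frozenset[tuple[str, str]]

    def __init__(self, genes: GeneSet, directed_edges: Iterable[tuple[str, str]]):
        edges = frozenset(directed_edges)
        for u, v in edges:
            if u == v:
                raise InvalidInputError(f"self-loop on gene {u!r}")
            genes.index(u)
            genes.index(v)
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "directed_edges", edges)
        n = len(genes)
        children: list[list[int]] = [[] for _ in range(n)]
        for u, v in edges:
            children[genes.index(u)].append(genes.index(v))
        if _toposort(n, children) is None:
            raise CyclicNetworkError("directed edges contain a cycle")
        object.__setattr__(self, "_children", children)

    # --- index-level reachability helpers (bitmask descendants) -----------

    def descendant_masks(self) -> list[int]:
        """For each node index, a bitmask of all strict descendants."""
        n = len(self.genes)
        children: list[list[int]] = self._children
        order = _toposort(n, children)
        assert order is not None
        desc = [0] * n
        for u in reversed(order):
            m = 0
            for v in children[u]:
                m |= (1 << v) | desc[v]
            desc[u] = m
        return desc

    def component_labels(self) -> list[int]:
        """Weakly-connected-component label per node index (union-find)."""
        n = len(self.genes)
        parent = list(range(n))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for u, v in self.directed_edges:
            ra, rb = find(self.genes.index(u)), find(self.genes.index(v))
            if ra != rb:
                parent[ra] = rb
        return [find(i) for i in range(n)]

    def is_ancestor(self, u: str, v: str) -> bool:
        """True iff a directed path u -> ... -> v exists."""
        iu, iv = self.genes.index(u), self.genes.index(v)
        return bool(self.descendant_masks()[iu] >> iv & 1)

    def skeleton(self) -> frozenset[tuple[str, str]]:
        idx = self.genes.index
        return frozenset(
            (u, v) if idx(u) < idx(v) else (v, u) for u, v in self.directed_edges
        )

    def in_scaffold(self, ppi: PPIGraph) -> bool:
        return self.skeleton() <= ppi.edges

    def sorted_edges(self) -> list[tuple[str, str]]:
        idx = self.genes.index
        return sorted(self.directed_edges, key=lambda e: (idx(e[0]), idx(e[1])))

    def __len__(self) -> int:
        return len(self.directed_edges)


@dataclass(frozen=True)
class AnnealingSchedule:
    """Inverse-temperature ladder 1 = beta_0 > ... > beta_{m-1} = 0."""

    betas: tuple[float, ...]
    temperatures: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        betas = tuple(float(b) for b in self.betas)
        object.__setattr__(self, "betas", betas)
        if len(betas) < 2:
            raise InvalidInputError("schedule needs at least two levels")
        if betas[0] != 1.0 or betas[-1] != 0.0:
            raise InvalidInputError("schedule must start at beta=1 and end at beta=0")
        if any(b1 <= b2 for b1, b2 in zip(betas, betas[1:])):
            raise InvalidInputError("betas must be strictly decreasing")

    def __len__(self) -> int:
        return len(self.betas)


@dataclass(frozen=True)
class WeightedSample:
    """One annealing-run output: a network and its log importance weight."""

    network: PathwayNetwork
    log_weight: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_weight):
            raise InvalidInputError("log_weight must be finite")


@dataclass(frozen=True)
class SampleEnsemble:
    """K weighted networks from K independent annealing runs."""

    samples: tuple[WeightedSample, ...]
    scaffold: PPIGraph
    schedule: AnnealingSchedule
    seed: int

    def __init__(
        self,
        samples: Iterable[WeightedSample],
        scaffold: PPIGraph,
        schedule: AnnealingSchedule,
        seed: int,
    ):
        samples = tuple(samples)
        if not samples:
            raise InvalidInputError("ensemble must contain at least one sample")
        for s in samples:
            if s.network.genes is not scaffold.genes and s.network.genes != scaffold.genes:
                raise InvalidInputError("all networks must share the scaffold's GeneSet")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "scaffold", scaffold)
        object.__setattr__(self, "schedule", schedule)
        object.__setattr__(self, "seed", seed)

    def log_weights(self) -> np.ndarray:
        return np.array([s.log_weight for s in self.samples])

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class Substructure:
    """A conjunction of required directed edges and ancestry orderings.

    ``required_edges`` demand exact directed edges; ``required_orderings``
    (upstream, downstream) demand only a directed path.  Empty substructure
    matches every network.
    """

    required_edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)
    required_orderings: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __init__(
        self,
        required_edges: Iterable[tuple[str, str]] = (),
        required_orderings: Iterable[tuple[str, str]] = (),
    ):
        object.__setattr__(self, "required_edges", frozenset(required_edges))
        object.__setattr__(self, "required_orderings", frozenset(required_orderings))

    def gene_names(self) -> set[str]:
        out: set[str] = set()
        for u, v in self.required_edges | self.required_orderings:
            out.add(u)
            out.add(v)
        return out


def validate(fd: FitnessData, ppi: PPIGraph) -> list[str]:
    """Cross-check a fitness dataset against a scaffold; returns issues.

    An empty list means every invariant holds and the gene sets agree.
    """
    issues: list[str] = []
    n = len(fd.genes)
    if fd.S.shape != (n,):
        issues.append(f"S has shape {fd.S.shape}, expected ({n},)")
    for name, mat in (("D", fd.D), ("E", fd.E)):
        if mat.shape != (n, n):
            issues.append(f"{name} has shape {mat.shape}, expected ({n}, {n})")
            continue
        both = np.isfinite(mat) & np.isfinite(mat.T)
        bad = np.argwhere(both & ~np.isclose(mat, mat.T, rtol=0, atol=1e-12))
        for i, j in bad:
            if i < j:
                issues.append(
                    f"{name} asymmetric at ({fd.genes[i]}, {fd.genes[j]}): "
                    f"{mat[i, j]} vs {mat[j, i]}"
                )
    if np.isscalar(fd.sigma2):
        if not fd.sigma2 > 0:
            issues.append(f"sigma2 must be positive, got {fd.sigma2}")
    else:
        if fd.sigma2.shape != (n, n):
            issues.append(f"sigma2 matrix has shape {fd.sigma2.shape}, expected ({n}, {n})")
        elif not np.all(fd.sigma2[~np.eye(n, dtype=bool)] > 0):
            issues.append("sigma2 matrix has non-positive off-diagonal entries")
    if np.any(fd.S < 0):
        issues.append("negative single-mutant fitness values")
    for a, b in ppi.edges:
        for g in (a, b):
            if g not in fd.genes:
                issues.append(f"scaffold edge endpoint {g!r} not in gene set")
    if ppi.genes.genes != fd.genes.genes:
        issues.append("scaffold GeneSet differs from fitness GeneSet")
    return issues
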