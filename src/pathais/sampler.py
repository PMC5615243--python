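"""Annealed importance sampling of pathway networks.

Target distribution: p(N | D) proportional to f(N) = exp(global score),
restricted to directed acyclic subgraphs of the protein-interaction
scaffold.  A ladder of tempered distributions p_j proportional to
f(N)^{beta_j} (1 = beta_0 > ... > beta_{m-1} = 0) connects the uniform
distribution over all acyclic orientations of scaffold subsets to the
target.  Each annealing run starts from an exact uniform draw, applies
Metropolis–Hastings transitions level by level while the temperature
cools, and accumulates the standard AIS telescoping importance weight

    log w = sum_{j=0}^{m-2} (beta_j - beta_{j+1}) * log f(n_{j+1}),

where n_{j+1} is the state entering level j.  Because every tempered
distribution shares the same support, the uniform base density cancels
from the weight.  K independent runs form a weighted ensemble that the
pooling module turns into substructure confidences.

Moves are edge-local: for each scaffold edge absent from the current
network two orientations can be added; each present directed edge can be
deleted or reversed; moves creating a cycle are excluded.  The proposal
is uniform over this legal set, with a Hastings correction for the
changing set size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import InvalidInputError, NoMoveError
from .model import (
    AnnealingSchedule,
    PairScoreTable,
    PathwayNetwork,
    PPIGraph,
    SampleEnsemble,
    WeightedSample,
)
from .scoring import log_global_score

__all__ = [
    "MoveProposal",
    "make_schedule",
    "schedule_from_temperatures",
    "sample_initial",
    "legal_moves",
    "apply_move",
    "propose",
    "mh_step",
    "annealing_run",
    "run_ensemble",
    "effective_sample_size",
]

MoveKind = Literal["add", "delete", "reverse"]


@dataclass(frozen=True)
class MoveProposal:
    """One elementary edit of a candidate network."""

    kind: MoveKind
    edge: tuple[str, str]


def make_schedule(m: int, shape: str = "linear") -> AnnealingSchedule:
    """Build an inverse-temperature ladder of m levels from 1 down to 0.

    ``linear`` spaces the betas evenly; ``geometric`` concentrates levels
    near beta = 0 (useful when the target is very peaked), with the floor
    pinned exactly at 0.
    """
    if m < 2:
        raise InvalidInputError(f"need at least 2 levels, got {m}")
    if shape == "linear":
        betas = np.linspace(1.0, 0.0, m)
    elif shape == "geometric":
        eps = 1e-3
        raw = np.geomspace(1.0, eps, m)
        betas = (raw - eps) / (1.0 - eps)
    else:
        raise InvalidInputError(f"unknown schedule shape {shape!r}")
    betas[0], betas[-1] = 1.0, 0.0
    return AnnealingSchedule(tuple(betas))


def schedule_from_temperatures(temps) -> AnnealingSchedule:
    """Convert a temperature vector into a beta ladder.

    Temperatures are normalized to [0, 1] and reversed so the hottest
    level maps to beta = 0 and the coldest to beta = 1.
    """
    t = np.asarray(list(temps), dtype=float)
    if t.size < 2:
        raise InvalidInputError("need at least 2 temperatures")
    t = np.sort(t)
    lo, hi = t[0], t[-1]
    if hi <= lo:
        raise InvalidInputError("temperatures must not all be equal")
    betas = 1.0 - (t - lo) / (hi - lo)
    return AnnealingSchedule(tuple(betas))


def sample_initial(ppi: PPIGraph, rng: np.random.Generator) -> PathwayNetwork:
    """Exact uniform draw over all acyclic directed subgraphs of the scaffold.

    Rejection construction: each scaffold edge is independently absent,
    forward, or backward with probability 1/3; cyclic outcomes are redrawn
    wholesale.  Every acyclic outcome has equal probability, so the
    accepted draw is exactly uniform.
    """
    edges = ppi.sorted_edges()
    if not edges:
        return PathwayNetwork(ppi.genes, ())
    idx = ppi.genes.index
    n = len(ppi.genes)
    while True:
        states = rng.integers(0, 3, size=len(edges))
        directed = []
        for (a, b), s in zip(edges, states):
            if s == 1:
                directed.append((a, b))
            elif s == 2:
                directed.append((b, a))
        if _is_acyclic_edges(n, [(idx(u), idx(v)) for u, v in directed]):
            return PathwayNetwork(ppi.genes, directed)


def _is_acyclic_edges(n: int, edges: list[tuple[int, int]]) -> bool:
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = [0] * n
    for u, v in edges:
        children[u].append(v)
        indeg[v] += 1
    stack = [u for u in range(n) if indeg[u] == 0]
    seen = 0
    while stack:
        u = stack.pop()
        seen += 1
        for v in children[u]:
            indeg[v] -= 1
            if indeg[v] == 0:
                stack.append(v)
    return seen == n


def legal_moves(n: PathwayNetwork, ppi: PPIGraph) -> list[MoveProposal]:
    """All acyclicity-preserving single-edge moves, in deterministic order."""
    desc = n.descendant_masks()
    idx = n.genes.index
    present = n.directed_edges
    moves: list[MoveProposal] = []
    for a, b in ppi.sorted_edges():
        ia, ib = idx(a), idx(b)
        if (a, b) in present or (b, a) in present:
            u, v = (a, b) if (a, b) in present else (b, a)
            moves.append(MoveProposal("delete", (u, v)))
            if _reverse_ok(n, u, v):
                moves.append(MoveProposal("reverse", (u, v)))
        else:
            # add a->b cycles iff b already reaches a, and vice versa
            if not (desc[ib] >> ia & 1):
                moves.append(MoveProposal("add", (a, b)))
            if not (desc[ia] >> ib & 1):
                moves.append(MoveProposal("add", (b, a)))
    return moves


def _reverse_ok(n: PathwayNetwork, u: str, v: str) -> bool:
    """Reversing u->v stays acyclic iff u is unreachable from v and no
    alternative u->...->v path survives the removal."""
    idx = n.genes.index
    iu, iv = idx(u), idx(v)
    children: list[list[int]] = [[] for _ in range(len(n.genes))]
    for a, b in n.directed_edges:
        if (a, b) != (u, v):
            children[idx(a)].append(idx(b))
    # after removing u->v and adding v->u, a cycle exists iff u still
    # reaches v through some other path
    stack, seen = [iu], {iu}
    while stack:
        x = stack.pop()
        for y in children[x]:
            if y == iv:
                return False
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return True


def apply_move(n: PathwayNetwork, move: MoveProposal) -> PathwayNetwork:
    edges = set(n.directed_edges)
    if move.kind == "add":
        edges.add(move.edge)
    elif move.kind == "delete":
        edges.remove(move.edge)
    elif move.kind == "reverse":
        u, v = move.edge
        edges.remove((u, v))
        edges.add((v, u))
    else:  # pragma: no cover - guarded by MoveKind
        raise InvalidInputError(f"unknown move kind {move.kind!r}")
    return PathwayNetwork(n.genes, edges)


def propose(
    n: PathwayNetwork, ppi: PPIGraph, rng: np.random.Generator
) -> MoveProposal:
    """Uniform draw from the legal move set."""
    moves = legal_moves(n, ppi)
    if not moves:
        raise NoMoveError("no legal moves: the scaffold has no edges")
    return moves[rng.integers(0, len(moves))]


def mh_step(
    n: PathwayNetwork,
    beta: float,
    table: PairScoreTable,
    ppi: PPIGraph,
    rng: np.random.Generator,
) -> PathwayNetwork:
    """One Metropolis–Hastings transition targeting f(N)^beta."""
    new, _ = _mh_step_scored(n, log_global_score(n, table), beta, table, ppi, rng)
    return new


def _mh_step_scored(
    n: PathwayNetwork,
    logf_n: float,
    beta: float,
    table: PairScoreTable,
    ppi: PPIGraph,
    rng: np.random.Generator,
) -> tuple[PathwayNetwork, float]:
    """MH transition carrying the current log-score to avoid recomputation."""
    moves = legal_moves(n, ppi)
    if not moves:
        raise NoMoveError("no legal moves: the scaffold has no edges")
    move = moves[rng.integers(0, len(moves))]
    candidate = apply_move(n, move)
    logf_c = log_global_score(candidate, table)
    # Hastings correction: proposal prob is 1/|moves|, so the ratio is
    # |moves(n)| / |moves(candidate)|
    log_accept = beta * (logf_c - logf_n) + math.log(len(moves)) - math.log(
        len(legal_moves(candidate, ppi))
    )
    if log_accept >= 0 or rng.random() < math.exp(log_accept):
        return candidate, logf_c
    return n, logf_n


def annealing_run(
    table: PairScoreTable,
    ppi: PPIGraph,
    schedule: AnnealingSchedule,
    steps_per_level: int = 1,
    rng: np.random.Generator | None = None,
) -> WeightedSample:
    """One annealing run: uniform start, tempered MH sweeps, AIS weight."""
    if steps_per_level < 1:
        raise InvalidInputError("steps_per_level must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    betas = schedule.betas
    state = sample_initial(ppi, rng)
    logf = log_global_score(state, table)
    log_w = 0.0
    for j in range(len(betas) - 2, -1, -1):
        log_w += (betas[j] - betas[j + 1]) * logf
        for _ in range(steps_per_level):
            state, logf = _mh_step_scored(state, logf, betas[j], table, ppi, rng)
    return WeightedSample(state, log_w)


def run_ensemble(
    table: PairScoreTable,
    ppi: PPIGraph,
    schedule: AnnealingSchedule,
    K: int,
    steps_per_level: int = 1,
    base_seed: int = 0,
) -> SampleEnsemble:
    """K independent annealing runs with deterministically derived streams.

    Per-run generators are spawned from ``base_seed`` via
    ``numpy.random.SeedSequence``, so the ensemble is bit-reproducible for
    a fixed seed regardless of execution order.
    """
    if K < 1:
        raise InvalidInputError(f"K must be >= 1, got {K}")
    children = np.random.SeedSequence(base_seed).spawn(K)
    samples = []
    for i, child in enumerate(children):
        try:
            samples.append(
                annealing_run(
                    table, ppi, schedule, steps_per_level, np.random.default_rng(child)
                )
            )
        except NoMoveError as err:
            raise NoMoveError(f"annealing run {i}: {err}") from err
    return SampleEnsemble(samples, ppi, schedule, base_seed)


def effective_sample_size(ensemble: SampleEnsemble) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2, from log-weights."""
    lw = ensemble.log_weights()
    lw = lw - lw.max()
    w = np.exp(lw)
    return float(w.sum() ** 2 / (w**2).sum())
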