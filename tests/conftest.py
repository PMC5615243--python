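import numpy as np
import pytest

from pathais.model import (
    FitnessData,
    GeneSet,
    PairScoreTable,
    PPIGraph,
)
from pathais.scoring import neutral_expectation


@pytest.fixture
def genes3():
    return GeneSet(["a", "b", "c"])


@pytest.fixture
def triangle(genes3):
    return PPIGraph(genes3, [("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def single_edge():
    gs = GeneSet(["x", "y"])
    return PPIGraph(gs, [("x", "y")])


def make_fitness(genes, S, D, sigma2=0.0025):
    """Assemble a FitnessData with the multiplicative neutral expectation."""
    n = len(genes)
    E = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i != j:
                E[i, j] = neutral_expectation(S[i], S[j])
    return FitnessData(genes, np.asarray(S, float), np.asarray(D, float), E, sigma2)


@pytest.fixture
def fd3(genes3):
    S = [0.8, 0.9, 0.7]
    D = np.array(
        [
            [np.nan, 0.80, 0.56],
            [0.80, np.nan, 0.63],
            [0.56, 0.63, np.nan],
        ]
    )
    return make_fitness(genes3, S, D)


def duplicated_profile_fixture(n=15, seed=0):
    """Symmetric fitness matrix where g1 duplicates g0 and g3 duplicates g2.

    Entries follow D[i, j] = B[c(i), c(j)] for a random symmetric base B,
    with c collapsing each duplicate onto its partner, so the duplicated
    genes have identical interaction profiles.  Returns (fd, masked_value)
    after masking D(g0, g2); regression on the perfectly correlated
    partner profiles must restore the masked value exactly.
    """
    rng = np.random.default_rng(seed)
    genes = GeneSet(f"g{i}" for i in range(n))
    B = rng.uniform(0.1, 1.0, (n, n))
    B = (B + B.T) / 2

    def c(i):
        return {1: 0, 3: 2}.get(i, i)

    D = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i != j:
                D[i, j] = B[c(i), c(j)]
    truth = D[0, 2]
    D[0, 2] = D[2, 0] = np.nan
    fd = make_fitness(genes, rng.uniform(0.3, 0.9, n), D)
    return fd, truth


def random_table(genes, rng, scale=1.0):
    """A PairScoreTable with arbitrary finite scores (not from data)."""
    n = len(genes)
    scores = np.full((n, n, 4), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            vals = rng.normal(0.0, scale, size=4)
            scores[i, j] = vals
            scores[j, i] = vals
    return PairScoreTable(genes, scores)


def table_pair_dict(table):
    """Reshape a PairScoreTable into the oracle's {(x, y): 4-vector} form."""
    genes = list(table.genes)
    out = {}
    for i, x in enumerate(genes):
        for j in range(i + 1, len(genes)):
            out[(x, genes[j])] = table.scores[i, j]
    return out
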