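import itertools

import numpy as np
import pytest

from pathais.errors import InvalidInputError
from pathais.model import (
    GeneSet,
    PathwayNetwork,
    PPIGraph,
    SampleEnsemble,
    Substructure,
    WeightedSample,
)
from pathais.pooling import (
    best_structure,
    confidence,
    contains,
    edge_confidence_map,
    linear_ordering_substructures,
    single_edge_substructures,
)
from pathais.sampler import make_schedule


def make_ensemble(ppi, nets_and_logw, seed=0):
    samples = [WeightedSample(n, lw) for n, lw in nets_and_logw]
    return SampleEnsemble(samples, ppi, make_schedule(2), seed)


@pytest.fixture
def chain_genes():
    return GeneSet(["x", "y", "z"])


@pytest.fixture
def chain_ppi(chain_genes):
    return PPIGraph(chain_genes, [("x", "y"), ("y", "z"), ("x", "z")])


class TestContains:
    def test_empty_substructure_matches_everything(self, chain_genes):
        n = PathwayNetwork(chain_genes, ())
        assert contains(n, Substructure())

    def test_edge_subset(self, chain_genes):
        n = PathwayNetwork(chain_genes, [("x", "y"), ("y", "z")])
        assert contains(n, Substructure(required_edges=[("x", "y")]))
        assert not contains(n, Substructure(required_edges=[("y", "x")]))

    def test_ordering_via_ancestry(self, chain_genes):
        n = PathwayNetwork(chain_genes, [("x", "y"), ("y", "z")])
        assert contains(n, Substructure(required_orderings=[("x", "z")]))
        assert not contains(n, Substructure(required_orderings=[("z", "x")]))

    def test_unknown_gene_rejected(self, chain_genes):
        n = PathwayNetwork(chain_genes, ())
        with pytest.raises(InvalidInputError):
            contains(n, Substructure(required_edges=[("x", "nope")]))


class TestConfidence:
    def test_present_in_all_samples(self, chain_ppi, chain_genes):
        n = PathwayNetwork(chain_genes, [("x", "y")])
        ens = make_ensemble(chain_ppi, [(n, 0.3)] * 4)
        assert confidence(ens, Substructure(required_edges=[("x", "y")])) == 1.0

    def test_equal_weights_three_of_four(self, chain_ppi, chain_genes):
        with_edge = PathwayNetwork(chain_genes, [("x", "y")])
        without = PathwayNetwork(chain_genes, ())
        ens = make_ensemble(chain_ppi, [(with_edge, 1.0)] * 3 + [(without, 1.0)])
        s = Substructure(required_edges=[("x", "y")])
        assert confidence(ens, s) == pytest.approx(0.75)

    def test_weights_two_one_one(self, chain_ppi, chain_genes):
        with_edge = PathwayNetwork(chain_genes, [("x", "y")])
        without = PathwayNetwork(chain_genes, ())
        ens = make_ensemble(
            chain_ppi,
            [(with_edge, np.log(2.0)), (without, 0.0), (without, 0.0)],
        )
        s = Substructure(required_edges=[("x", "y")])
        assert confidence(ens, s) == pytest.approx(0.5)

    def test_rescaling_weights_is_invariant(self, chain_ppi, chain_genes):
        rng = np.random.default_rng(0)
        nets = [
            PathwayNetwork(chain_genes, [("x", "y")]),
            PathwayNetwork(chain_genes, ()),
            PathwayNetwork(chain_genes, [("y", "x"), ("y", "z")]),
        ]
        lw = rng.normal(size=3)
        s = Substructure(required_edges=[("y", "z")])
        c1 = confidence(make_ensemble(chain_ppi, zip(nets, lw)), s)
        c2 = confidence(make_ensemble(chain_ppi, zip(nets, lw + 123.4)), s)
        assert c1 == pytest.approx(c2, rel=1e-12)

    def test_monotone_in_added_constraints(self, chain_ppi, chain_genes):
        rng = np.random.default_rng(1)
        nets = []
        for _ in range(20):
            edges = []
            for a, b in chain_ppi.sorted_edges():
                r = rng.random()
                if r < 1 / 3:
                    edges.append((a, b))
                elif r < 2 / 3:
                    edges.append((b, a))
            try:
                nets.append(PathwayNetwork(chain_genes, edges))
            except InvalidInputError:
                nets.append(PathwayNetwork(chain_genes, ()))
        ens = make_ensemble(chain_ppi, [(n, rng.normal()) for n in nets])
        small = Substructure(required_edges=[("x", "y")])
        big = Substructure(required_edges=[("x", "y")], required_orderings=[("x", "z")])
        assert confidence(ens, big) <= confidence(ens, small) + 1e-15
        assert 0.0 <= confidence(ens, big) <= 1.0
        assert confidence(ens, Substructure()) == 1.0


class TestEdgeConfidenceMap:
    def test_identical_ensemble_gives_zero_one(self, chain_ppi, chain_genes):
        n = PathwayNetwork(chain_genes, [("x", "y")])
        conf = edge_confidence_map(make_ensemble(chain_ppi, [(n, 0.0)] * 3))
        assert conf[("x", "y")] == 1.0
        assert conf[("y", "x")] == 0.0
        assert conf[("y", "z")] == 0.0

    def test_sum_to_one_decomposition(self, chain_ppi, chain_genes):
        # uniform ensemble over the three states of each pair, built by hand
        nets = [
            PathwayNetwork(chain_genes, ()),
            PathwayNetwork(chain_genes, [("x", "y")]),
            PathwayNetwork(chain_genes, [("y", "x")]),
        ]
        ens = make_ensemble(chain_ppi, [(n, 0.0) for n in nets])
        conf = edge_confidence_map(ens)
        for a, b in chain_ppi.sorted_edges():
            absent = sum(
                1 / 3
                for n in nets
                if (a, b) not in n.directed_edges and (b, a) not in n.directed_edges
            )
            assert conf[(a, b)] + conf[(b, a)] + absent == pytest.approx(1.0)

    def test_rows_cover_both_orientations(self, chain_ppi, chain_genes):
        n = PathwayNetwork(chain_genes, ())
        conf = edge_confidence_map(make_ensemble(chain_ppi, [(n, 0.0)]))
        assert len(conf) == 2 * len(chain_ppi)


class TestBestStructure:
    def test_picks_maximal_confidence(self, chain_ppi, chain_genes):
        n = PathwayNetwork(chain_genes, [("x", "y")])
        ens = make_ensemble(chain_ppi, [(n, 0.0)] * 2)
        s_all = Substructure(required_edges=[("x", "y")])
        s_none = Substructure(required_edges=[("y", "x")])
        best, c = best_structure(ens, [s_none, s_all])
        assert best == s_all and c == 1.0

    def test_tie_broken_by_first_occurrence(self, chain_ppi, chain_genes):
        n = PathwayNetwork(chain_genes, [("x", "y")])
        ens = make_ensemble(chain_ppi, [(n, 0.0)])
        s1 = Substructure(required_edges=[("x", "y")])
        s2 = Substructure(required_orderings=[("x", "y")])
        best, c = best_structure(ens, [s2, s1])  # both have confidence 1
        assert best == s2

    def test_empty_candidates_rejected(self, chain_ppi, chain_genes):
        n = PathwayNetwork(chain_genes, ())
        ens = make_ensemble(chain_ppi, [(n, 0.0)])
        with pytest.raises(InvalidInputError):
            best_structure(ens, [])

    def test_linear_ordering_argmax_matches_brute_force(self, chain_ppi, chain_genes):
        rng = np.random.default_rng(3)
        nets, lws = [], []
        for _ in range(30):
            edges = []
            for a, b in chain_ppi.sorted_edges():
                r = rng.random()
                if r < 0.45:
                    edges.append((a, b))
                elif r < 0.6:
                    edges.append((b, a))
            try:
                nets.append(PathwayNetwork(chain_genes, edges))
            except InvalidInputError:
                continue
            lws.append(rng.normal())
        ens = make_ensemble(chain_ppi, zip(nets, lws))
        cands = linear_ordering_substructures(chain_genes)
        best, c = best_structure(ens, cands)
        # brute force over the same candidates with plain normalized weights
        w = np.exp(np.array(lws) - max(lws))
        w /= w.sum()
        def brute_conf(s):
            return sum(wi for wi, n in zip(w, nets) if contains(n, s))
        expected = max(cands, key=lambda s: (brute_conf(s),))
        assert c == pytest.approx(brute_conf(expected))


class TestGenerators:
    def test_single_edge_generator_covers_scaffold(self, chain_ppi):
        subs = single_edge_substructures(chain_ppi)
        assert len(subs) == 2 * len(chain_ppi)

    def test_ordering_generator_size_and_cap(self):
        assert len(linear_ordering_substructures(["a", "b", "c"])) == 6
        with pytest.raises(InvalidInputError):
            linear_ordering_substructures([f"g{i}" for i in range(8)])
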