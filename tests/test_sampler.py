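import numpy as np
import pytest
from scipy import stats

from pathais.errors import InvalidInputError, NoMoveError
from pathais.model import GeneSet, PathwayNetwork, PPIGraph
from pathais.sampler import (
    annealing_run,
    apply_move,
    effective_sample_size,
    legal_moves,
    make_schedule,
    mh_step,
    propose,
    run_ensemble,
    sample_initial,
    schedule_from_temperatures,
)
from pathais.scoring import log_global_score

from conftest import random_table
from oracles import exact_network_posterior


class TestSchedule:
    def test_two_levels_is_plain_importance_sampling(self):
        assert make_schedule(2).betas == (1.0, 0.0)

    def test_linear_spacing(self):
        assert make_schedule(3).betas == (1.0, 0.5, 0.0)

    @pytest.mark.parametrize("shape", ["linear", "geometric"])
    def test_endpoints_and_monotonicity(self, shape):
        betas = make_schedule(5, shape).betas
        assert betas[0] == 1.0 and betas[-1] == 0.0
        assert all(a > b for a, b in zip(betas, betas[1:]))

    def test_too_few_levels(self):
        with pytest.raises(InvalidInputError):
            make_schedule(1)

    def test_temperature_vector_conversion(self):
        s = schedule_from_temperatures([1.0, 2.0, 4.0])
        assert s.betas[0] == 1.0 and s.betas[-1] == 0.0
        assert len(s) == 3


class TestSampleInitial:
    def test_single_edge_uniform_over_three_states(self, single_edge):
        rng = np.random.default_rng(42)
        counts = {"empty": 0, "fwd": 0, "rev": 0}
        for _ in range(10_000):
            n = sample_initial(single_edge, rng)
            if not n.directed_edges:
                counts["empty"] += 1
            elif ("x", "y") in n.directed_edges:
                counts["fwd"] += 1
            else:
                counts["rev"] += 1
        _, p = stats.chisquare(list(counts.values()))
        assert p > 1e-3  # consistent with uniform over the 3 acyclic states

    def test_empty_scaffold_gives_empty_network(self, genes3):
        ppi = PPIGraph(genes3, [])
        n = sample_initial(ppi, np.random.default_rng(0))
        assert len(n) == 0

    def test_triangle_never_cyclic(self, triangle):
        rng = np.random.default_rng(7)
        for _ in range(500):
            n = sample_initial(triangle, rng)  # constructor asserts acyclicity
            assert n.in_scaffold(triangle)


class TestMoves:
    def test_empty_network_on_single_edge(self, single_edge):
        n = PathwayNetwork(single_edge.genes, ())
        moves = legal_moves(n, single_edge)
        assert {(m.kind, m.edge) for m in moves} == {
            ("add", ("x", "y")),
            ("add", ("y", "x")),
        }

    def test_chain_reverse_is_legal(self):
        genes = GeneSet(["x", "y", "z"])
        ppi = PPIGraph(genes, [("x", "y"), ("y", "z")])
        n = PathwayNetwork(genes, [("x", "y"), ("y", "z")])
        moves = legal_moves(n, ppi)
        assert ("reverse", ("x", "y")) in {(m.kind, m.edge) for m in moves}

    def test_cycle_closing_add_excluded(self, genes3, triangle):
        n = PathwayNetwork(genes3, [("a", "b"), ("b", "c")])
        kinds = {(m.kind, m.edge) for m in legal_moves(n, triangle)}
        assert ("add", ("c", "a")) not in kinds
        assert ("add", ("a", "c")) in kinds

    def test_propose_errors_on_empty_scaffold(self, genes3):
        ppi = PPIGraph(genes3, [])
        n = PathwayNetwork(genes3, ())
        with pytest.raises(NoMoveError):
            propose(n, ppi, np.random.default_rng(0))

    def test_apply_move_roundtrip(self, single_edge):
        n = PathwayNetwork(single_edge.genes, ())
        m = propose(n, single_edge, np.random.default_rng(1))
        n2 = apply_move(n, m)
        assert len(n2) == 1


class TestMHStep:
    def test_stationary_distribution_on_single_edge(self, single_edge):
        """Long MH chain at beta=1 matches the enumeration-exact posterior."""
        genes = single_edge.genes
        rng = np.random.default_rng(5)
        table = random_table(genes, rng)
        pair_scores = {("x", "y"): table.scores[0, 1]}
        nets, p_exact = exact_network_posterior(
            ["x", "y"], [("x", "y")], pair_scores
        )
        key = {frozenset(): 0, frozenset({("x", "y")}): 1, frozenset({("y", "x")}): 2}
        exact = np.zeros(3)
        for g, pi in zip(nets, p_exact):
            exact[key[frozenset(g.edges)]] += pi

        n = sample_initial(single_edge, rng)
        counts = np.zeros(3)
        for _ in range(20_000):
            n = mh_step(n, 1.0, table, single_edge, rng)
            counts[key[frozenset(n.directed_edges)]] += 1
        freq = counts / counts.sum()
        assert np.abs(freq - exact).max() < 0.03

    def test_beta_zero_targets_uniform(self, single_edge):
        rng = np.random.default_rng(11)
        table = random_table(single_edge.genes, rng, scale=5.0)
        n = sample_initial(single_edge, rng)
        counts = np.zeros(3)
        key = {frozenset(): 0, frozenset({("x", "y")}): 1, frozenset({("y", "x")}): 2}
        for _ in range(15_000):
            n = mh_step(n, 0.0, table, single_edge, rng)
            counts[key[frozenset(n.directed_edges)]] += 1
        freq = counts / counts.sum()
        assert np.abs(freq - 1 / 3).max() < 0.03


class TestAnnealing:
    def test_flat_target_gives_equal_weights(self, triangle):
        table = random_table(triangle.genes, np.random.default_rng(0), scale=0.0)
        ens = run_ensemble(table, triangle, make_schedule(10), K=50, base_seed=3)
        lw = ens.log_weights()
        assert np.ptp(lw) < 1e-12
        assert effective_sample_size(ens) == pytest.approx(50.0)

    def test_two_level_schedule_is_plain_importance_sampling(self, single_edge):
        rng_table = np.random.default_rng(9)
        table = random_table(single_edge.genes, rng_table)
        seed = np.random.SeedSequence(123)
        sample = annealing_run(
            table, single_edge, make_schedule(2), rng=np.random.default_rng(seed)
        )
        # replay the initial uniform draw with an identical stream
        initial = sample_initial(single_edge, np.random.default_rng(np.random.SeedSequence(123)))
        assert sample.log_weight == pytest.approx(
            log_global_score(initial, table), rel=1e-14
        )

    def test_ensemble_is_bit_reproducible(self, triangle):
        table = random_table(triangle.genes, np.random.default_rng(2))
        e1 = run_ensemble(table, triangle, make_schedule(8), K=10, base_seed=77)
        e2 = run_ensemble(table, triangle, make_schedule(8), K=10, base_seed=77)
        assert [s.network.directed_edges for s in e1.samples] == [
            s.network.directed_edges for s in e2.samples
        ]
        assert np.array_equal(e1.log_weights(), e2.log_weights())

    def test_single_run_ensemble(self, single_edge):
        table = random_table(single_edge.genes, np.random.default_rng(1))
        ens = run_ensemble(table, single_edge, make_schedule(5), K=1, base_seed=0)
        assert len(ens) == 1

    def test_weights_are_finite(self, triangle):
        table = random_table(triangle.genes, np.random.default_rng(4), scale=3.0)
        ens = run_ensemble(table, triangle, make_schedule(20), K=30, base_seed=5)
        assert np.all(np.isfinite(ens.log_weights()))

    def test_ais_estimate_matches_enumeration_on_single_edge(self, single_edge):
        """Weighted edge-presence estimate converges to the exact posterior."""
        rng = np.random.default_rng(6)
        table = random_table(single_edge.genes, rng, scale=1.5)
        from oracles import exact_edge_probability

        exact = exact_edge_probability(
            ["x", "y"], [("x", "y")], {("x", "y"): table.scores[0, 1]}, "x", "y"
        )
        ens = run_ensemble(table, single_edge, make_schedule(20), K=2000, base_seed=8)
        lw = ens.log_weights()
        w = np.exp(lw - lw.max())
        est = sum(
            wi for wi, s in zip(w, ens.samples) if ("x", "y") in s.network.directed_edges
        ) / w.sum()
        assert est == pytest.approx(exact, abs=0.03)
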