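import math

import numpy as np
import pytest

from conftest import all_dags, dm_log_marginal, make_discrete, random_discrete
from ictonet.errors import StructuralError
from ictonet.preprocess import SliceSchema
from ictonet.structure import (DAGStructure, SearchConfig, fit_cpts,
                               hill_climb, joint_probability, local_bdeu,
                               neighbor_moves, random_dag, total_bdeu)

SCHEMA = SliceSchema()


def _basal(*names):
    return tuple(f"{n}_basal" for n in names)


class TestLocalBdeu:
    def test_parentless_binary_matches_closed_form(self):
        # one observation of each state, alpha = 1: marginal likelihood
        # (1/2) * (1/4) = 1/8, hence score = -3 ln 2
        data = make_discrete({"A_basal": [0, 1]})
        score = local_bdeu("A_basal", (), data, ess=1.0)
        assert score == pytest.approx(-3 * math.log(2), rel=1e-12)

    def test_empty_dataset_scores_zero(self):
        data = make_discrete({"A_basal": [], "B_basal": []},
                             arity={"A_basal": 2, "B_basal": 3})
        assert local_bdeu("A_basal", (), data, 1.0) == 0.0
        assert local_bdeu("A_basal", ("B_basal",), data, 7.0) == 0.0

    def test_identical_columns_score_equivalent_both_directions(self, rng):
        col = rng.integers(0, 2, size=60)
        a, b = _basal("A", "B")
        data = make_discrete({a: col, b: col.copy()})
        fwd = local_bdeu(a, (), data, 10.0) + local_bdeu(b, (a,), data, 10.0)
        rev = local_bdeu(b, (), data, 10.0) + local_bdeu(a, (b,), data, 10.0)
        assert fwd == pytest.approx(rev, rel=1e-12)

    def test_child_in_parents_rejected(self):
        data = make_discrete({"A_basal": [0, 1]})
        with pytest.raises(StructuralError):
            local_bdeu("A_basal", ("A_basal",), data, 1.0)
        with pytest.raises(ValueError):
            local_bdeu("A_basal", (), data, 0.0)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_sequential_dirichlet_multinomial_oracle(self, trial):
        g = np.random.default_rng(trial)
        names = list(_basal("A", "B", "C"))
        data = random_discrete(g, names, n=int(g.integers(5, 50)))
        order = list(g.permutation(names))
        parents_of = {}
        for i, v in enumerate(order):
            k = int(g.integers(0, i + 1))
            parents_of[v] = tuple(order[i - k:i])
        ess = float(g.choice([1.0, 4.0, 10.0]))
        total = sum(local_bdeu(v, ps, data, ess)
                    for v, ps in parents_of.items())
        oracle = dm_log_marginal(data, parents_of, ess)
        assert total == pytest.approx(oracle, abs=1e-9)


class TestTotalBdeu:
    def test_decomposes_over_nodes(self, rng):
        names = list(_basal("A", "B"))
        data = random_discrete(rng, names, 40)
        g = DAGStructure(names)
        assert total_bdeu(g, data, 10.0) == pytest.approx(
            sum(local_bdeu(v, (), data, 10.0) for v in names))

    def test_adding_arc_changes_only_child_local_score(self, rng):
        names = list(_basal("A", "B", "C"))
        data = random_discrete(rng, names, 50)
        g = DAGStructure(names)
        before = {v: local_bdeu(v, g.parents(v), data, 10.0) for v in names}
        g.add_arc(names[0], names[2])
        after = {v: local_bdeu(v, g.parents(v), data, 10.0) for v in names}
        assert before[names[0]] == after[names[0]]
        assert before[names[1]] == after[names[1]]
        assert total_bdeu(g, data, 10.0) == pytest.approx(sum(after.values()))

    def test_markov_equivalent_chains_tie(self, rng):
        a, b, c = _basal("A", "B", "C")
        data = random_discrete(rng, [a, b, c], 60)
        chain = DAGStructure((a, b, c), [(a, b), (b, c)])
        rev = DAGStructure((a, b, c), [(c, b), (b, a)])
        fork = DAGStructure((a, b, c), [(b, a), (b, c)])
        s1, s2, s3 = (total_bdeu(g, data, 10.0) for g in (chain, rev, fork))
        assert s1 == pytest.approx(s2, abs=1e-9)
        assert s1 == pytest.approx(s3, abs=1e-9)


class TestNeighborMoves:
    def test_empty_two_node_graph_offers_both_additions(self):
        a, b = _basal("A", "B")
        moves = neighbor_moves(DAGStructure((a, b)), SCHEMA)
        assert set(moves) == {("add", a, b), ("add", b, a)}

    def test_backward_in_time_arcs_never_emitted(self):
        nodes = ("TH_basal", "TH_gtcs")
        moves = neighbor_moves(DAGStructure(nodes), SCHEMA)
        assert moves == [("add", "TH_basal", "TH_gtcs")]
        # a forward inter-slice arc cannot be reversed
        g = DAGStructure(nodes, [("TH_basal", "TH_gtcs")])
        kinds = {m[0] for m in neighbor_moves(g, SCHEMA)}
        assert "reverse" not in kinds

    def test_enumeration_matches_brute_force_on_three_nodes(self, rng):
        nodes = _basal("A", "B", "C")
        for arcs in all_dags(nodes)[::3]:
            g = DAGStructure(nodes, arcs)
            got = set(neighbor_moves(g, SCHEMA))
            expected = set()
            for u in nodes:
                for v in nodes:
                    if u == v:
                        continue
                    if (u, v) in arcs:
                        expected.add(("delete", u, v))
                        flipped = (arcs - {(u, v)}) | {(v, u)}
                        if _is_dag(nodes, flipped):
                            expected.add(("reverse", u, v))
                    elif _is_dag(nodes, arcs | {(u, v)}):
                        expected.add(("add", u, v))
            assert got == expected

    def test_max_parents_limits_additions(self):
        a, b, c = _basal("A", "B", "C")
        g = DAGStructure((a, b, c), [(a, c)])
        moves = neighbor_moves(g, SCHEMA, max_parents=1)
        assert ("add", b, c) not in moves


def _is_dag(nodes, arcs):
    import networkx as nx

    g = nx.DiGraph(list(arcs))
    g.add_nodes_from(nodes)
    return nx.is_directed_acyclic_graph(g)


class TestHillClimb:
    def test_deterministic_copy_yields_single_arc(self):
        g = np.random.default_rng(3)
        col = g.integers(0, 2, size=200)
        a, b = _basal("A", "B")
        data = make_discrete({a: col, b: col.copy()})
        res = hill_climb(data, SCHEMA, SearchConfig(max_iterations=500, seed=0))
        assert len(res.dag.arcs) == 1
        assert res.dag.arcs <= {(a, b), (b, a)}

    def test_independent_columns_yield_empty_graph(self):
        g = np.random.default_rng(4)
        a, b = _basal("A", "B")
        data = make_discrete({a: g.integers(0, 2, 500),
                              b: g.integers(0, 2, 500)})
        res = hill_climb(data, SCHEMA, SearchConfig(max_iterations=500, seed=0))
        assert res.dag.arcs == set()

    def test_fixed_seed_reproduces_arcs(self, rng):
        data = random_discrete(rng, list(_basal("A", "B", "C")), 80)
        cfg = SearchConfig(max_iterations=2000, seed=42)
        r1 = hill_climb(data, SCHEMA, cfg)
        r2 = hill_climb(data, SCHEMA, cfg)
        assert r1.dag.arcs == r2.dag.arcs
        assert r1.score == r2.score

    def test_ascent_scores_strictly_increase_and_dag_is_valid(self, rng):
        data = random_discrete(rng, list(_basal("A", "B", "C")), 60)
        res = hill_climb(data, SCHEMA, SearchConfig(max_iterations=3000, seed=7))
        for ascent in res.trace:
            assert all(s2 > s1 for s1, s2 in zip(ascent, ascent[1:]))
        res.dag.validate(SCHEMA)

    def test_tiny_budget_warns_but_returns(self, rng):
        data = random_discrete(rng, list(_basal("A", "B", "C")), 30)
        with pytest.warns(UserWarning):
            res = hill_climb(data, SCHEMA,
                             SearchConfig(max_iterations=2, seed=0))
        res.dag.validate(SCHEMA)


class TestRandomDag:
    def test_respects_schema_and_probability_extremes(self, rng):
        nodes = ("TH_basal", "HP_basal", "TH_gtcs", "HP_gtcs")
        g0 = random_dag(nodes, SCHEMA, rng, arc_prob=0.0)
        assert g0.arcs == set()
        g1 = random_dag(nodes, SCHEMA, rng, arc_prob=1.0)
        g1.validate(SCHEMA)
        assert len(g1.arcs) == 6  # 2 intra-slice pairs + 4 forward arcs


class TestCpts:
    def test_prior_mean_without_data(self):
        data = make_discrete({"A_basal": []}, arity={"A_basal": 2})
        g = DAGStructure(("A_basal",))
        cpts = fit_cpts(g, data, ess=4.0)
        assert cpts["A_basal"].prob(0) == pytest.approx(0.5)

    def test_deterministic_child_approaches_certainty(self):
        a, b = _basal("A", "B")
        col = np.tile([0, 1], 400)
        data = make_discrete({a: col, b: col.copy()})
        cpts = fit_cpts(DAGStructure((a, b), [(a, b)]), data, ess=1.0)
        # closed-form posterior mean: (400 + 1/4) / (400 + 1/2)
        assert cpts[b].prob(1, (1,)) == pytest.approx(400.25 / 400.5)

    def test_rows_sum_to_one(self, rng):
        names = list(_basal("A", "B", "C"))
        data = random_discrete(rng, names, 40)
        g = DAGStructure(names, [(names[0], names[2]), (names[1], names[2])])
        for cpt in fit_cpts(g, data, 10.0).values():
            for row in cpt.table.values():
                assert row.sum() == pytest.approx(1.0, abs=1e-9)


class TestJointProbability:
    def test_empty_graph_fair_binaries(self):
        a, b = _basal("A", "B")
        data = make_discrete({a: [], b: []}, arity={a: 2, b: 2})
        cpts = fit_cpts(DAGStructure((a, b)), data, 1.0)
        for sa in (0, 1):
            for sb in (0, 1):
                assert joint_probability(cpts, {a: sa, b: sb}) == \
                    pytest.approx(0.25)

    def test_sums_to_one_on_random_networks(self, rng):
        import itertools

        names = list(_basal("A", "B", "C"))
        data = random_discrete(rng, names, 30)
        for arcs in (set(), {(names[0], names[1])},
                     {(names[0], names[2]), (names[1], names[2])}):
            cpts = fit_cpts(DAGStructure(names, arcs), data, 10.0)
            total = sum(
                joint_probability(cpts, dict(zip(names, states)))
                for states in itertools.product(
                    *(range(data.arity[v]) for v in names)))
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_incomplete_assignment_rejected(self):
        a, b = _basal("A", "B")
        data = make_discrete({a: [0], b: [0]})
        cpts = fit_cpts(DAGStructure((a, b)), data, 1.0)
        with pytest.raises(ValueError):
            joint_probability(cpts, {a: 0})
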