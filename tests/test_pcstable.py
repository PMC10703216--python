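"""PC-stable skeleton learning, orientation, and CPDAG recovery."""

import numpy as np
import pandas as pd
import pytest

from conftest import linear_gaussian_cov
from protsig import (
    CPDAG,
    OracleTester,
    SyntheticConfig,
    ci_test,
    cpdag_from_dag,
    direct_markers,
    generate_dag_data,
    learn_cpdag,
    learn_skeleton_stable,
)
from protsig.io_preprocess import InputError
from protsig.pcstable_network import apply_meek_rules, orient_v_structures


def sem_data(edges, n=5000, seed=0, noise_sd=1.0):
    cfg = SyntheticConfig(n_per_class=n // 2, m_proteins=0, dag_spec=edges,
                          seed=seed, noise_sd=noise_sd)
    df, truth = generate_dag_data(cfg)
    return df, truth


class TestCiTest:
    def test_independent_normals_usually_pass(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame({"x": rng.normal(size=2000), "y": rng.normal(size=2000)})
            hits += ci_test(df, "x", "y", alpha=0.05).independent
        assert hits >= 33  # ~95% under the null, binomial slack

    def test_perfect_dependence(self):
        x = np.linspace(0, 1, 100)
        df = pd.DataFrame({"x": x, "y": x})
        res = ci_test(df, "x", "y")
        assert not res.independent and res.p_value < 1e-10

    def test_chain_partial_correlation_vanishes(self):
        df, _ = sem_data([("A", "B", 0.8), ("B", "C", 0.8)], n=5000, seed=2)
        assert ci_test(df, "A", "C", ("B",), alpha=0.01).independent
        assert not ci_test(df, "A", "C", (), alpha=0.01).independent

    def test_symmetry_in_arguments(self):
        df, _ = sem_data([("A", "B", 0.5)], n=1000, seed=3)
        r1 = ci_test(df, "A", "B")
        r2 = ci_test(df, "B", "A")
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_g2_discrete_chain(self):
        """On a genuinely discrete chain A -> B -> C the G² test separates
        A from C given B but not marginally.  (With *continuous* variables
        the quantile discretization can leave residual within-bin
        dependence, so the discrete route is validated on discrete data.)"""
        rng = np.random.default_rng(4)
        n = 4000
        a = rng.integers(0, 3, n)
        b = np.where(rng.uniform(size=n) < 0.7, a, rng.integers(0, 3, n))
        c = np.where(rng.uniform(size=n) < 0.7, b, rng.integers(0, 3, n))
        df = pd.DataFrame({"A": a, "B": b, "C": c}, dtype=float)
        assert ci_test(df, "A", "C", ("B",), alpha=0.01, method="g2_disc").independent
        assert not ci_test(df, "A", "C", (), alpha=0.01, method="g2_disc").independent


class TestSkeleton:
    def test_mutually_independent_variables_empty_skeleton(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(2000, 4)), columns=list("ABCD"))
        skel, _ = learn_skeleton_stable(df, alpha=0.01)
        assert skel.number_of_edges() == 0

    def test_chain_skeleton_exact(self):
        df, _ = sem_data([("A", "B", 0.8), ("B", "C", 0.8)], n=5000, seed=1)
        skel, sepsets = learn_skeleton_stable(df, alpha=0.01)
        assert {tuple(sorted(e)) for e in skel.edges} == {("A", "B"), ("B", "C")}
        assert sepsets[frozenset(("A", "C"))] == ("B",)

    def test_order_independence(self):
        df, _ = sem_data(
            [("A", "B", 0.7), ("B", "D", 0.7), ("C", "D", 0.7), ("A", "C", 0.7)],
            n=3000, seed=6,
        )
        skel1, sep1 = learn_skeleton_stable(df, alpha=0.01)
        shuffled = df[["D", "B", "A", "C"]]
        skel2, sep2 = learn_skeleton_stable(shuffled, alpha=0.01)
        assert set(map(frozenset, skel1.edges)) == set(map(frozenset, skel2.edges))
        assert sep1 == sep2


class TestOrientation:
    def test_collider_oriented_from_data(self):
        df, _ = sem_data([("A", "C", 0.8), ("B", "C", 0.8)], n=5000, seed=7)
        cpdag = learn_cpdag(df, alpha=0.01)
        assert cpdag.directed == {("A", "C"), ("B", "C")}
        assert cpdag.undirected == set()

    def test_chain_not_oriented_as_collider(self):
        df, _ = sem_data([("A", "B", 0.8), ("B", "C", 0.8)], n=5000, seed=8)
        cpdag = learn_cpdag(df, alpha=0.01)
        assert cpdag.directed == set()
        assert cpdag.undirected == {frozenset(("A", "B")), frozenset(("B", "C"))}

    def test_no_unshielded_triples_is_noop(self):
        import networkx as nx

        skel = nx.Graph([("A", "B")])
        pdag = orient_v_structures(skel, {})
        assert pdag.directed == set() and pdag.undirected == {frozenset(("A", "B"))}

    def test_meek_r1(self):
        pdag = CPDAG(nodes=["a", "b", "c"], directed={("a", "b")},
                     undirected={frozenset(("b", "c"))})
        out = apply_meek_rules(pdag)
        assert ("b", "c") in out.directed

    def test_meek_r2(self):
        pdag = CPDAG(nodes=["a", "b", "c"],
                     directed={("a", "b"), ("b", "c")},
                     undirected={frozenset(("a", "c"))})
        out = apply_meek_rules(pdag)
        assert ("a", "c") in out.directed

    def test_complete_cpdag_is_fixed_point(self):
        cpdag = cpdag_from_dag([("A", "C"), ("B", "C")])
        again = apply_meek_rules(cpdag)
        assert again == cpdag


BENCHMARKS = {
    "chain": [("A", "B", 0.8), ("B", "C", 0.8)],
    "fork": [("B", "A", 0.8), ("B", "C", 0.8)],
    "collider": [("A", "C", 0.8), ("B", "C", 0.8)],
    "diamond": [("A", "B", 0.7), ("A", "C", 0.7), ("B", "D", 0.7), ("C", "D", 0.7)],
}


class TestRecovery:
    @pytest.mark.parametrize("name", list(BENCHMARKS))
    def test_oracle_recovery_is_exact(self, name):
        """With analytic partial correlations as the CI oracle, PC-stable
        returns exactly the true CPDAG."""
        edges = BENCHMARKS[name]
        oracle = OracleTester(linear_gaussian_cov(edges))
        learned = learn_cpdag(oracle)
        assert learned == cpdag_from_dag([(a, b) for a, b, _ in edges])

    @pytest.mark.parametrize("name", list(BENCHMARKS))
    def test_data_recovery_at_n5000(self, name):
        df, truth = sem_data(BENCHMARKS[name], n=5000, seed=11)
        assert learn_cpdag(df, alpha=0.01) == truth

    def test_directed_subgraph_always_acyclic(self):
        df, _ = sem_data(BENCHMARKS["diamond"], n=3000, seed=12)
        cpdag = learn_cpdag(df, alpha=0.01)
        assert cpdag.directed_is_acyclic()

    def test_edge_count_monotone_in_alpha(self):
        df, _ = sem_data(
            [("A", "B", 0.3), ("B", "C", 0.3), ("C", "D", 0.3)], n=800, seed=13
        )
        strict = learn_cpdag(df, alpha=0.001).n_edges()
        loose = learn_cpdag(df, alpha=0.2).n_edges()
        assert strict <= loose


class TestDirectMarkers:
    def test_adjacency_readoff(self):
        cpdag = CPDAG(
            nodes=["P1", "P2", "P3", "P4", "class"],
            directed={("P1", "class")},
            undirected={frozenset(("class", "P2")), frozenset(("P3", "P4"))},
        )
        out = direct_markers(cpdag, "class")
        assert out == [("P1", "to_class"), ("P2", "undirected")]

    def test_empty_graph(self):
        cpdag = CPDAG(nodes=["P1", "class"])
        assert direct_markers(cpdag, "class") == []

    def test_absent_class_node_rejected(self):
        with pytest.raises(InputError):
            direct_markers(CPDAG(nodes=["P1"]), "class")

    def test_recovers_class_parents_in_sem(self):
        """Class wired to exactly two proteins among decoys: the class
        neighbors found by PC-stable are those two in most seeded runs."""
        hits = 0
        for seed in range(10):
            edges = [("A", "class", 2.0), ("B", "class", -2.0),
                     ("C", "D", 0.8)]
            cfg = SyntheticConfig(n_per_class=2500, m_proteins=8,
                                  dag_spec=edges, seed=100 + seed)
            df, _ = generate_dag_data(cfg)
            cpdag = learn_cpdag(df, alpha=0.01)
            found = {p for p, _ in direct_markers(cpdag, "class")}
            hits += found == {"A", "B"}
        assert hits >= 8


class TestCpdagFromDag:
    def test_chain_fully_undirected(self):
        cp = cpdag_from_dag([("A", "B"), ("B", "C")])
        assert cp.directed == set()
        assert cp.undirected == {frozenset(("A", "B")), frozenset(("B", "C"))}

    def test_collider_compelled(self):
        cp = cpdag_from_dag([("A", "C"), ("B", "C")])
        assert cp.directed == {("A", "C"), ("B", "C")}

    def test_cycle_rejected(self):
        with pytest.raises(InputError):
            cpdag_from_dag([("A", "B"), ("B", "A")])
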