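import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from siidanet.io import Roster
from siidanet.networks import (
    DirectedBinaryNetwork,
    UndefinedStatisticError,
    aggregate_layers,
    edge_reciprocity,
    in_degree_vector,
    interviewed_subgraph_reciprocity,
    jaccard,
    random_network_null,
    siida_assortment,
)


def net(edges, nodes=None, name=""):
    nodes = nodes or {v for e in edges for v in e}
    return DirectedBinaryNetwork(nodes=frozenset(nodes), edges=frozenset(edges), layer_name=name)


def test_network_rejects_self_loops():
    with pytest.raises(ValueError, match="self-loop"):
        net([("a", "a")])


def test_aggregate_union_semantics():
    a = net([("a", "b")], nodes={"a", "b", "c"})
    b = net([("a", "b"), ("b", "c")], nodes={"a", "b", "c"})
    c = net([], nodes={"a", "b", "c"})
    agg = aggregate_layers(a, b, c)
    assert agg.edges == {("a", "b"), ("b", "c")}
    # idempotent on identical layers
    same = aggregate_layers(b, b, b)
    assert same.edges == b.edges
    # disjoint edge sets add up
    d1 = net([("a", "b"), ("b", "a")], nodes=set("abcdef"))
    d2 = net([("c", "d"), ("d", "c"), ("a", "c")], nodes=set("abcdef"))
    d3 = net([("e", "f"), ("f", "e"), ("a", "e"), ("b", "e")], nodes=set("abcdef"))
    assert aggregate_layers(d1, d2, d3).n_edges == 2 + 3 + 4


def test_aggregate_contains_each_layer(community):
    for layer in community.layers:
        assert layer.edges <= community.cooperation.edges


@pytest.mark.parametrize(
    "edges,expected",
    [
        ([("1", "2"), ("2", "1"), ("3", "4"), ("4", "3")], 1.0),
        ([("1", "2"), ("2", "1"), ("1", "3")], 2 / 3),
        ([("1", "2"), ("2", "3"), ("3", "1")], 0.0),
    ],
)
def test_edge_reciprocity_enumeration(edges, expected):
    assert edge_reciprocity(net(edges)) == pytest.approx(expected)


def test_reciprocity_undefined_on_empty():
    with pytest.raises(UndefinedStatisticError):
        edge_reciprocity(net([], nodes={"a", "b"}))


def test_siida_assortment_enumeration(small_roster):
    # 4 edges, 3 within-siida (a,b,c in s1; d in s2)
    n = net([("a", "b"), ("b", "c"), ("c", "a"), ("a", "d")], nodes=set("abcdef"))
    assert siida_assortment(n, small_roster) == pytest.approx(0.75)
    within = net([("a", "b"), ("b", "a")], nodes=set("abcdef"))
    assert siida_assortment(within, small_roster) == 1.0
    across = net([("a", "d"), ("b", "e"), ("c", "f")], nodes=set("abcdef"))
    assert siida_assortment(across, small_roster) == 0.0


def test_assortment_requires_labels(small_roster):
    n = net([("zz", "a")], nodes={"zz", "a"})
    with pytest.raises(KeyError, match="zz"):
        siida_assortment(n, small_roster)


def test_jaccard_cases():
    a = net([("1", "2"), ("2", "3")])
    b = net([("1", "2"), ("3", "1")])
    assert jaccard(a, b) == pytest.approx(1 / 3)
    assert jaccard(a, a) == 1.0
    disjoint = net([("4", "5")], nodes={"4", "5"})
    assert jaccard(a, disjoint) == 0.0
    assert jaccard(a, b) == jaccard(b, a)
    empty = net([], nodes={"1"})
    with pytest.raises(UndefinedStatisticError):
        jaccard(empty, empty)


def test_in_degree_counts_distinct_namers(small_roster):
    empty = net([], nodes=set("abcdef"))
    assert (in_degree_vector(empty, small_roster) == 0).all()
    star = net([(v, "a") for v in "bcdef"], nodes=set("abcdef"))
    deg = in_degree_vector(star, small_roster)
    assert deg["a"] == 5
    assert deg.drop("a").eq(0).all()


def test_in_degree_counts_dyad_once_across_layers(small_roster):
    layers = [net([("b", "a")], nodes=set("abcdef"), name=k) for k in "xyz"]
    agg = aggregate_layers(*layers)
    assert in_degree_vector(agg, small_roster)["a"] == 1


def test_interviewed_subgraph_reciprocity(small_roster):
    # a,b,c,d interviewed; e,f not. Edges among interviewed: 3, of which 2 mutual.
    n = net(
        [("a", "b"), ("b", "a"), ("c", "d"), ("a", "e"), ("e", "f")],
        nodes=set("abcdef"),
    )
    assert interviewed_subgraph_reciprocity(n, small_roster) == pytest.approx(2 / 3)
    all_int = Roster(
        small_roster.table.assign(interviewed=1)
    )
    assert interviewed_subgraph_reciprocity(n, all_int) == edge_reciprocity(n)


def test_interviewed_subgraph_empty_is_undefined(small_roster):
    n = net([("a", "e"), ("b", "f")], nodes=set("abcdef"))
    with pytest.raises(UndefinedStatisticError):
        interviewed_subgraph_reciprocity(n, small_roster)


# ---------------------------------------------------------------------------
# randomization nulls


def test_null_reproducible_and_in_range():
    nodes = [f"n{i}" for i in range(12)]
    rng = np.random.default_rng(0)
    edges = set()
    while len(edges) < 25:
        i, j = rng.choice(12, 2, replace=False)
        edges.add((nodes[i], nodes[j]))
    n = net(edges, nodes=nodes)
    a = random_network_null(n, edge_reciprocity, n_rep=1, seed=5)
    b = random_network_null(n, edge_reciprocity, n_rep=1, seed=5)
    assert a.null_values[0] == b.null_values[0]
    full = random_network_null(n, edge_reciprocity, n_rep=200, seed=6)
    assert ((full.null_values >= 0) & (full.null_values <= 1)).all()
    assert 0 < full.quantile <= 1


def test_null_mean_reciprocity_matches_closed_form():
    """E[reciprocity] of a fixed-edge-count directed random graph is
    (m-1)/(n(n-1)-1): a given edge's reverse slot is one of the remaining
    n(n-1)-1 slots, m-1 of which are occupied."""
    n_nodes, m = 20, 40
    nodes = [f"n{i}" for i in range(n_nodes)]
    base = net([(nodes[i], nodes[(i + 1) % n_nodes]) for i in range(n_nodes)]
               + [(nodes[i], nodes[(i + 2) % n_nodes]) for i in range(n_nodes)],
               nodes=nodes)
    assert base.n_edges == m
    null = random_network_null(base, edge_reciprocity, n_rep=1000, seed=9)
    expected = (m - 1) / (n_nodes * (n_nodes - 1) - 1)
    se = null.null_values.std(ddof=1) / np.sqrt(null.n_rep)
    assert abs(null.null_values.mean() - expected) < 3 * se


def test_complete_mutual_network_is_extreme_in_null():
    nodes = list("abcde")
    n = net([(i, j) for i in nodes for j in nodes if i != j], nodes=nodes)
    # fewer edges than the complete graph so the null can vary
    sub = net([("a", "b"), ("b", "a"), ("c", "d"), ("d", "c")], nodes=nodes)
    null = random_network_null(sub, edge_reciprocity, n_rep=300, seed=2)
    assert null.observed_value == 1.0
    assert (null.null_values <= null.observed_value).all()


def test_null_assortment_expectation_matches_pair_fraction(small_roster):
    """Null assortment has expectation = fraction of same-siida ordered pairs."""
    n = net([("a", "b"), ("a", "c"), ("d", "e"), ("a", "d"), ("b", "e"), ("c", "e")],
            nodes=set("abcdef"))
    null = random_network_null(
        n, siida_assortment, roster=small_roster, n_rep=2000, seed=4
    )
    siida = small_roster.siida_of()
    ids = small_roster.ids
    pairs = [(i, j) for i in ids for j in ids if i != j]
    frac_same = np.mean([siida[i] == siida[j] for i, j in pairs])
    se = null.null_values.std(ddof=1) / np.sqrt(null.n_rep)
    assert abs(null.null_values.mean() - frac_same) < 3 * se


def test_null_rejects_overfull_graph():
    n = net([("a", "b")], nodes={"a", "b"})
    dense = DirectedBinaryNetwork(
        nodes=frozenset("ab"), edges=frozenset([("a", "b"), ("b", "a")])
    )
    null = random_network_null(dense, edge_reciprocity, n_rep=2, seed=1)
    assert null.observed_value == 1.0  # saturated graph still valid
    with pytest.raises(UndefinedStatisticError):
        random_network_null(net([], nodes={"a", "b"}), edge_reciprocity, n_rep=2, seed=1)


@given(st.integers(0, 2**31 - 1))
def test_null_quantile_bounds(seed):
    n = net([("a", "b"), ("b", "c"), ("c", "a")], nodes=set("abcd"))
    null = random_network_null(n, edge_reciprocity, n_rep=19, seed=seed)
    assert 0 < null.quantile <= 1
    assert 0 < null.p_two_sided <= 1
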