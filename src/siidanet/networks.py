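"""Directed binary networks and their descriptive statistics.

The community's cooperation data form directed binary networks: one layer
per elicitation prompt (advice, help, sharing items), aggregated by union
into a single cooperation network, plus a gift network from the economic
game. Statistics of interest are edge reciprocity (share of directed links
whose reverse also exists), assortment on herding-group (siida) membership
(share of links joining members of the same siida), and Jaccard similarity
between layers. Observed values are compared against nulls drawn from
directed Erdős–Rényi graphs with the same numbers of nodes and edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .io import GiftLedger, Roster

__all__ = [
    "DirectedBinaryNetwork",
    "NullDistribution",
    "UndefinedStatisticError",
    "network_from_edge_table",
    "gift_network",
    "aggregate_layers",
    "edge_reciprocity",
    "dyad_reciprocity",
    "siida_assortment",
    "jaccard",
    "random_network_null",
    "in_degree_vector",
    "interviewed_subgraph_reciprocity",
]


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is requested on a network where it has no value
    (e.g. reciprocity of an empty edge set)."""


@dataclass(frozen=True)
class DirectedBinaryNetwork:
    """A labelled directed graph without self-loops or edge weights."""

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    layer_name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))
        object.__setattr__(self, "edges", frozenset(self.edges))
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on node {i!r} in layer {self.layer_name!r}")
            if i not in self.nodes or j not in self.nodes:
                raise ValueError(
                    f"edge ({i!r}, {j!r}) uses a node outside the node set"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, i: str, j: str) -> bool:
        return (i, j) in self.edges

    def subgraph(self, keep: Iterable[str], layer_name: str | None = None) -> "DirectedBinaryNetwork":
        keep = frozenset(keep)
        return DirectedBinaryNetwork(
            nodes=self.nodes & keep,
            edges=frozenset((i, j) for i, j in self.edges if i in keep and j in keep),
            layer_name=self.layer_name if layer_name is None else layer_name,
        )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    def adjacency(self, order: list[str]) -> np.ndarray:
        idx = {v: k for k, v in enumerate(order)}
        a = np.zeros((len(order), len(order)))
        for i, j in self.edges:
            a[idx[i], idx[j]] = 1.0
        return a


def network_from_edge_table(
    edges: pd.DataFrame, nodes: Iterable[str], layer: str | None = None
) -> DirectedBinaryNetwork:
    """Build one layer from a long edge table (columns ego, alter, layer)."""
    df = edges
    name = layer or ""
    if layer is not None:
        df = df[df["layer"] == layer]
    return DirectedBinaryNetwork(
        nodes=frozenset(str(v) for v in nodes),
        edges=frozenset((str(r.ego), str(r.alter)) for r in df.itertuples(index=False)),
        layer_name=name,
    )


def gift_network(ledger: GiftLedger, nodes: Iterable[str]) -> DirectedBinaryNetwork:
    """Binary gift network: edge giver -> recipient iff any litres were given."""
    return DirectedBinaryNetwork(
        nodes=frozenset(str(v) for v in nodes),
        edges=frozenset((rec.giver, rec.recipient) for rec in ledger.records),
        layer_name="gift",
    )


def aggregate_layers(*layers: DirectedBinaryNetwork, layer_name: str = "cooperation") -> DirectedBinaryNetwork:
    """Union of layers: an edge is present iff present in at least one layer."""
    if not layers:
        raise ValueError("need at least one layer to aggregate")
    nodes: frozenset[str] = frozenset()
    edges: frozenset[tuple[str, str]] = frozenset()
    for layer in layers:
        nodes |= layer.nodes
        edges |= layer.edges
    return DirectedBinaryNetwork(nodes=nodes, edges=edges, layer_name=layer_name)


def edge_reciprocity(net: DirectedBinaryNetwork) -> float:
    """Fraction of directed edges (i, j) whose reverse (j, i) also exists."""
    if net.n_edges == 0:
        raise UndefinedStatisticError(
            f"edge reciprocity is undefined on the empty network {net.layer_name!r}"
        )
    mutual = sum(1 for i, j in net.edges if (j, i) in net.edges)
    return mutual / net.n_edges


def dyad_reciprocity(net: DirectedBinaryNetwork) -> float:
    """Fraction of connected unordered dyads that are mutual.

    Alternative, dyad-based definition: among unordered pairs joined by at
    least one directed edge, the share joined in both directions.
    """
    if net.n_edges == 0:
        raise UndefinedStatisticError(
            f"dyad reciprocity is undefined on the empty network {net.layer_name!r}"
        )
    dyads = {frozenset(e) for e in net.edges}
    mutual = sum(1 for d in dyads if len(d) == 2 and all(
        (a, b) in net.edges for a in d for b in d if a != b
    ))
    return mutual / len(dyads)


def siida_assortment(net: DirectedBinaryNetwork, roster: Roster) -> float:
    """Fraction of edges whose two endpoints share a siida label."""
    if net.n_edges == 0:
        raise UndefinedStatisticError(
            f"assortment is undefined on the empty network {net.layer_name!r}"
        )
    siida = roster.siida_of()
    unlabeled = {v for v in net.nodes if v not in siida}
    if unlabeled:
        raise KeyError(f"nodes without a siida label: {sorted(unlabeled)}")
    within = sum(1 for i, j in net.edges if siida[i] == siida[j])
    return within / net.n_edges


def jaccard(net_a: DirectedBinaryNetwork, net_b: DirectedBinaryNetwork) -> float:
    """Jaccard index of the two edge sets: |A ∩ B| / |A ∪ B|."""
    union = net_a.edges | net_b.edges
    if not union:
        raise UndefinedStatisticError("Jaccard index is undefined when both edge sets are empty")
    return len(net_a.edges & net_b.edges) / len(union)


def in_degree_vector(net: DirectedBinaryNetwork, roster: Roster) -> pd.Series:
    """Distinct-nominator in-degree per licence owner (0 for the never-named)."""
    counts = {v: 0 for v in roster.licensed_ids}
    for _, j in net.edges:
        if j in counts:
            counts[j] += 1
    return pd.Series(counts, name="in_degree").sort_index()


def interviewed_subgraph_reciprocity(net: DirectedBinaryNetwork, roster: Roster) -> float:
    """Edge reciprocity on the subgraph induced by interviewed individuals.

    Restricting both egos and alters to interviewed people removes the
    artefactual non-reciprocity of alters who were never asked.
    """
    sub = net.subgraph(roster.interviewed_ids)
    if sub.n_edges == 0:
        raise UndefinedStatisticError(
            "no edges among interviewed individuals; reciprocity undefined"
        )
    return edge_reciprocity(sub)


@dataclass
class NullDistribution:
    """An observed statistic against its fixed-density random-graph null."""

    statistic_name: str
    observed_value: float
    null_values: np.ndarray
    n_rep: int
    seed: int
    quantile: float = field(init=False)
    p_two_sided: float = field(init=False)

    def __post_init__(self) -> None:
        self.null_values = np.asarray(self.null_values, dtype=float)
        if self.n_rep < 1 or len(self.null_values) != self.n_rep:
            raise ValueError("null_values must have length n_rep >= 1")
        le = np.count_nonzero(self.null_values <= self.observed_value)
        ge = np.count_nonzero(self.null_values >= self.observed_value)
        # add-one convention keeps empirical p in (0, 1]
        self.quantile = (le + 1) / (self.n_rep + 1)
        self.p_two_sided = min(1.0, 2 * min(le + 1, ge + 1) / (self.n_rep + 1))


def _random_fixed_edge_network(
    nodes: list[str], m: int, rng: np.random.Generator
) -> DirectedBinaryNetwork:
    """Uniform draw of m distinct ordered non-self pairs on the given nodes."""
    n = len(nodes)
    slots = rng.choice(n * (n - 1), size=m, replace=False)
    edges = []
    for s in slots:
        i, rem = divmod(int(s), n - 1)
        j = rem if rem < i else rem + 1
        edges.append((nodes[i], nodes[j]))
    return DirectedBinaryNetwork(nodes=frozenset(nodes), edges=frozenset(edges))


def random_network_null(
    net: DirectedBinaryNetwork,
    statistic: Callable[..., float],
    *,
    roster: Roster | None = None,
    n_rep: int = 1000,
    seed: int,
) -> NullDistribution:
    """Compare an observed statistic against random networks with the same
    numbers of nodes and edges.

    Each replicate draws ``net.n_edges`` distinct directed non-self edges
    uniformly on the observed node set (directed Erdős–Rényi with a fixed
    edge count); siida labels stay attached to the nodes. ``statistic`` is
    ``edge_reciprocity`` (called as f(net)) or ``siida_assortment`` (called
    as f(net, roster)).
    """
    if net.n_edges == 0:
        raise UndefinedStatisticError("null distribution undefined on an empty network")
    n = net.n_nodes
    if net.n_edges > n * (n - 1):
        raise ValueError("more edges than ordered non-self pairs")
    args = () if roster is None else (roster,)
    observed = statistic(net, *args)
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes)
    null_values = np.empty(n_rep)
    for k in range(n_rep):
        rep = _random_fixed_edge_network(nodes, net.n_edges, rng)
        null_values[k] = statistic(rep, *args)
    return NullDistribution(
        statistic_name=getattr(statistic, "__name__", "statistic"),
        observed_value=observed,
        null_values=null_values,
        n_rep=n_rep,
        seed=seed,
    )
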