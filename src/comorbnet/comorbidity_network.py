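"""Disease comorbidity network (DCN) built by clique expansion of rules.

Every rule {X -> Y} contributes all C(k, 2) unordered pairs among its
k = |X u Y| distinct diseases as edges; duplicates across rules merge into
a single undirected, unweighted edge.  A rule {OUD, cancer -> fever, pain}
therefore contributes the 6 edges {OUD,fever}, {OUD,pain}, {cancer,fever},
{cancer,pain}, {OUD,cancer} and {fever,pain}.  The number of rules backing
an edge is kept as diagnostic metadata only; propagation treats the graph
as unweighted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx

from .rule_mining import AssociationRule

logger = logging.getLogger(__name__)

__all__ = [
    "rules_to_network",
    "network_stats",
    "seed_component",
    "NetworkStats",
    "write_edgelist",
    "read_edgelist",
]


def rules_to_network(rules: Iterable[AssociationRule]) -> nx.Graph:
    """Clique-expand mined rules into the undirected comorbidity network."""
    g = nx.Graph()
    n_rules = 0
    n_skipped = 0
    for rule in rules:
        n_rules += 1
        items = sorted(rule.items)
        if len(items) < 2:
            n_skipped += 1
            logger.warning("skipping rule with fewer than two distinct diseases: %s", items)
            continue
        for u, v in combinations(items, 2):
            if g.has_edge(u, v):
                g[u][v]["rule_count"] += 1
            else:
                g.add_edge(u, v, rule_count=1)
    if n_rules == 0:
        raise ValueError("no rules supplied")
    return g


@dataclass(frozen=True)
class NetworkStats:
    node_count: int
    edge_count: int
    degree_distribution: tuple  # sorted descending
    component_sizes: tuple  # sorted descending


def network_stats(g: nx.Graph) -> NetworkStats:
    degrees = tuple(sorted((d for _, d in g.degree()), reverse=True))
    comps = tuple(sorted((len(c) for c in nx.connected_components(g)), reverse=True))
    return NetworkStats(
        node_count=g.number_of_nodes(),
        edge_count=g.number_of_edges(),
        degree_distribution=degrees,
        component_sizes=comps,
    )


def seed_component(g: nx.Graph, seed: str) -> nx.Graph:
    """Induced subgraph on the connected component containing the seed.

    Restricting propagation to the seed's component keeps the walk's
    normalization exact: nodes unreachable from the seed would carry zero
    stationary probability anyway.
    """
    if seed not in g:
        raise KeyError(f"seed disease {seed!r} is not a node of the network")
    members = nx.node_connected_component(g, seed)
    return g.subgraph(members).copy()


def write_edgelist(g: nx.Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_u\tnode_v\trule_count\n")
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data.get('rule_count', 1)}\n")


def read_edgelist(path) -> nx.Graph:
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("node_u"):
            raise ValueError(f"unexpected edge-list header: {header!r}")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            u, v, rc = line.split("\t")
            g.add_edge(u, v, rule_count=int(rc))
    return g
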