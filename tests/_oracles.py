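"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by the most direct method available
(exhaustive enumeration, dense linear algebra, direct tallies) so that the
package's optimized implementations can be checked against it.  Nothing
here calls the code paths under test.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def apriori_enumerate(transactions, min_count, max_size):
    """Frequent itemsets by exhaustive per-transaction subset counting."""
    counts = {}
    for items in transactions:
        items = sorted(items)
        for size in range(1, min(max_size, len(items)) + 1):
            for combo in combinations(items, size):
                key = frozenset(combo)
                counts[key] = counts.get(key, 0) + 1
    return {k: c for k, c in counts.items() if c >= min_count}


def clique_expand_pairs(rule_itemsets):
    """All unordered disease pairs across rules, duplicates merged."""
    edges = set()
    for items in rule_itemsets:
        for pair in combinations(sorted(items), 2):
            edges.add(frozenset(pair))
    return edges


def rwr_linear_solve(graph, seed, c):
    """Stationary restart-walk vector via P* = c (I - (1-c) W)^-1 P0.

    W is the column-stochastic propagation operator (adjacency with each
    column divided by its degree), so P* lies on the probability simplex.
    """
    import networkx as nx

    nodes = sorted(graph.nodes)
    idx = {node: i for i, node in enumerate(nodes)}
    adj = nx.to_numpy_array(graph, nodelist=nodes)
    w = adj / adj.sum(axis=0, keepdims=True)
    p0 = np.zeros(len(nodes))
    p0[idx[seed]] = 1.0
    p = c * np.linalg.solve(np.eye(len(nodes)) - (1.0 - c) * w, p0)
    return dict(zip(nodes, p))


def bfs_component(adj_lists, start):
    """Connected-component membership by explicit breadth-first search."""
    seen = {start}
    frontier = [start]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj_lists.get(u, ()):
                if v not in seen:
                    seen.add(v)
                    nxt.append(v)
        frontier = nxt
    return seen


def mantel_haenszel_statsmodels(strata):
    """CMH estimate/CI/p via statsmodels (independent implementation)."""
    from statsmodels.stats.contingency_tables import StratifiedTable

    tables = [
        np.array([[t.a, t.b], [t.c_, t.d]], dtype=float) for _, t in strata
    ]
    st = StratifiedTable(tables)
    low, high = st.oddsratio_pooled_confint(alpha=0.05)
    res = st.test_null_odds(correction=False)
    return st.oddsratio_pooled, low, high, res.pvalue
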