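"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library code paths (and networkx):
all-pairs distances by Floyd-Warshall, clustering by explicit triangle
enumeration, betweenness by exhaustive shortest-path enumeration, parsimony
change by exhaustive assignment search.  They are only feasible on small
graphs/trees, which is what the tests use them on.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from annaceti.network_model import AnatomicalNetwork, Bone


# ---------------------------------------------------------------------------
# network construction helpers


def net_from_edges(edges, taxon="test"):
    """Anatomical network over the edge list; every bone midline."""
    names = sorted({n for e in edges for n in e})
    return AnatomicalNetwork(taxon, [Bone(n) for n in names], list(edges))


@pytest.fixture
def triangle():
    return net_from_edges([("a", "b"), ("b", "c"), ("a", "c")], "triangle")


@pytest.fixture
def star5():
    """Hub with four leaves."""
    return net_from_edges([("hub", f"leaf{i}") for i in range(4)], "star5")


@pytest.fixture
def path3():
    return net_from_edges([("a", "b"), ("b", "c")], "path3")


def random_connected_edges(n, p, rng):
    """Edge list of a connected Erdos-Renyi draw (rejection sampling)."""
    names = [f"n{i}" for i in range(n)]
    while True:
        edges = [(names[i], names[j]) for i in range(n) for j in range(i + 1, n)
                 if rng.random() < p]
        if len(edges) >= n - 1 and _oracle_connected(names, edges):
            return edges


def all_connected_graphs(n):
    """Every labeled connected graph on n nodes (feasible for n <= 5)."""
    names = [f"n{i}" for i in range(n)]
    possible = list(itertools.combinations(names, 2))
    for bits in range(1, 2 ** len(possible)):
        edges = [e for i, e in enumerate(possible) if bits >> i & 1]
        if _oracle_connected(names, edges):
            yield edges


# ---------------------------------------------------------------------------
# oracles


def _adjacency(names, edges):
    idx = {n: i for i, n in enumerate(names)}
    adj = [[False] * len(names) for _ in names]
    for a, b in edges:
        adj[idx[a]][idx[b]] = adj[idx[b]][idx[a]] = True
    return idx, adj


def oracle_distances(names, edges):
    """All-pairs shortest-path matrix by Floyd-Warshall."""
    idx, adj = _adjacency(names, edges)
    n = len(names)
    dist = [[0 if i == j else (1 if adj[i][j] else math.inf) for j in range(n)]
            for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    return idx, dist

def _oracle_connected(names, edges):
    touched = {n for e in edges for n in e}
    if set(names) - touched:
        return False
    _, dist = oracle_distances(names, edges)
    return all(d != math.inf for row in dist for d in row)


def oracle_average_path_length(names, edges):
    _, dist = oracle_distances(names, edges)
    n = len(names)
    pairs = [dist[i][j] for i in range(n) for j in range(i + 1, n)]
    return sum(pairs) / len(pairs)


def oracle_local_clustering(names, edges):
    """Per-node clustering by counting connected neighbor pairs."""
    idx, adj = _adjacency(names, edges)
    out = {}
    for v in names:
        nbrs = [u for u in names if adj[idx[v]][idx[u]]]
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        closed = sum(1 for a, b in itertools.combinations(nbrs, 2)
                     if adj[idx[a]][idx[b]])
        out[v] = closed / (k * (k - 1) / 2)
    return out


def _all_shortest_paths(names, edges, s, t):
    idx, dist = oracle_distances(names, edges)
    _, adj = _adjacency(names, edges)
    target_len = dist[idx[s]][idx[t]]
    paths = []

    def extend(path):
        last = path[-1]
        if last == t:
            if len(path) - 1 == target_len:
                paths.append(path)
            return
        if len(path) - 1 >= target_len:
            return
        for u in names:
            if adj[idx[last]][idx[u]] and u not in path:
                if dist[idx[u]][idx[t]] == target_len - len(path):
                    extend(path + [u])

    extend([s])
    return paths


def oracle_betweenness(names, edges):
    """Unnormalized pair-count betweenness by explicit path enumeration."""
    out = {n: 0.0 for n in names}
    for s, t in itertools.combinations(names, 2):
        paths = _all_shortest_paths(names, edges, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                out[v] += 1.0 / len(paths)
    return out


def oracle_harmonic_closeness(names, edges):
    idx, dist = oracle_distances(names, edges)
    n = len(names)
    return {v: sum(1.0 / dist[idx[v]][idx[u]] for u in names
                   if u != v and dist[idx[v]][idx[u]] != math.inf) / (n - 1)
            for v in names}


def oracle_parcellation(sizes):
    total = sum(sizes)
    return 1.0 - sum((s / total) ** 2 for s in sizes)


def oracle_parsimony_change(tree, tips):
    """Minimal total absolute change by exhaustive search over tip values.

    For linear parsimony an optimal reconstruction exists with every internal
    state equal to some tip value, so the search over that finite grid is
    exact.
    """
    values = sorted(set(tips.values()))
    internals = tree.internal_nodes
    best = math.inf
    for assign in itertools.product(values, repeat=len(internals)):
        amap = {n.node_id: v for n, v in zip(internals, assign)}

        def node_value(node):
            return tips[node.label] if node.is_leaf else amap[node.node_id]

        cost = sum(abs(node_value(parent) - node_value(child))
                   for parent in tree.nodes for child in parent.children)
        best = min(best, cost)
    return best
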