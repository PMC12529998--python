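"""Independent brute-force oracles used to validate the graph metrics.

Everything here is deliberately naive — plain BFS, explicit geodesic
enumeration, iterative peeling, exhaustive cut enumeration — and shares no
code with the package implementation it checks.
"""

from collections import deque
from itertools import combinations

import numpy as np


def bfs_distances(adj: dict, source):
    """Plain BFS shortest-path lengths from ``source``; adj: node -> set."""
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _all_geodesics(adj: dict, s, t):
    """Enumerate all shortest s-t paths by backtracking along BFS levels."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def back(node, tail):
        if node == s:
            paths.append([s] + tail)
            return
        for prev in adj[node]:
            if prev in dist and dist[prev] == dist[node] - 1:
                back(prev, [node] + tail)

    back(t, [])
    return paths


def betweenness_enumeration(adj: dict):
    """Unnormalized betweenness: each unordered pair counted once, ties split."""
    nodes = sorted(adj)
    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = _all_geodesics(adj, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


def coreness_peeling(adj: dict):
    """k-core index by repeated removal of minimum-degree vertices."""
    remaining = {v: set(nbrs) for v, nbrs in adj.items()}
    core = {}
    k = 0
    while remaining:
        k = max(k, min(len(n) for n in remaining.values()))
        while remaining and min(len(n) for n in remaining.values()) <= k:
            v = min(remaining, key=lambda x: len(remaining[x]))
            core[v] = k
            for u in remaining[v]:
                remaining[u].discard(v)
            del remaining[v]
    return core


def min_edge_cut_bruteforce(adj: dict, a, b):
    """Minimum a/b edge cut by enumerating every vertex bipartition.

    Vectorized over the 2^(n-2) subsets containing ``a`` but not ``b``;
    feasible for graphs up to 12 nodes.
    """
    nodes = sorted(adj)
    others = [v for v in nodes if v not in (a, b)]
    edges = [(u, v) for u, v in combinations(nodes, 2) if v in adj[u]]
    if not edges:
        return 0
    n_sub = 1 << len(others)
    idx = np.arange(n_sub, dtype=np.uint32)

    def membership(x):
        if x == a:
            return np.ones(n_sub, dtype=bool)
        if x == b:
            return np.zeros(n_sub, dtype=bool)
        return (idx >> others.index(x)) & 1 == 1

    crossings = np.zeros(n_sub, dtype=np.int64)
    for u, v in edges:
        crossings += membership(u) ^ membership(v)
    return int(crossings.min())


def mann_whitney_auc(scores, labels):
    """Pairwise-comparison AUC estimate, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == np.max(labels)]
    neg = scores[labels != np.max(labels)]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def adjacency(net) -> dict:
    """Adjacency-set view of a Network, including isolated nodes."""
    return {v: net.neighbors(v) for v in net.nodes}
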