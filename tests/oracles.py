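"""Independent brute-force oracles shared by unit and acceptance tests.

Each function recomputes a quantity by direct enumeration or closed
form, independently of the library code paths it is used to check.
"""

import itertools
import math
from collections import deque

from lncnet.io import GeneSetCollection


def brute_force_betweenness(pairs):
    """Unnormalized betweenness by exhaustive shortest-path enumeration
    (BFS predecessor links, then full back-tracking)."""
    adj: dict[str, set[str]] = {}
    for a, b in pairs:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    nodes = sorted(adj)
    score = dict.fromkeys(nodes, 0.0)

    def all_shortest_paths(s, t):
        dist = {s: 0}
        preds: dict[str, list[str]] = {s: []}
        q = deque([s])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    preds[v] = [u]
                    q.append(v)
                elif dist[v] == dist[u] + 1:
                    preds[v].append(u)
        if t not in dist:
            return []
        paths = []

        def back(v, acc):
            if v == s:
                paths.append([s, *reversed(acc)])
                return
            for u in preds[v]:
                back(u, acc + [v])

        back(t, [])
        return paths

    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(s, t)
        for path in paths:
            for v in path[1:-1]:
                score[v] += 1.0 / len(paths)
    return score


def hypergeom_tail(overlap, universe, set_size, module):
    """Exact upper-tail P(X >= overlap) by direct combinatorial sum."""
    total = math.comb(universe, module)
    acc = 0
    for x in range(overlap, min(set_size, module) + 1):
        acc += math.comb(set_size, x) * math.comb(universe - set_size, module - x)
    return acc / total


def universe_symbols(n):
    return [f"G{i:03d}" for i in range(n)]


def collection_of(**sets):
    coll = GeneSetCollection()
    for name, members in sets.items():
        coll.add(name, members)
    return coll
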