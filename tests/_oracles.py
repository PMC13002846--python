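"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations


def all_simple_paths(adj: dict, s, t) -> list[list]:
    """Every simple path from s to t by depth-first enumeration."""
    paths = []

    def walk(node, visited, path):
        if node == t:
            paths.append(path[:])
            return
        for nxt in sorted(adj.get(node, ())):
            if nxt not in visited:
                visited.add(nxt)
                path.append(nxt)
                walk(nxt, visited, path)
                path.pop()
                visited.remove(nxt)

    walk(s, {s}, [s])
    return paths


def oracle_betweenness(edges, nodes=None) -> dict:
    """Normalized betweenness by exhaustive shortest-path enumeration.

    For every unordered node pair, enumerates all simple paths, keeps the
    shortest ones, and credits each interior node with the fraction of
    geodesics passing through it; normalizes by (n-1)(n-2)/2.
    """
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    if nodes is None:
        nodes = sorted(adj)
    else:
        nodes = sorted(nodes)
    n = len(nodes)
    bc = {v: 0.0 for v in nodes}
    if n < 3:
        return bc
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            paths = all_simple_paths(adj, s, t)
            if not paths:
                continue
            shortest = min(len(p) for p in paths)
            geo = [p for p in paths if len(p) == shortest]
            for v in nodes:
                if v in (s, t):
                    continue
                bc[v] += sum(1 for p in geo if v in p) / len(geo)
    norm = (n - 1) * (n - 2) / 2
    return {v: bc[v] / norm for v in nodes}
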