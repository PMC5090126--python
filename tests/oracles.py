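"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: exhaustive path enumeration, direct
formula evaluation, step-up adjustment by its definition. None of it shares
code with the package.
"""

from itertools import combinations

import numpy as np
from scipy.stats import rankdata


# ---------------------------------------------------------------- statistics

def spearman_by_ranks(x, y):
    """Spearman rho as the Pearson correlation of average ranks."""
    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def bh_stepup(p):
    """Benjamini-Hochberg adjusted p-values, straight from the definition.

    adj for the i-th smallest p is min over k >= i of p_(k) * m / k, capped
    at 1; returned in the input order.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running_min = np.inf
    for idx in range(m - 1, -1, -1):
        k = idx + 1
        running_min = min(running_min, p[order[idx]] * m / k)
        adj_sorted[idx] = min(1.0, running_min)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


# ---------------------------------------------------------------- graphs

def _adjacency(edges):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    return adj


def all_shortest_paths(nodes, edges):
    """Map each unordered pair to its list of shortest simple paths.

    Exhaustive DFS enumeration of every simple path, then filtering the
    minimum length. Unreachable pairs are absent from the result.
    """
    adj = _adjacency(edges)
    nodes = list(nodes)
    result = {}
    for s, t in combinations(nodes, 2):
        paths = []

        def extend(path):
            last = path[-1]
            if last == t:
                paths.append(list(path))
                return
            for nxt in adj.get(last, ()):
                if nxt not in path:
                    path.append(nxt)
                    extend(path)
                    path.pop()

        extend([s])
        if paths:
            best = min(len(p) for p in paths)
            result[frozenset((s, t))] = [p for p in paths if len(p) == best]
    return result


def betweenness_oracle(nodes, edges, normalized=True):
    """Normalized vertex betweenness by counting shortest paths one by one."""
    nodes = list(nodes)
    sp = all_shortest_paths(nodes, edges)
    btw = {n: 0.0 for n in nodes}
    for pair, paths in sp.items():
        s, t = tuple(pair)
        total = len(paths)
        for n in nodes:
            if n in pair:
                continue
            through = sum(1 for p in paths if n in p)
            btw[n] += through / total
    if normalized:
        v = len(nodes)
        scale = 2.0 / ((v - 1) * (v - 2)) if v > 2 else 0.0
        btw = {n: b * scale for n, b in btw.items()}
    return btw


def edge_betweenness_oracle(nodes, edges):
    """Unnormalized edge betweenness via the same path enumeration."""
    sp = all_shortest_paths(nodes, edges)
    eb = {frozenset(e): 0.0 for e in edges}
    for paths in sp.values():
        total = len(paths)
        for p in paths:
            for u, v in zip(p, p[1:]):
                eb[frozenset((u, v))] += 1.0 / total
    return eb


def clustering_oracle(nodes, edges):
    """Local clustering by counting connected neighbor pairs."""
    adj = _adjacency(edges)
    out = {}
    for n in nodes:
        nbrs = list(adj.get(n, ()))
        k = len(nbrs)
        if k < 2:
            out[n] = 0.0
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if b in adj[a])
        out[n] = links / (k * (k - 1) / 2)
    return out


def transitivity_oracle(nodes, edges):
    """3 * triangles / connected triples; None when no triple exists."""
    adj = _adjacency(edges)
    triangles = sum(
        1 for a, b, c in combinations(nodes, 3)
        if b in adj.get(a, ()) and c in adj.get(a, ()) and c in adj.get(b, ())
    )
    triples = 0
    for n in nodes:
        d = len(adj.get(n, ()))
        triples += d * (d - 1) // 2
    if triples == 0:
        return None
    return 3.0 * triangles / triples


def distances_oracle(nodes, edges):
    """Hop distances between all mutually reachable unordered pairs."""
    sp = all_shortest_paths(nodes, edges)
    return {pair: len(paths[0]) - 1 for pair, paths in sp.items()}


def diameter_oracle(nodes, edges):
    """Diameter over the largest component(s), plus component count.

    Components tying for largest contribute the maximum diameter.
    """
    adj = _adjacency(edges)
    unseen = set(nodes)
    comps = []
    while unseen:
        start = unseen.pop()
        comp = {start}
        stack = [start]
        while stack:
            for nbr in adj.get(stack.pop(), ()):
                if nbr not in comp:
                    comp.add(nbr)
                    stack.append(nbr)
        unseen -= comp
        comps.append(comp)
    top = max(len(c) for c in comps)
    diam = 0
    for comp in comps:
        if len(comp) == top:
            dist = distances_oracle(comp, [e for e in edges
                                           if set(e) <= comp])
            if dist:
                diam = max(diam, max(dist.values()))
    return diam, len(comps)


def average_shortest_path_oracle(nodes, edges):
    """Mean hop distance over all connected unordered pairs (NaN if none)."""
    dist = distances_oracle(nodes, edges)
    if not dist:
        return float("nan")
    return float(np.mean(list(dist.values())))
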