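"""Independent brute-force oracles used to validate the graph and stats code.

Everything here is written from the textbook definitions with no reuse of the
package's implementations: Floyd-Warshall distances, betweenness by explicit
enumeration of all simple paths, clustering by direct triple loops, Wilcoxon
p-values by full 2^m sign enumeration, and flood-fill connected components.
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths; lengths[i, j] = 0 means no edge."""
    n = lengths.shape[0]
    d = np.where(lengths > 0, lengths.astype(float), np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def betweenness_by_enumeration(lengths: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
    """Unnormalised betweenness by enumerating every simple path per pair.

    For each unordered pair (s, t): list all simple s-t paths, find the
    minimal total length, count the shortest paths sigma_st and, for every
    interior node i, the share sigma_st(i)/sigma_st.
    """
    n = lengths.shape[0]
    adj = [[j for j in range(n) if lengths[i, j] > 0] for i in range(n)]
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = []

        def extend(node, visited, dist):
            if node == t:
                paths.append((dist, frozenset(visited) - {s, t}))
                return
            for nxt in adj[node]:
                if nxt not in visited:
                    extend(nxt, visited | {nxt}, dist + lengths[node, nxt])

        extend(s, {s}, 0.0)
        if not paths:
            continue
        best = min(d for d, _ in paths)
        shortest = [inner for d, inner in paths if d <= best * (1 + rtol) + 1e-15]
        sigma = len(shortest)
        for inner in shortest:
            for i in inner:
                bc[i] += 1.0 / sigma
    return bc


def clustering_triple_sum(w: np.ndarray, mode: str) -> np.ndarray:
    """Per-node clustering by direct triple loops over all (j, h) pairs."""
    n = w.shape[0]
    a = (w > 0).astype(float)
    c = np.zeros(n)
    wmax = w.max() if w.max() > 0 else 1.0
    for i in range(n):
        k = int(a[i].sum())
        if k < 2:
            continue
        acc = 0.0
        for j in range(n):
            for h in range(n):
                if j == i or h == i or j == h:
                    continue
                if mode == "binary":
                    acc += a[i, j] * a[i, h] * a[j, h]
                else:
                    acc += ((w[i, j] / wmax) * (w[i, h] / wmax) * (w[j, h] / wmax)) ** (1 / 3)
        c[i] = acc / (k * (k - 1))
    return c


def wilcoxon_exact_by_enumeration(d: np.ndarray) -> tuple:
    """(W, two-sided p) over all 2^m sign assignments of |d| midranks."""
    from scipy.stats import rankdata

    d = np.asarray(d, float)
    d = d[d != 0]
    m = d.size
    ranks = rankdata(np.abs(d))
    wplus_obs = ranks[d > 0].sum()
    total = m * (m + 1) / 2
    wplus_all = np.array([
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=m)
    ])
    n_assign = wplus_all.size
    eps = 1e-9
    cdf = (wplus_all <= wplus_obs + eps).sum() / n_assign
    sf = (wplus_all >= wplus_obs - eps).sum() / n_assign
    return min(wplus_obs, total - wplus_obs), min(1.0, 2.0 * min(cdf, sf))


def flood_fill_components(edges, n: int):
    """Connected components (as sorted tuples of edge indices) by flood fill."""
    edges = [tuple(e) for e in edges]
    adj = {}
    for idx, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, idx))
        adj.setdefault(v, []).append((u, idx))
    seen_nodes = set()
    comps = []
    for start in sorted(adj):
        if start in seen_nodes:
            continue
        stack = [start]
        seen_nodes.add(start)
        comp_edges = set()
        while stack:
            u = stack.pop()
            for v, idx in adj[u]:
                comp_edges.add(idx)
                if v not in seen_nodes:
                    seen_nodes.add(v)
                    stack.append(v)
        comps.append(tuple(sorted(comp_edges)))
    return comps


def random_graph(rng, n_max: int = 8, weighted: bool = True, p: float = 0.35):
    """Random symmetric weight matrix for oracle comparisons."""
    n = int(rng.integers(3, n_max + 1))
    mask = rng.random((n, n)) < p
    mask = np.triu(mask, 1)
    w = np.zeros((n, n))
    if weighted:
        vals = rng.uniform(0.1, 1.0, size=mask.sum())
    else:
        vals = np.ones(mask.sum())
    w[mask] = vals
    return w + w.T
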