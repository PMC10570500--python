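"""Global and nodal graph metrics on thresholded FC networks.

All metrics run in either ``binary`` mode (edges count as length 1) or
``weighted`` mode (edge length 1/w, Onnela weighted clustering); weighted is
the default since thresholded FC networks keep their correlation weights.

Small-worldness sigma = gamma / lambda compares clustering and characteristic
path length against degree-preserving Maslov-Sneppen rewired null networks in
which each edge carries its weight along through the swaps.  Characteristic
path length averages over reachable pairs only; efficiency counts unreachable
pairs as zero contribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from .fc import FCMatrix

__all__ = [
    "GlobalMetrics", "NodalMetrics",
    "shortest_path_lengths", "global_efficiency", "characteristic_path_length",
    "clustering_coefficients", "nodal_metrics", "rewire_null",
    "small_worldness", "global_metrics",
]


@dataclass(frozen=True)
class GlobalMetrics:
    """Whole-network summary for one scan."""

    overall_strength: float
    global_efficiency: float
    gamma: float      # clustering normalised by rewired nulls
    lambda_: float    # characteristic path length normalised by rewired nulls
    sigma: float      # gamma / lambda
    n_null: int


@dataclass(frozen=True)
class NodalMetrics:
    """Per-node metrics; arrays indexed by region."""

    degree: np.ndarray
    strength: np.ndarray
    efficiency: np.ndarray
    betweenness: np.ndarray


def _as_w(fc) -> np.ndarray:
    return fc.w if isinstance(fc, FCMatrix) else np.asarray(fc, dtype=float)


def _length_matrix(w: np.ndarray, mode: str) -> np.ndarray:
    if mode == "binary":
        return (w > 0).astype(float)
    if mode == "weighted":
        with np.errstate(divide="ignore"):
            ell = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
        return ell
    raise ValueError(f"unknown mode {mode!r}")


def shortest_path_lengths(fc, mode: str = "weighted") -> np.ndarray:
    """All-pairs shortest-path distance matrix; unreachable pairs are +inf."""
    w = _as_w(fc)
    ell = _length_matrix(w, mode)
    d = shortest_path(csr_array(ell), method="D", directed=False)
    np.fill_diagonal(d, 0.0)
    return d


def global_efficiency(fc, mode: str = "weighted") -> float:
    """Mean inverse shortest-path length over ordered node pairs (1/inf = 0)."""
    w = _as_w(fc)
    n = w.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    d = shortest_path_lengths(w, mode)
    inv = np.zeros_like(d)
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    return float(inv[off].sum() / (n * (n - 1)))


def characteristic_path_length(fc, mode: str = "weighted") -> float:
    """Mean shortest-path distance over reachable (finite) off-diagonal pairs."""
    d = shortest_path_lengths(_as_w(fc), mode)
    off = ~np.eye(d.shape[0], dtype=bool)
    finite = off & np.isfinite(d)
    if not finite.any():
        return float("nan")
    return float(d[finite].mean())


def clustering_coefficients(fc, mode: str = "weighted") -> np.ndarray:
    """Per-node clustering coefficient.

    Binary: C_i = 2 T_i / (k_i (k_i - 1)).  Weighted (Onnela): geometric-mean
    triangle intensity of weights normalised by the network maximum,
    C_i = sum_jh (w'_ij w'_ih w'_jh)^{1/3} / (k_i (k_i - 1)).  Nodes of degree
    < 2 get C_i = 0.
    """
    w = _as_w(fc)
    a = (w > 0).astype(float)
    k = a.sum(axis=1)
    denom = k * (k - 1)
    if mode == "binary":
        tri = np.diag(a @ a @ a)
    elif mode == "weighted":
        wmax = w.max()
        if wmax == 0:
            return np.zeros(w.shape[0])
        wh = np.cbrt(w / wmax)
        tri = np.diag(wh @ wh @ wh)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri / np.where(denom > 0, denom, 1.0), 0.0)
    return c


def _graph(w: np.ndarray, mode: str) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(w.shape[0]))
    iu, ju = np.triu_indices(w.shape[0], 1)
    mask = w[iu, ju] > 0
    if mode == "binary":
        g.add_edges_from(zip(iu[mask].tolist(), ju[mask].tolist()))
    else:
        g.add_weighted_edges_from(
            zip(iu[mask].tolist(), ju[mask].tolist(), (1.0 / w[iu, ju][mask]).tolist()),
            weight="length",
        )
    return g


def nodal_metrics(fc, mode: str = "weighted") -> NodalMetrics:
    """Degree, weighted strength, nodal efficiency and raw betweenness.

    Degree is the count of incident edges; strength the sum of incident
    weights; nodal efficiency the mean inverse distance to all other nodes;
    betweenness the unnormalised Brandes count of pair dependencies (each
    unordered source-target pair counted once).
    """
    w = _as_w(fc)
    n = w.shape[0]
    degree = (w > 0).sum(axis=1).astype(float)
    strength = w.sum(axis=1)
    d = shortest_path_lengths(w, mode)
    inv = np.zeros_like(d)
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    efficiency = inv.sum(axis=1) / (n - 1) if n > 1 else np.zeros(n)
    g = _graph(w, mode)
    bc = nx.betweenness_centrality(
        g, normalized=False, weight=None if mode == "binary" else "length"
    )
    betweenness = np.array([bc[i] for i in range(n)])
    return NodalMetrics(degree=degree, strength=strength,
                        efficiency=efficiency, betweenness=betweenness)


def rewire_null(fc, n_swaps_per_edge: int = 10, seed=None) -> FCMatrix:
    """Degree-preserving Maslov-Sneppen rewiring with weights carried on edges.

    Performs ``n_swaps_per_edge * n_edges`` double-edge-swap attempts; an
    attempt is applied only when it creates neither self-loops nor duplicate
    edges.  Deterministic under ``seed``.
    """
    w = _as_w(fc)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, 1)
    mask = w[iu, ju] > 0
    u = iu[mask].astype(np.int64)
    v = ju[mask].astype(np.int64)
    wt = w[iu, ju][mask]
    m = u.size
    if m < 2:
        warnings.warn("fewer than 2 edges; returning an unchanged copy", stacklevel=2)
        return FCMatrix(w=w.copy())
    rng = np.random.default_rng(seed)
    present = set((u * n + v).tolist())
    attempts = int(n_swaps_per_edge) * m
    pairs = rng.integers(0, m, size=(attempts, 2))
    flips = rng.random(attempts) < 0.5
    for (a, b), flip in zip(pairs, flips):
        if a == b:
            continue
        ua, va = u[a], v[a]
        ub, vb = (v[b], u[b]) if flip else (u[b], v[b])
        # proposed replacement edges: (ua, ub) and (va, vb)
        if ua == ub or va == vb:
            continue
        e1 = (ua * n + ub) if ua < ub else (ub * n + ua)
        e2 = (va * n + vb) if va < vb else (vb * n + va)
        if e1 == e2 or e1 in present or e2 in present:
            continue
        present.remove(ua * n + va)
        present.remove(min(u[b], v[b]) * n + max(u[b], v[b]))
        present.add(e1)
        present.add(e2)
        u[a], v[a] = min(ua, ub), max(ua, ub)
        u[b], v[b] = min(va, vb), max(va, vb)
    out = np.zeros_like(w)
    out[u, v] = wt
    out[v, u] = wt
    return FCMatrix(w=out)


def small_worldness(fc, n_null: int = 100, n_swaps_per_edge: int = 10,
                    seed=None, mode: str = "weighted"):
    """(gamma, lambda, sigma) against rewired null networks.

    gamma = C_real / mean(C_null); lambda = L_real / mean(L_null);
    sigma = gamma / lambda.  NaN when a null mean is zero or path length is
    undefined (fully disconnected network).
    """
    w = _as_w(fc)
    c_real = float(clustering_coefficients(w, mode).mean())
    l_real = characteristic_path_length(w, mode)
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    children = ss.spawn(n_null)
    c_null = np.empty(n_null)
    l_null = np.empty(n_null)
    for k in range(n_null):
        nullw = rewire_null(w, n_swaps_per_edge=n_swaps_per_edge, seed=children[k]).w
        c_null[k] = clustering_coefficients(nullw, mode).mean()
        l_null[k] = characteristic_path_length(nullw, mode)
    cbar, lbar = float(np.mean(c_null)), float(np.nanmean(l_null))
    gamma = c_real / cbar if cbar > 0 else float("nan")
    lam = l_real / lbar if lbar > 0 and np.isfinite(l_real) else float("nan")
    sigma = gamma / lam if np.isfinite(gamma) and np.isfinite(lam) and lam > 0 else float("nan")
    return gamma, lam, sigma


def global_metrics(fc, mode: str = "weighted", n_null: int = 100,
                   n_swaps_per_edge: int = 10, seed=None) -> GlobalMetrics:
    """Bundle overall strength, global efficiency and small-world indices."""
    fc = fc if isinstance(fc, FCMatrix) else FCMatrix(w=_as_w(fc))
    gamma, lam, sigma = small_worldness(
        fc, n_null=n_null, n_swaps_per_edge=n_swaps_per_edge, seed=seed, mode=mode
    )
    return GlobalMetrics(
        overall_strength=fc.overall_strength,
        global_efficiency=global_efficiency(fc, mode),
        gamma=gamma, lambda_=lam, sigma=sigma, n_null=n_null,
    )
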