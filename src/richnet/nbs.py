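"""Network-based statistic (NBS) for paired pre/post designs.

The NBS controls family-wise error over connected components of edges rather
than over individual edges: a paired t statistic is computed for every edge
from the subject-wise post-minus-pre differences, edges passing a primary
threshold (default t = 3, positive direction) are kept, and connected
components of the kept-edge graph are sized by their number of edges.  The
null distribution of the maximal component size is built by randomly flipping
the sign of each subject's difference matrix (exact exchangeability for a
paired design) and repeating the thresholding; each observed component gets
p = (1 + #{null max sizes >= observed size}) / (n_permutations + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_array
from scipy.sparse.csgraph import connected_components

__all__ = ["Component", "NBSResult", "edgewise_paired_t",
           "suprathreshold_components", "nbs_paired"]

_PERM_CHUNK = 512  # permutations processed per vectorised block


@dataclass(frozen=True)
class Component:
    """One suprathreshold connected component; size is its edge count."""

    edges: np.ndarray  # (size, 2) node index pairs, i < j
    size: int
    p_value: float = float("nan")


@dataclass(frozen=True)
class NBSResult:
    t_map: np.ndarray
    threshold: float
    direction: str
    components: tuple
    null_max_sizes: np.ndarray
    n_permutations: int
    seed: object

    @property
    def p_values(self) -> np.ndarray:
        return np.array([c.p_value for c in self.components])


def _as_matrix_stack(mats) -> np.ndarray:
    arr = np.stack([m.w if hasattr(m, "w") else np.asarray(m, float) for m in mats])
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ValueError("expected a list of square matrices")
    return arr


def _diff_vectors(pre, post):
    pre = _as_matrix_stack(pre)
    post = _as_matrix_stack(post)
    if pre.shape != post.shape:
        raise ValueError("pre and post lists must match in length and node count")
    if pre.shape[0] < 3:
        raise ValueError("paired t needs at least 3 subjects")
    n = pre.shape[1]
    iu = np.triu_indices(n, 1)
    d = (post - pre)[:, iu[0], iu[1]]  # subjects x edges
    return d, iu, n


def _t_from_diffs(d: np.ndarray) -> np.ndarray:
    s = d.shape[0]
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(s)), 0.0)
    return t


def edgewise_paired_t(pre, post) -> np.ndarray:
    """Symmetric matrix of paired t statistics (post minus pre) per edge.

    Edges with zero difference variance across subjects get t = 0 with a
    warning.
    """
    d, iu, n = _diff_vectors(pre, post)
    zero_var = (d.std(axis=0, ddof=1) == 0) & (d.mean(axis=0) != 0)
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} edge(s) with constant nonzero difference; t set to 0",
            stacklevel=2,
        )
    tvec = _t_from_diffs(d)
    t = np.zeros((n, n))
    t[iu[0], iu[1]] = tvec
    return t + t.T


def _kept_mask(tvec: np.ndarray, threshold: float, direction: str) -> np.ndarray:
    if direction == "positive":
        return tvec > threshold
    if direction == "negative":
        return tvec < -threshold
    if direction == "two_sided":
        return np.abs(tvec) > threshold
    raise ValueError(f"unknown direction {direction!r}")


def _components_from_edges(u: np.ndarray, v: np.ndarray):
    """Connected components of an edge list; yields (edge_index_array,) groups."""
    if u.size == 0:
        return []
    nodes, inv = np.unique(np.concatenate([u, v]), return_inverse=True)
    uu, vv = inv[: u.size], inv[u.size:]
    k = nodes.size
    g = coo_array((np.ones(u.size), (uu, vv)), shape=(k, k))
    _, lab = connected_components(g, directed=False)
    edge_lab = lab[uu]
    groups = []
    for c in np.unique(edge_lab):
        groups.append(np.flatnonzero(edge_lab == c))
    return groups


def _max_component_size(u: np.ndarray, v: np.ndarray) -> int:
    groups = _components_from_edges(u, v)
    return max((g.size for g in groups), default=0)


def suprathreshold_components(t_map: np.ndarray, threshold: float,
                              direction: str = "positive"):
    """Connected components of the suprathreshold-edge graph, sized in edges.

    Returns Components sorted by decreasing size (ties broken by smallest node
    pair) with p_value unset (NaN).
    """
    if threshold <= 0:
        raise ValueError("primary threshold must be positive")
    t_map = np.asarray(t_map, float)
    n = t_map.shape[0]
    iu = np.triu_indices(n, 1)
    tvec = t_map[iu]
    kept = _kept_mask(tvec, threshold, direction)
    u, v = iu[0][kept], iu[1][kept]
    comps = []
    for g in _components_from_edges(u, v):
        edges = np.column_stack([u[g], v[g]])
        order = np.lexsort((edges[:, 1], edges[:, 0]))
        comps.append(Component(edges=edges[order], size=int(g.size)))
    comps.sort(key=lambda c: (-c.size, c.edges[0, 0], c.edges[0, 1]))
    return comps


def nbs_paired(pre, post, threshold: float = 3.0, n_permutations: int = 5000,
               direction: str = "positive", seed=None) -> NBSResult:
    """Full paired NBS with subject sign-flip permutations.

    ``pre``/``post`` are matched lists of square FC matrices (raw correlation
    matrices by convention; any symmetric edge maps work).  Deterministic for
    a fixed ``seed``.
    """
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations gives unstable p-values", stacklevel=2)
    d, iu, n = _diff_vectors(pre, post)
    s = d.shape[0]
    tvec = _t_from_diffs(d)
    t_map = np.zeros((n, n))
    t_map[iu[0], iu[1]] = tvec
    t_map = t_map + t_map.T
    observed = suprathreshold_components(t_map, threshold, direction)

    rng = np.random.default_rng(seed)
    ssq = (d * d).sum(axis=0)  # invariant under sign flips
    null_max = np.empty(n_permutations, dtype=np.int64)
    done = 0
    while done < n_permutations:
        k = min(_PERM_CHUNK, n_permutations - done)
        signs = rng.integers(0, 2, size=(k, s)) * 2 - 1
        mean = (signs @ d) / s
        var = (ssq - s * mean * mean) / (s - 1)
        np.clip(var, 0.0, None, out=var)
        with np.errstate(invalid="ignore", divide="ignore"):
            tperm = np.where(var > 0, mean / np.sqrt(var / s), 0.0)
        for row in range(k):
            kept = _kept_mask(tperm[row], threshold, direction)
            null_max[done + row] = _max_component_size(iu[0][kept], iu[1][kept])
        done += k

    scored = tuple(
        Component(
            edges=c.edges, size=c.size,
            p_value=float((1 + (null_max >= c.size).sum()) / (n_permutations + 1)),
        )
        for c in observed
    )
    return NBSResult(
        t_map=t_map, threshold=float(threshold), direction=direction,
        components=scored, null_max_sizes=null_max,
        n_permutations=int(n_permutations), seed=seed,
    )
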