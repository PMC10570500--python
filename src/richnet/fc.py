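"""Functional-connectivity network construction.

Pairwise Pearson correlation between regional time courses gives a raw FC
matrix; edge p-values come from the usual t transform
``t = r * sqrt((n-2) / (1-r^2))`` on ``n-2`` degrees of freedom (two-sided).
Family-wise error control across the E = n(n-1)/2 edges (Bonferroni by
default, Holm optional) combined with exclusion of negative correlations
yields the sparse nonnegative weighted network used by all downstream graph
analysis; surviving edges keep their raw correlation value as weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["RawFC", "FCMatrix", "pearson_fc", "threshold_fwe",
           "read_series_tsv", "write_fc_tsv", "read_fc_tsv"]


@dataclass(frozen=True)
class RawFC:
    """Unthresholded correlation structure of one scan."""

    r: np.ndarray
    p: np.ndarray
    n_timepoints: int

    @property
    def n_nodes(self) -> int:
        return self.r.shape[0]


@dataclass(frozen=True)
class FCMatrix:
    """Thresholded, symmetric, nonnegative weighted adjacency (zero diagonal)."""

    w: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("weight matrix must have zero diagonal")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        object.__setattr__(self, "w", w)

    @property
    def n_nodes(self) -> int:
        return self.w.shape[0]

    @property
    def overall_strength(self) -> float:
        """Sum of all connection weights (each undirected edge counted once)."""
        iu = np.triu_indices(self.n_nodes, 1)
        return float(self.w[iu].sum())

    def edges(self):
        """(i, j, weight) arrays over nonzero upper-triangle entries."""
        iu = np.triu_indices(self.n_nodes, 1)
        mask = self.w[iu] > 0
        return iu[0][mask], iu[1][mask], self.w[iu][mask]


def pearson_fc(series) -> RawFC:
    """Raw Pearson FC matrix of one (timepoints x regions) series.

    Zero-variance columns get r = 0, p = 1 on all their edges (with a
    warning); fewer than 3 timepoints or non-finite values are rejected.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError("series must be 2-D (timepoints x regions)")
    t, n = x.shape
    if t < 3:
        raise ValueError("need at least 3 timepoints for edge p-values")
    if not np.isfinite(x).all():
        raise ValueError("series contains NaN or infinite values")
    sd = x.std(axis=0)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant column(s); their edges get r=0, p=1",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    if flat.any():
        r[flat, :] = 0.0
        r[:, flat] = 0.0
    np.fill_diagonal(r, 1.0)
    df = t - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt(df / (1.0 - r * r))
    tstat[np.abs(r) >= 1.0] = np.inf
    p = 2.0 * sps.t.sf(np.abs(tstat), df)
    if flat.any():
        p[flat, :] = 1.0
        p[:, flat] = 1.0
    np.fill_diagonal(p, 0.0)
    p = (p + p.T) / 2.0  # exact symmetry despite float noise
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return RawFC(r=r, p=p, n_timepoints=t)


def _holm_reject(pvec: np.ndarray, alpha: float) -> np.ndarray:
    order = np.argsort(pvec, kind="stable")
    m = pvec.size
    reject = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if pvec[idx] < alpha / (m - rank):
            reject[idx] = True
        else:
            break
    return reject


def threshold_fwe(raw: RawFC, alpha: float = 0.05, method: str = "bonferroni") -> FCMatrix:
    """Family-wise-error threshold a raw FC matrix; drop negative edges.

    Bonferroni keeps edge (i, j) iff ``p_ij < alpha / E`` with E = n(n-1)/2;
    Holm applies the step-down variant.  Either way an edge also needs
    ``r_ij > 0``; survivors carry their raw ``r`` as weight.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    n = raw.n_nodes
    iu = np.triu_indices(n, 1)
    pvec = raw.p[iu]
    if method == "bonferroni":
        keep = pvec < alpha / pvec.size
    elif method == "holm":
        keep = _holm_reject(pvec, alpha)
    else:
        raise ValueError(f"unknown FWE method {method!r}")
    keep &= raw.r[iu] > 0
    w = np.zeros((n, n))
    w[iu[0][keep], iu[1][keep]] = raw.r[iu][keep]
    w = w + w.T
    return FCMatrix(w=w)


def read_series_tsv(path):
    """Read a (timepoints x regions) series TSV; returns (array, region names)."""
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(float), list(df.columns)


def write_fc_tsv(fc, names, path) -> Path:
    """Write a square weight matrix as TSV with region-name header row/column."""
    w = fc.w if isinstance(fc, FCMatrix) else np.asarray(fc, float)
    df = pd.DataFrame(w, index=names, columns=names)
    path = Path(path)
    df.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_fc_tsv(path):
    """Read a square FC TSV written by :func:`write_fc_tsv`; (FCMatrix, names)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FCMatrix(w=df.to_numpy(float)), list(df.columns)
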