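"""Nonparametric statistics: Wilcoxon signed-rank, Spearman, BH-FDR.

The Wilcoxon test drops zero differences, midranks ties, and returns an exact
two-sided p-value by enumerating the distribution of the positive-rank sum
over all 2^m sign assignments (via convolution over doubled ranks, which stay
integral under midranking) whenever m <= 12; beyond that a normal
approximation with tie-corrected variance and continuity correction is used.

Spearman's rho is the Pearson correlation of midranks with a t-transform
p-value; for n <= 8 an exact permutation p over all n! orderings is returned
instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = ["StatResult", "wilcoxon_signed_rank", "spearman", "bh_fdr",
           "EXACT_WILCOXON_MAX_N", "EXACT_SPEARMAN_MAX_N"]

EXACT_WILCOXON_MAX_N = 12
EXACT_SPEARMAN_MAX_N = 8

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class StatResult:
    """Outcome of one nonparametric test."""

    statistic: float
    p_value: float
    n_effective: int
    method: str


def _wplus_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts over 2*W+ values for all sign assignments (ranks doubled to ints)."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts += shifted
    return counts


def wilcoxon_signed_rank(x, y) -> StatResult:
    """Two-sided Wilcoxon signed-rank test of paired samples (d = y - x).

    Zero differences are dropped; the statistic is W = min(W+, W-).  All-zero
    differences give p = 1 (method ``degenerate``); 1 or 2 nonzero differences
    are rejected as uninformative.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    d = y - x
    if not np.isfinite(d).all():
        raise ValueError("non-finite paired values")
    d = d[d != 0]
    m = d.size
    if m == 0:
        return StatResult(statistic=0.0, p_value=1.0, n_effective=0, method="degenerate")
    if m < 3:
        raise ValueError("need at least 3 nonzero differences")
    ranks = sps.rankdata(np.abs(d))
    wplus = float(ranks[d > 0].sum())
    total = m * (m + 1) / 2
    w = min(wplus, total - wplus)
    if m <= EXACT_WILCOXON_MAX_N:
        ranks2 = np.rint(2 * ranks).astype(int)
        counts = _wplus_distribution(ranks2)
        n_assign = 2.0 ** m
        w2 = int(round(2 * wplus))
        cdf = counts[: w2 + 1].sum() / n_assign
        sf = counts[w2:].sum() / n_assign
        p = min(1.0, 2.0 * min(cdf, sf))
        method = "exact"
    else:
        mu = total / 2.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = m * (m + 1) * (2 * m + 1) / 24.0 - (tie_counts ** 3 - tie_counts).sum() / 48.0
        dev = wplus - mu
        cc = 0.5 * np.sign(dev)
        z = (dev - cc) / np.sqrt(var)
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
        method = "approx"
    return StatResult(statistic=w, p_value=max(p, _TINY), n_effective=m, method=method)


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def spearman(x, y) -> StatResult:
    """Spearman rank correlation with two-sided p-value.

    Exact permutation p for n <= 8; otherwise the t transform
    ``t = rho sqrt((n-2)/(1-rho^2))`` on n-2 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero variance in ranks; correlation undefined")
    rho = _rank_corr(rx, ry)
    if n <= EXACT_SPEARMAN_MAX_N:
        cx = rx - rx.mean()
        cy = ry - ry.mean()
        norm = np.sqrt((cx @ cx) * (cy @ cy))
        perms = np.array(list(permutations(cy)))
        rho_perm = (perms @ cx) / norm
        count = int((np.abs(rho_perm) >= abs(rho) - 1e-12).sum())
        p = count / factorial(n)
        method = "exact"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * sps.t.sf(abs(t), n - 2)
        method = "approx"
    return StatResult(statistic=rho, p_value=max(min(p, 1.0), _TINY),
                      n_effective=n, method=method)


def bh_fdr(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up across a family of p-values.

    Returns ``(reject_mask, adjusted_p)`` at level ``q``; empty input gives
    empty arrays.
    """
    p = np.asarray(p_values, float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, adjusted
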