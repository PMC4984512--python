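"""Independent brute-force oracles used to check the fitting machinery.

Everything here deliberately avoids the package's prefix-sum algebra:
fits are plain design-matrix least squares via numpy lstsq, searches
are naive Python loops, and NODF is an explicit double loop over
pairs.  These implementations are slow but transparently correct on
small inputs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def line_rss(x: np.ndarray, y: np.ndarray) -> float:
    if len(np.unique(x)) == 1:
        return float(((y - y.mean()) ** 2).sum())
    X = np.column_stack([np.ones_like(x), x])
    return ols_rss(X, y)[1]


def segment_rss(x, y, thresholds) -> float:
    """Sum of independent per-segment OLS RSS values."""
    edges = [-math.inf, *thresholds, math.inf]
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (x > lo) & (x <= hi)
        total += line_rss(x[sel], y[sel])
    return total


def hinge_rss(x, y, t) -> float:
    X = np.column_stack([np.ones_like(x), np.maximum(0.0, x - t)])
    return ols_rss(X, y)[1]


def _grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(math.floor((hi - lo) / step + 1e-9))
    g = lo + step * np.arange(n + 1)
    g = g[g <= hi + 1e-12]
    if hi - g[-1] > 1e-12:
        g = np.append(g, hi)
    return g


def brute_lh1(x, y, step, minseg):
    """(T1, rss) minimising the hinge fit over the inclusive grid."""
    best = (math.inf, None)
    for t in _grid(x.min(), x.max(), step):
        n_lo = int((x <= t).sum())
        if n_lo < minseg or len(x) - n_lo < minseg:
            continue
        r = hinge_rss(x, y, t)
        if r < best[0]:
            best = (r, t)
    return best[1], best[0]


def brute_two_slope(x, y, minseg):
    best = (math.inf, None)
    for t in np.unique(x)[:-1]:
        n_lo = int((x <= t).sum())
        if n_lo < minseg or len(x) - n_lo < minseg:
            continue
        r = segment_rss(x, y, [t])
        if r < best[0]:
            best = (r, t)
    return best[1], best[0]


def brute_three_slope(x, y, minseg):
    vals = np.unique(x)
    best = (math.inf, None)
    for t1, t2 in itertools.combinations(vals, 2):
        ns = [
            int((x <= t1).sum()),
            int(((x > t1) & (x <= t2)).sum()),
            int((x > t2).sum()),
        ]
        if min(ns) < minseg:
            continue
        r = segment_rss(x, y, [t1, t2])
        if r < best[0]:
            best = (r, (t1, t2))
    return best[1], best[0]


def brute_lh2(x, y, step, minseg):
    """Naive 2D search: T2 over data values, T1 over the grid below it."""
    best = (math.inf, None)
    for t2 in np.unique(x):
        upper = x > t2
        if upper.sum() < minseg:
            continue
        sel = ~upper
        for t1 in _grid(x.min(), t2, step):
            if t1 >= t2:
                continue
            n1 = int((x <= t1).sum())
            n2 = int(sel.sum()) - n1
            if n1 < minseg or n2 < minseg:
                continue
            r = hinge_rss(x[sel], y[sel], t1) + line_rss(x[upper], y[upper])
            if r < best[0]:
                best = (r, (t1, t2))
    return best[1], best[0]


def nodf_brute(m: np.ndarray) -> float:
    """NODF by explicit pair loops."""

    def pair_sum(vectors):
        total, npairs = 0.0, 0
        for a, b in itertools.combinations(vectors, 2):
            ta, tb = a.sum(), b.sum()
            npairs += 1
            if ta == tb or min(ta, tb) == 0:
                continue
            poorer, richer = (a, b) if ta < tb else (b, a)
            total += 100.0 * float((poorer & richer).sum()) / poorer.sum()
        return total, npairs

    rows = [m[i, :].astype(int) for i in range(m.shape[0])]
    cols = [m[:, j].astype(int) for j in range(m.shape[1])]
    rs, rp = pair_sum(rows)
    cs, cp = pair_sum(cols)
    return (rs + cs) / (rp + cp)


def enumerate_ff_space(m: np.ndarray) -> list[np.ndarray]:
    """All binary matrices sharing the marginals of small m (brute force)."""
    r, c = m.shape
    rt, ct = m.sum(axis=1), m.sum(axis=0)
    out = []
    for bits in itertools.product((0, 1), repeat=r * c):
        cand = np.array(bits, dtype=np.int8).reshape(r, c)
        if (cand.sum(axis=1) == rt).all() and (cand.sum(axis=0) == ct).all():
            out.append(cand)
    return out
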