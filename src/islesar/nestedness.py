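"""NODF nestedness, binary null models, and portion-level sampling.

NODF (nestedness metric based on overlap and decreasing fill) scores a
binary species x island matrix between 0 (no nestedness) and 100
(perfect nestedness).  For every unordered pair of columns the pair
score is 0 if the two column totals tie (or either is 0) and otherwise
100 * (shared presences) / (total of the poorer column); row pairs are
scored the same way, and NODF averages all pair scores.  Because the
score is defined through marginal totals, it is invariant to row and
column permutation.

Significance is assessed against Monte-Carlo ensembles from three
binary null models of increasing constraint:

EE  equiprobable-equiprobable: only the total number of presences is
    kept; occupied cells are re-drawn uniformly without replacement.
CC  an intermediate, probabilistic model: cell (i, j) is occupied
    independently with probability (row fill_i + column fill_j) / 2,
    preserving expected shape and fill.
FF  fixed-fixed: both marginal total vectors are preserved exactly;
    sampled (asymptotically uniformly) by curveball trades.

The portion-sampling procedure repeatedly scores NODF on random
column (island) subsets to characterise nestedness of parts of the
system even when the whole is antinested.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PresenceAbsenceMatrix",
    "NestednessResult",
    "PortionSamplingResult",
    "compute_nodf",
    "null_ee",
    "null_cc",
    "null_ff",
    "nestedness_significance",
    "sample_portions",
    "enumerate_portions",
]


@dataclass
class PresenceAbsenceMatrix:
    """Binary species (rows) x islands (columns) occurrence matrix."""

    species_ids: list[str]
    island_ids: list[str]
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells)
        if self.cells.ndim != 2:
            raise ValueError("cells must be 2-dimensional")
        if not np.isin(self.cells, (0, 1)).all():
            raise ValueError("cells must be binary 0/1")
        self.cells = self.cells.astype(np.int8)
        r, c = self.cells.shape
        if len(self.species_ids) != r or len(self.island_ids) != c:
            raise ValueError("label lengths must match matrix shape")

    @classmethod
    def from_cells(cls, cells, species_ids=None, island_ids=None) -> "PresenceAbsenceMatrix":
        cells = np.asarray(cells)
        r, c = cells.shape
        if species_ids is None:
            species_ids = [f"sp{i:04d}" for i in range(r)]
        if island_ids is None:
            island_ids = [f"isl{j:04d}" for j in range(c)]
        return cls(list(species_ids), list(island_ids), cells)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    @property
    def row_totals(self) -> np.ndarray:
        return self.cells.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.cells.sum(axis=0)

    @property
    def fill(self) -> float:
        """Percentage of 1-cells."""
        r, c = self.cells.shape
        return 100.0 * float(self.cells.sum()) / (r * c)

    def _replace(self, cells: np.ndarray) -> "PresenceAbsenceMatrix":
        return PresenceAbsenceMatrix(list(self.species_ids), list(self.island_ids), cells)


@dataclass
class NestednessResult:
    """Observed NODF with a Monte-Carlo null comparison.

    ``p_value`` is the upper-tail probability (1 + #{null NODF >=
    observed}) / (1 + ensemble size): small values indicate nestedness
    beyond the null, values near 1 indicate antinestedness.  The
    lower tail is reported alongside since reported probabilities in
    the literature do not always state their tail.
    """

    nodf: float
    null_model: str
    ensemble_size: int
    p_value: float
    p_lower: float
    null_mean: float
    null_sd: float


@dataclass
class PortionSamplingResult:
    """NODF distribution over random column subsets of a matrix."""

    n_iterations: int
    nodf_samples: np.ndarray
    nodf_max: float
    histogram: "np.ndarray"  # columns: bin_left, bin_right, scaled_density
    exhaustive: bool = False


# ---------------------------------------------------------------------------
# NODF
# ---------------------------------------------------------------------------


def _pair_score_sum(m: np.ndarray) -> tuple[float, int]:
    """Sum of column-pair NODF scores of ``m`` and the number of pairs."""
    t = m.sum(axis=0).astype(float)
    c = m.shape[1]
    if c < 2:
        return 0.0, 0
    ov = (m.T.astype(np.int64) @ m.astype(np.int64)).astype(float)
    iu, ju = np.triu_indices(c, k=1)
    ti, tj = t[iu], t[ju]
    poorer = np.minimum(ti, tj)
    valid = (ti != tj) & (poorer > 0)
    scores = np.where(valid, 100.0 * ov[iu, ju] / np.where(poorer > 0, poorer, 1.0), 0.0)
    return float(scores.sum()), len(iu)


def _nodf_raw(m: np.ndarray) -> float:
    """NODF of a binary array; tolerates degenerate shapes (0 pairs -> 0)."""
    col_sum, n_col_pairs = _pair_score_sum(m)
    row_sum, n_row_pairs = _pair_score_sum(m.T)
    denom = n_col_pairs + n_row_pairs
    if denom == 0:
        return 0.0
    return (col_sum + row_sum) / denom


def compute_nodf(matrix: PresenceAbsenceMatrix | np.ndarray) -> float:
    """NODF of a presence-absence matrix, in [0, 100]."""
    m = matrix.cells if isinstance(matrix, PresenceAbsenceMatrix) else np.asarray(matrix)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("matrix cells must be binary 0/1")
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("matrix must have at least 2 rows and 2 columns")
    return _nodf_raw(m)


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------


def null_ee(matrix: PresenceAbsenceMatrix, rng: np.random.Generator) -> PresenceAbsenceMatrix:
    """Equiprobable-equiprobable null: same shape and total fill,
    occupied cells placed uniformly at random without replacement."""
    m = matrix.cells
    total = int(m.sum())
    flat = np.zeros(m.size, dtype=np.int8)
    pos = rng.choice(m.size, size=total, replace=False)
    flat[pos] = 1
    return matrix._replace(flat.reshape(m.shape))


def null_cc(matrix: PresenceAbsenceMatrix, rng: np.random.Generator) -> PresenceAbsenceMatrix:
    """Probabilistic intermediate null: cell (i, j) occupied with
    probability (row fill_i + column fill_j) / 2; expected fill equals
    the observed fill."""
    m = matrix.cells
    r, c = m.shape
    rowfill = m.sum(axis=1, dtype=float) / c
    colfill = m.sum(axis=0, dtype=float) / r
    p = 0.5 * (rowfill[:, None] + colfill[None, :])
    draw = (rng.random((r, c)) < p).astype(np.int8)
    return matrix._replace(draw)


def _curveball_trades(row_sets: list[set[int]], n_trades: int, rng: np.random.Generator) -> None:
    """In-place curveball trades preserving all row and column totals."""
    n_rows = len(row_sets)
    if n_rows < 2:
        return
    pairs = rng.integers(0, n_rows, size=(n_trades, 2))
    for a, b in pairs:
        if a == b:
            continue
        ra, rb = row_sets[a], row_sets[b]
        a_only = list(ra - rb)
        b_only = list(rb - ra)
        if not a_only or not b_only:
            continue
        pool = a_only + b_only
        rng.shuffle(pool)
        shared = ra & rb
        row_sets[a] = shared | set(pool[: len(a_only)])
        row_sets[b] = shared | set(pool[len(a_only) :])


def _sets_to_cells(row_sets: list[set[int]], shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=np.int8)
    for i, s in enumerate(row_sets):
        if s:
            out[i, list(s)] = 1
    return out


def null_ff(
    matrix: PresenceAbsenceMatrix,
    rng: np.random.Generator,
    burn_in: int | None = None,
    thin: int | None = None,
) -> PresenceAbsenceMatrix:
    """Fixed-fixed null: a (asymptotically uniform) random matrix with
    exactly the observed row and column totals, drawn by curveball
    trades after ``burn_in`` trades (default 1000*(rows+cols))."""
    m = matrix.cells
    r, c = m.shape
    if burn_in is None:
        burn_in = 1000 * (r + c)
    row_sets = [set(np.flatnonzero(m[i]).tolist()) for i in range(r)]
    degenerate = all(len(s) in (0, c) for s in row_sets)
    if degenerate:
        warnings.warn(
            "matrix admits a unique fixed-fixed configuration; returned unchanged",
            RuntimeWarning,
            stacklevel=2,
        )
        return matrix._replace(m.copy())
    _curveball_trades(row_sets, burn_in, rng)
    return matrix._replace(_sets_to_cells(row_sets, (r, c)))


def ff_ensemble(
    matrix: PresenceAbsenceMatrix,
    n_draws: int,
    rng: np.random.Generator,
    burn_in: int | None = None,
    thin: int | None = None,
):
    """Yield ``n_draws`` fixed-fixed matrices from one curveball chain.

    The chain burns in once and then emits a draw every ``thin``
    trades (default 10*(rows+cols)), which is far cheaper than
    restarting the burn-in for every ensemble member.
    """
    m = matrix.cells
    r, c = m.shape
    if burn_in is None:
        burn_in = 1000 * (r + c)
    if thin is None:
        thin = 10 * (r + c)
    row_sets = [set(np.flatnonzero(m[i]).tolist()) for i in range(r)]
    degenerate = all(len(s) in (0, c) for s in row_sets)
    if degenerate:
        warnings.warn(
            "matrix admits a unique fixed-fixed configuration; ensemble is constant",
            RuntimeWarning,
            stacklevel=2,
        )
        for _ in range(n_draws):
            yield matrix._replace(m.copy())
        return
    _curveball_trades(row_sets, burn_in, rng)
    for _ in range(n_draws):
        _curveball_trades(row_sets, thin, rng)
        yield matrix._replace(_sets_to_cells(row_sets, (r, c)))


_NULL_MODELS = ("EE", "CC", "FF")


def nestedness_significance(
    matrix: PresenceAbsenceMatrix,
    null_model: str = "FF",
    ensemble_size: int = 1000,
    adaptive: bool = False,
    rng: np.random.Generator | None = None,
    burn_in: int | None = None,
    thin: int | None = None,
    adaptive_cap: int = 10_000,
    adaptive_block: int = 100,
    ci_width: float = 0.02,
) -> NestednessResult:
    """Monte-Carlo NODF significance under one null model.

    p = (1 + #{null NODF >= observed}) / (1 + N), one-sided toward
    nestedness; a large p marks an antinested matrix.  In adaptive
    mode the ensemble grows in blocks until a bootstrap 95% interval
    on p is narrower than ``ci_width`` (capped at ``adaptive_cap``).
    """
    null_model = null_model.upper()
    if null_model not in _NULL_MODELS:
        raise ValueError(f"null_model must be one of {_NULL_MODELS}")
    if rng is None:
        rng = np.random.default_rng()
    if not adaptive and ensemble_size < 100:
        raise ValueError("ensemble_size must be >= 100 (or use adaptive mode)")
    observed = compute_nodf(matrix)

    def _draws(k: int) -> list[float]:
        if null_model == "FF":
            return [
                _nodf_raw(nm.cells)
                for nm in ff_ensemble(matrix, k, rng, burn_in=burn_in, thin=thin)
            ]
        fn = null_ee if null_model == "EE" else null_cc
        return [_nodf_raw(fn(matrix, rng).cells) for _ in range(k)]

    if not adaptive:
        null_vals = np.array(_draws(ensemble_size))
    else:
        vals: list[float] = []
        while True:
            vals.extend(_draws(adaptive_block))
            arr = np.array(vals)
            n_boot = 200
            idx = rng.integers(0, len(arr), size=(n_boot, len(arr)))
            p_boot = (1.0 + (arr[idx] >= observed).sum(axis=1)) / (1.0 + len(arr))
            lo, hi = np.percentile(p_boot, [2.5, 97.5])
            if hi - lo < ci_width or len(arr) >= adaptive_cap:
                break
        null_vals = np.array(vals)

    n_ens = len(null_vals)
    p_upper = (1.0 + int((null_vals >= observed).sum())) / (1.0 + n_ens)
    p_low = (1.0 + int((null_vals <= observed).sum())) / (1.0 + n_ens)
    return NestednessResult(
        nodf=observed,
        null_model=null_model,
        ensemble_size=n_ens,
        p_value=p_upper,
        p_lower=p_low,
        null_mean=float(null_vals.mean()),
        null_sd=float(null_vals.std(ddof=0)),
    )


# ---------------------------------------------------------------------------
# portion-level nestedness
# ---------------------------------------------------------------------------


def _portion_nodf(sub: np.ndarray) -> float:
    """NODF of one column subset after the portion-procedure steps.

    All-zero rows are deleted; a submatrix filled wholly by 1 scores 0
    by convention; otherwise rows and columns are ordered by
    decreasing marginal totals (which does not change NODF, only the
    canonical presentation) and NODF computed.
    """
    keep = sub.sum(axis=1) > 0
    sub = sub[keep]
    if sub.size == 0 or sub.all():
        return 0.0
    order_r = np.argsort(-sub.sum(axis=1), kind="stable")
    order_c = np.argsort(-sub.sum(axis=0), kind="stable")
    return _nodf_raw(sub[order_r][:, order_c])


def _histogram(samples: np.ndarray, bins: int = 50) -> np.ndarray:
    counts, edges = np.histogram(samples, bins=bins, range=(0.0, 100.0))
    dens = counts.astype(float)
    if dens.max() > 0:
        dens = dens / dens.max()  # density scaled to maximum of one
    return np.column_stack([edges[:-1], edges[1:], dens])


def sample_portions(
    matrix: PresenceAbsenceMatrix,
    n_iterations: int,
    rng: np.random.Generator | None = None,
    bins: int = 50,
) -> PortionSamplingResult:
    """NODF distribution over random island subsets.

    Each iteration draws a subset size n uniformly from
    {3, ..., columns - 1}, draws n distinct columns, and scores the
    submatrix per the portion procedure.  Requires at least 4 columns
    (otherwise no valid n exists).
    """
    c = matrix.shape[1]
    if c < 4:
        raise ValueError("portion sampling needs a matrix with >= 4 columns")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    m = matrix.cells
    samples = np.empty(n_iterations)
    for it in range(n_iterations):
        n = int(rng.integers(3, c))  # uniform on {3, ..., c-1}
        cols = rng.choice(c, size=n, replace=False)
        samples[it] = _portion_nodf(m[:, cols])
    return PortionSamplingResult(
        n_iterations=n_iterations,
        nodf_samples=samples,
        nodf_max=float(samples.max()),
        histogram=_histogram(samples, bins),
    )


def enumerate_portions(
    matrix: PresenceAbsenceMatrix, cap: int = 2**20, bins: int = 50
) -> PortionSamplingResult:
    """Exact companion to :func:`sample_portions`: scores every column
    subset of size 3 ... columns-1.  Refuses when 2**columns exceeds
    ``cap``; use sampling for larger matrices."""
    c = matrix.shape[1]
    if c < 4:
        raise ValueError("portion enumeration needs a matrix with >= 4 columns")
    if 2**c > cap:
        raise ValueError(
            f"2^{c} column subsets exceed the cap {cap}; use sample_portions instead"
        )
    m = matrix.cells
    vals = [
        _portion_nodf(m[:, list(cols)])
        for size in range(3, c)
        for cols in itertools.combinations(range(c), size)
    ]
    samples = np.array(vals)
    return PortionSamplingResult(
        n_iterations=len(samples),
        nodf_samples=samples,
        nodf_max=float(samples.max()),
        histogram=_histogram(samples, bins),
        exhaustive=True,
    )
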