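"""Minimum-RSS threshold search, AIC selection, and model fitting.

Every candidate SAR form is linear in its coefficients once the break
points are fixed, so fitting proceeds in two layers:

* conditional least squares given thresholds
  (:func:`fit_given_thresholds`) -- ordinary least squares per
  segment for the discontinuous forms, a hinge regression
  ``logS ~ 1 + max(0, logA - T1)`` for the left-horizontal forms;
* a search over candidate thresholds that keeps the minimum-RSS fit.
  Continuous break points (the left-horizontal hinges) move the RSS
  as they slide between data points, so they are searched on a fine
  grid (default step 0.001 log10 units).  Discontinuous break points
  only matter through the induced partition, so their candidates are
  the observed log-area values themselves.

Model selection uses AIC = 2K - 2 logL with the Gaussian profile
log-likelihood logL = -(n/2)(ln 2pi + ln(RSS/n) + 1); K counts
coefficients + thresholds + the residual-variance parameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sar_models import (
    ALL_FORMS,
    MODEL_SPECS,
    ModelForm,
    SARDataset,
    SARModelSpec,
    SARParams,
    count_parameters,
    evaluate_model,
)

__all__ = [
    "SearchSettings",
    "SARFit",
    "NoFit",
    "InfeasibleThresholdError",
    "ModelSelectionTable",
    "fit_given_thresholds",
    "search_thresholds",
    "search_one_threshold_continuous",
    "search_one_threshold_discontinuous",
    "search_two_thresholds",
    "continuous_grid",
    "two_slope_candidates",
    "log_likelihood",
    "select_model",
    "run_sie_analysis",
]

_RSS_FLOOR = 1e-300
_VAR_TOL = 1e-12


class InfeasibleThresholdError(ValueError):
    """Signals that a candidate threshold leaves a segment undersized.

    Searches catch this (or pre-filter) and skip the candidate; it is
    an error only when raised from a direct :func:`fit_given_thresholds`
    call.
    """


@dataclass(frozen=True)
class SearchSettings:
    """Tunables for the threshold searches.

    grid_step is the increment for continuous break points, in log10
    area units; min_segment_points is the smallest number of
    observations a segment may hold (3 allows a line plus one residual
    degree of freedom).  Ties in RSS are broken toward the smallest
    threshold(s).
    """

    grid_step: float = 0.001
    min_segment_points: int = 3
    rss_floor: float = _RSS_FLOOR
    # RSS below rss_rel_floor * TSS is numerically indistinguishable from
    # a perfect fit (double-precision cancellation noise); such fits share
    # a common floored likelihood so AIC falls back to the K penalty
    rss_rel_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.min_segment_points < 2:
            raise ValueError("min_segment_points must be >= 2")


@dataclass
class SARFit:
    """One fitted SAR model: parameters, RSS, likelihood and AIC."""

    spec: SARModelSpec
    params: SARParams
    rss: float
    n: int
    logL: float
    K: int
    aic: float
    rss_floored: bool = False
    n_candidates: int | None = None

    @property
    def form(self) -> ModelForm:
        return self.spec.form


@dataclass
class NoFit:
    """Explicit no-fit marker returned when no candidate is feasible."""

    spec: SARModelSpec
    reason: str

    @property
    def form(self) -> ModelForm:
        return self.spec.form


def log_likelihood(rss: float, n: int, rss_floor: float = _RSS_FLOOR) -> float:
    """Gaussian profile log-likelihood of a least-squares fit.

    With the MLE variance sigma^2 = RSS/n,
    logL = -(n/2) (ln 2pi + ln(RSS/n) + 1).  A perfect fit (RSS = 0)
    is floored at ``rss_floor`` to keep the logarithm finite.
    """
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
    if rss < rss_floor:
        warnings.warn(
            f"RSS {rss:g} below floor {rss_floor:g}; flooring before log-likelihood",
            RuntimeWarning,
            stacklevel=2,
        )
        rss = rss_floor
    return -(n / 2.0) * (math.log(2.0 * math.pi) + math.log(rss / n) + 1.0)


# ---------------------------------------------------------------------------
# prefix-sum workspace: O(1) segment OLS and vectorised hinge regression
# ---------------------------------------------------------------------------


class _Workspace:
    """Data sorted by log-area with prefix sums for O(1) segment OLS."""

    def __init__(self, data: SARDataset):
        order = np.argsort(data.log_area, kind="stable")
        self.x = data.log_area[order]
        self.y = data.log_richness[order]
        self.n = len(self.x)
        z = np.zeros(1)
        self.px = np.concatenate([z, np.cumsum(self.x)])
        self.py = np.concatenate([z, np.cumsum(self.y)])
        self.pxx = np.concatenate([z, np.cumsum(self.x * self.x)])
        self.pyy = np.concatenate([z, np.cumsum(self.y * self.y)])
        self.pxy = np.concatenate([z, np.cumsum(self.x * self.y)])
        self.tss = max(float(self.pyy[-1] - self.py[-1] ** 2 / self.n), 0.0)

    def n_below(self, t: float | np.ndarray) -> int | np.ndarray:
        """Number of observations with log-area <= t."""
        return np.searchsorted(self.x, t, side="right")

    def seg_rss(self, i, j):
        """RSS of the per-segment OLS line over sorted points [i, j).

        Vectorised over equal-shaped index arrays.  A segment with no
        spread in x gets slope 0 and intercept mean(y).
        """
        i = np.asarray(i)
        j = np.asarray(j)
        m = (j - i).astype(float)
        sx = self.px[j] - self.px[i]
        sy = self.py[j] - self.py[i]
        sxx = self.pxx[j] - self.pxx[i]
        syy = self.pyy[j] - self.pyy[i]
        sxy = self.pxy[j] - self.pxy[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            sxx_c = sxx - sx * sx / m
            syy_c = syy - sy * sy / m
            sxy_c = sxy - sx * sy / m
            slope = np.where(sxx_c > _VAR_TOL, sxy_c / np.where(sxx_c > 0, sxx_c, 1.0), 0.0)
        rss = syy_c - slope * sxy_c
        return np.maximum(rss, 0.0)

    def seg_line(self, i: int, j: int) -> tuple[float, float, float]:
        """(intercept, slope, rss) of the OLS line over sorted [i, j)."""
        m = j - i
        sx = self.px[j] - self.px[i]
        sy = self.py[j] - self.py[i]
        sxx_c = (self.pxx[j] - self.pxx[i]) - sx * sx / m
        sxy_c = (self.pxy[j] - self.pxy[i]) - sx * sy / m
        slope = sxy_c / sxx_c if sxx_c > _VAR_TOL else 0.0
        intercept = (sy - slope * sx) / m
        rss = float(self.seg_rss(np.array([i]), np.array([j]))[0])
        return intercept, slope, rss

    def hinge_rss(self, t, k: int):
        """RSS of ``y ~ 1 + max(0, x - T)`` over the first k sorted points.

        Vectorised over an array of thresholds ``t``.  Below T the
        predictor vanishes, so the fit is a plateau c1 continuing into
        a line of slope z1 hinged at T.
        """
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.x[:k], t, side="right")
        m = (k - idx).astype(float)
        sx_w = self.px[k] - self.px[idx]
        sy_w = self.py[k] - self.py[idx]
        sum_h = sx_w - m * t
        sum_h2 = (self.pxx[k] - self.pxx[idx]) - 2.0 * t * sx_w + m * t * t
        sum_hy = (self.pxy[k] - self.pxy[idx]) - t * sy_w
        sy = self.py[k]
        syy_c = self.pyy[k] - sy * sy / k
        shh_c = sum_h2 - sum_h * sum_h / k
        shy_c = sum_hy - sum_h * sy / k
        with np.errstate(invalid="ignore", divide="ignore"):
            slope = np.where(shh_c > _VAR_TOL, shy_c / np.where(shh_c > 0, shh_c, 1.0), 0.0)
        rss = syy_c - slope * shy_c
        return np.maximum(rss, 0.0)

    def hinge_line(self, t: float, k: int) -> tuple[float, float, float]:
        """(c1, z1, rss) of the hinge fit over the first k sorted points."""
        rss = float(self.hinge_rss(np.array([t]), k)[0])
        idx = int(np.searchsorted(self.x[:k], t, side="right"))
        m = k - idx
        sum_h = (self.px[k] - self.px[idx]) - m * t
        sum_h2 = (self.pxx[k] - self.pxx[idx]) - 2.0 * t * (self.px[k] - self.px[idx]) + m * t * t
        sum_hy = (self.pxy[k] - self.pxy[idx]) - t * (self.py[k] - self.py[idx])
        sy = self.py[k]
        shh_c = sum_h2 - sum_h * sum_h / k
        shy_c = sum_hy - sum_h * sy / k
        slope = shy_c / shh_c if shh_c > _VAR_TOL else 0.0
        intercept = (sy - slope * sum_h) / k
        return intercept, slope, rss


def _make_fit(
    spec: SARModelSpec,
    params: SARParams,
    rss: float,
    n: int,
    settings: SearchSettings,
    n_candidates: int | None = None,
    tss: float = 0.0,
) -> SARFit:
    floor = max(settings.rss_floor, settings.rss_rel_floor * tss)
    floored = rss < floor
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ll = log_likelihood(rss, n, rss_floor=floor)
    k = count_parameters(spec)
    return SARFit(
        spec=spec,
        params=params,
        rss=float(rss),
        n=n,
        logL=ll,
        K=k,
        aic=2.0 * k - 2.0 * ll,
        rss_floored=floored,
        n_candidates=n_candidates,
    )


def fit_given_thresholds(
    spec: SARModelSpec,
    data: SARDataset,
    thresholds: Sequence[float] = (),
    settings: SearchSettings | None = None,
) -> SARFit:
    """Least-squares coefficients for one form at fixed break points.

    The discontinuous forms fit an independent OLS line per induced
    segment; the left-horizontal forms fit the hinge regression (over
    all points for one threshold; over the points at or below T2, plus
    an independent upper line, for two).  Raises
    :class:`InfeasibleThresholdError` if any induced segment holds
    fewer than ``min_segment_points`` observations.
    """
    settings = settings or SearchSettings()
    thresholds = tuple(float(t) for t in thresholds)
    if len(thresholds) != spec.n_thresholds:
        raise ValueError(
            f"{spec.form.value} needs {spec.n_thresholds} thresholds, got {len(thresholds)}"
        )
    if len(thresholds) == 2 and not thresholds[0] < thresholds[1]:
        raise ValueError("thresholds must be strictly increasing")
    ws = _Workspace(data)
    return _fit_on_workspace(spec, ws, thresholds, settings)


def _fit_on_workspace(
    spec: SARModelSpec,
    ws: _Workspace,
    thresholds: tuple[float, ...],
    settings: SearchSettings,
    n_candidates: int | None = None,
) -> SARFit:
    n = ws.n
    mp = settings.min_segment_points
    form = spec.form

    def _need(*counts: int) -> None:
        if any(c < mp for c in counts):
            raise InfeasibleThresholdError(
                f"{form.value} at T={thresholds}: segment sizes {counts} < {mp}"
            )

    if form is ModelForm.POWER:
        _need(n)
        c1, z1, rss = ws.seg_line(0, n)
        params = SARParams((c1,), (z1,))
    elif form is ModelForm.LEFT_HORIZONTAL_1:
        (t1,) = thresholds
        i = int(ws.n_below(t1))
        _need(i, n - i)
        c1, z1, rss = ws.hinge_line(t1, n)
        params = SARParams((c1,), (z1,), (t1,))
    elif form is ModelForm.TWO_SLOPE:
        (t1,) = thresholds
        i = int(ws.n_below(t1))
        _need(i, n - i)
        c1, z1, r1 = ws.seg_line(0, i)
        c2, z2, r2 = ws.seg_line(i, n)
        rss = r1 + r2
        params = SARParams((c1, c2), (z1, z2), (t1,))
    elif form is ModelForm.LEFT_HORIZONTAL_2:
        t1, t2 = thresholds
        i = int(ws.n_below(t1))
        j = int(ws.n_below(t2))
        _need(i, j - i, n - j)
        c1, z1, r1 = ws.hinge_line(t1, j)
        b0, z2, r2 = ws.seg_line(j, n)
        # the plateau term c1 is unconditional in the model equation, so
        # the upper line b0 + z2*x is stored as c2 = b0 - c1
        rss = r1 + r2
        params = SARParams((c1, b0 - c1), (z1, z2), (t1, t2))
    elif form is ModelForm.THREE_SLOPE:
        t1, t2 = thresholds
        i = int(ws.n_below(t1))
        j = int(ws.n_below(t2))
        _need(i, j - i, n - j)
        c1, z1, r1 = ws.seg_line(0, i)
        c2, z2, r2 = ws.seg_line(i, j)
        c3, z3, r3 = ws.seg_line(j, n)
        rss = r1 + r2 + r3
        params = SARParams((c1, c2, c3), (z1, z2, z3), (t1, t2))
    else:  # pragma: no cover
        raise ValueError(f"unknown form {form}")
    # the prefix-sum rss steers the search; the reported value is
    # recomputed from residuals, which is immune to cancellation noise
    resid = ws.y - evaluate_model(spec, params, ws.x)
    rss = float(resid @ resid)
    return _make_fit(spec, params, rss, n, settings, n_candidates, tss=ws.tss)


# ---------------------------------------------------------------------------
# threshold searches
# ---------------------------------------------------------------------------


def continuous_grid(lo: float, hi: float, step: float) -> np.ndarray:
    """Inclusive grid from lo to hi in increments of ``step``.

    The endpoints are always present; interior points are lo + k*step.
    """
    if hi < lo:
        raise ValueError("hi must be >= lo")
    n_steps = int(math.floor((hi - lo) / step + 1e-9))
    grid = lo + step * np.arange(n_steps + 1)
    grid = grid[grid <= hi + 1e-12]
    if hi - grid[-1] > 1e-12:
        grid = np.append(grid, hi)
    else:
        grid[-1] = min(grid[-1], hi)
    return grid


def two_slope_candidates(data: SARDataset) -> np.ndarray:
    """Candidate break points for the discontinuous one-threshold form.

    Break points between adjacent data points do not change the RSS,
    so candidates are the distinct observed log-area values whose
    partition leaves both segments non-empty: n distinct values yield
    n - 1 candidates (1668 islands with distinct areas -> 1667).
    """
    vals = np.unique(data.log_area)
    return vals[:-1]


def search_one_threshold_continuous(
    data: SARDataset, settings: SearchSettings | None = None
) -> SARFit | NoFit:
    """Grid search for the left-horizontal (one threshold) form."""
    settings = settings or SearchSettings()
    spec = MODEL_SPECS[ModelForm.LEFT_HORIZONTAL_1]
    ws = _Workspace(data)
    grid = continuous_grid(ws.x[0], ws.x[-1], settings.grid_step)
    idx = np.searchsorted(ws.x, grid, side="right")
    feas = (idx >= settings.min_segment_points) & (
        ws.n - idx >= settings.min_segment_points
    )
    if not feas.any():
        return NoFit(spec, "no feasible grid candidate")
    cand = grid[feas]
    rss = ws.hinge_rss(cand, ws.n)
    best = float(cand[int(np.argmin(rss))])  # first minimum = smallest T1
    return _fit_on_workspace(spec, ws, (best,), settings, n_candidates=len(grid))


def search_one_threshold_discontinuous(
    data: SARDataset, settings: SearchSettings | None = None
) -> SARFit | NoFit:
    """Enumeration search for the two-slope form."""
    settings = settings or SearchSettings()
    spec = MODEL_SPECS[ModelForm.TWO_SLOPE]
    ws = _Workspace(data)
    cand = two_slope_candidates(data)
    n_cand = len(cand)
    if n_cand == 0:
        return NoFit(spec, "fewer than two distinct areas")
    idx = np.searchsorted(ws.x, cand, side="right")
    feas = (idx >= settings.min_segment_points) & (
        ws.n - idx >= settings.min_segment_points
    )
    if not feas.any():
        return NoFit(spec, "no feasible candidate partition")
    cand = cand[feas]
    idx = idx[feas]
    rss = ws.seg_rss(np.zeros_like(idx), idx) + ws.seg_rss(idx, np.full_like(idx, ws.n))
    best = float(cand[int(np.argmin(rss))])
    return _fit_on_workspace(spec, ws, (best,), settings, n_candidates=n_cand)


def search_two_thresholds(
    form: ModelForm | SARModelSpec,
    data: SARDataset,
    settings: SearchSettings | None = None,
) -> SARFit | NoFit:
    """Full two-level minimum-RSS search for the two-threshold forms.

    For the three-slope form both break points range over the observed
    log-area values (T1 < T2).  For the left-horizontal form with two
    thresholds the discontinuous T2 ranges over observed values while
    the continuous T1 is searched on the grid over [min logA, T2).
    The global minimum-RSS feasible pair is returned, which the
    record-the-inner-minimum two-pass procedure also attains; RSS ties
    break toward the lexicographically smallest (T1, T2).
    """
    settings = settings or SearchSettings()
    spec = form if isinstance(form, SARModelSpec) else MODEL_SPECS[form]
    if spec.form not in (ModelForm.THREE_SLOPE, ModelForm.LEFT_HORIZONTAL_2):
        raise ValueError(f"{spec.form.value} does not have two thresholds")
    ws = _Workspace(data)
    mp = settings.min_segment_points
    n = ws.n
    vals = np.unique(ws.x)
    n_candidates = 0
    best_rss = math.inf
    best_t: tuple[float, float] | None = None

    if spec.form is ModelForm.THREE_SLOPE:
        idx_vals = np.searchsorted(ws.x, vals, side="right")
        for a in range(len(vals) - 1):
            i = idx_vals[a]
            if i < mp or n - i < 2 * mp:
                continue
            t2s = vals[a + 1 :]
            js = idx_vals[a + 1 :]
            ok = (js - i >= mp) & (n - js >= mp)
            n_candidates += len(t2s)
            if not ok.any():
                continue
            t2s, js = t2s[ok], js[ok]
            rss = (
                ws.seg_rss(np.zeros_like(js), np.full_like(js, i))
                + ws.seg_rss(np.full_like(js, i), js)
                + ws.seg_rss(js, np.full_like(js, n))
            )
            b = int(np.argmin(rss))
            r = float(rss[b])
            t_pair = (float(vals[a]), float(t2s[b]))
            if r < best_rss or (r == best_rss and best_t is not None and t_pair < best_t):
                best_rss, best_t = r, t_pair
    else:  # left_horizontal_2
        for t2 in vals:
            j = int(ws.n_below(t2))
            if n - j < mp or j < 2 * mp:
                continue
            grid = continuous_grid(ws.x[0], float(t2), settings.grid_step)
            grid = grid[grid < t2]
            if len(grid) == 0:
                continue
            idx = np.searchsorted(ws.x, grid, side="right")
            ok = (idx >= mp) & (j - idx >= mp)
            n_candidates += len(grid)
            if not ok.any():
                continue
            g = grid[ok]
            rss = ws.hinge_rss(g, j) + float(
                ws.seg_rss(np.array([j]), np.array([n]))[0]
            )
            b = int(np.argmin(rss))
            r = float(rss[b])
            t_pair = (float(g[b]), float(t2))
            if r < best_rss or (r == best_rss and best_t is not None and t_pair < best_t):
                best_rss, best_t = r, t_pair

    if best_t is None:
        return NoFit(spec, "no feasible threshold pair")
    return _fit_on_workspace(spec, ws, best_t, settings, n_candidates=n_candidates)


def search_thresholds(
    form: ModelForm, data: SARDataset, settings: SearchSettings | None = None
) -> SARFit | NoFit:
    """Dispatch the appropriate minimum-RSS search for one form."""
    settings = settings or SearchSettings()
    if form is ModelForm.POWER:
        try:
            return fit_given_thresholds(MODEL_SPECS[form], data, (), settings)
        except InfeasibleThresholdError as exc:
            return NoFit(MODEL_SPECS[form], str(exc))
    if form is ModelForm.LEFT_HORIZONTAL_1:
        return search_one_threshold_continuous(data, settings)
    if form is ModelForm.TWO_SLOPE:
        return search_one_threshold_discontinuous(data, settings)
    return search_two_thresholds(form, data, settings)


# ---------------------------------------------------------------------------
# AIC model selection
# ---------------------------------------------------------------------------


@dataclass
class ModelSelectionTable:
    """AIC comparison across the candidate SAR forms.

    delta_aic is AIC - min AIC; weight the Akaike weight
    exp(-dAIC/2) normalised over the candidates; best the minimum-AIC
    form.  Forms whose search found no feasible fit appear in
    ``no_fit`` only.
    """

    fits: dict[ModelForm, SARFit]
    delta_aic: dict[ModelForm, float]
    weight: dict[ModelForm, float]
    best: ModelForm
    no_fit: dict[ModelForm, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Flat table shaped like one taxon block of a model-selection report."""
        rows = []
        for form in ALL_FORMS:
            if form not in self.fits:
                continue
            f = self.fits[form]
            c = f.params.intercepts
            z = f.params.slopes
            t = f.params.thresholds
            rows.append(
                {
                    "model": form.value,
                    "c1": c[0],
                    "c2": c[1] if len(c) > 1 else np.nan,
                    "c3": c[2] if len(c) > 2 else np.nan,
                    "z1": z[0],
                    "z2": z[1] if len(z) > 1 else np.nan,
                    "z3": z[2] if len(z) > 2 else np.nan,
                    "T1": t[0] if len(t) > 0 else np.nan,
                    "T2": t[1] if len(t) > 1 else np.nan,
                    "rss": f.rss,
                    "K": f.K,
                    "logL": f.logL,
                    "AIC": f.aic,
                    "delta_AIC": self.delta_aic[form],
                    "weight": self.weight[form],
                }
            )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        out: dict = {"best_model": self.best.value, "models": {}}
        for form, f in self.fits.items():
            out["models"][form.value] = {
                "intercepts": list(f.params.intercepts),
                "slopes": list(f.params.slopes),
                "thresholds": list(f.params.thresholds),
                "rss": f.rss,
                "n": f.n,
                "logL": f.logL,
                "K": f.K,
                "aic": f.aic,
                "delta_aic": self.delta_aic[form],
                "weight": self.weight[form],
                "rss_floored": f.rss_floored,
                "n_candidates": f.n_candidates,
            }
        if self.no_fit:
            out["no_fit"] = {form.value: r for form, r in self.no_fit.items()}
        return out


def select_model(fits: Iterable[SARFit | NoFit]) -> ModelSelectionTable:
    """Rank fits by AIC: delta AIC, Akaike weights and the best form."""
    usable: dict[ModelForm, SARFit] = {}
    dropped: dict[ModelForm, str] = {}
    for f in fits:
        if isinstance(f, NoFit):
            dropped[f.form] = f.reason
            continue
        if not math.isfinite(f.aic):
            warnings.warn(
                f"excluding {f.form.value}: non-finite AIC", RuntimeWarning, stacklevel=2
            )
            dropped[f.form] = "non-finite AIC"
            continue
        usable[f.form] = f
    if len(usable) < 2:
        raise ValueError("model selection needs at least two finite-AIC fits")
    aic_min = min(f.aic for f in usable.values())
    delta = {form: f.aic - aic_min for form, f in usable.items()}
    raw = {form: math.exp(-d / 2.0) for form, d in delta.items()}
    total = sum(raw.values())
    weight = {form: r / total for form, r in raw.items()}
    best = min(usable, key=lambda form: (usable[form].aic, ALL_FORMS.index(form)))
    return ModelSelectionTable(
        fits=usable, delta_aic=delta, weight=weight, best=best, no_fit=dropped
    )


def run_sie_analysis(
    data: SARDataset, settings: SearchSettings | None = None
) -> ModelSelectionTable:
    """Fit all five SAR forms with their searches and rank them by AIC."""
    settings = settings or SearchSettings()
    fits = []
    for form in ALL_FORMS:
        result = search_thresholds(form, data, settings)
        if isinstance(result, NoFit):
            warnings.warn(
                f"{form.value}: {result.reason}; dropped from selection",
                RuntimeWarning,
                stacklevel=2,
            )
        fits.append(result)
    return select_model(fits)
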