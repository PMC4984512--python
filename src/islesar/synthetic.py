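"""Synthetic SAR datasets and presence-absence matrices with known truth.

The generators emulate the statistical shape of an archipelago-scale
herpetofauna survey -- island areas spanning ~10 orders of magnitude
with many tiny islands, richness following one of the five SAR forms
with Gaussian noise in log space, and binary occurrence matrices with
controllable fill and nestedness -- so that every pipeline stage can
be exercised against a known ground truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nestedness import PresenceAbsenceMatrix
from .sar_models import (
    MODEL_SPECS,
    ModelForm,
    SARDataset,
    SARModelSpec,
    SARParams,
    evaluate_model,
    transform_richness,
)

__all__ = [
    "SARSimConfig",
    "MatrixSimConfig",
    "simulate_sar",
    "simulate_matrix",
]


@dataclass
class SARSimConfig:
    """Configuration for a synthetic species-area dataset.

    Log areas are drawn on ``log_area_range`` (default -4.4 .. 5.0,
    roughly 3.9e-5 to 1.1e5 km^2, ten orders of magnitude).  The
    response is the true model's prediction plus Gaussian noise of sd
    ``noise_sd`` in log-richness units.  With ``integerize`` the
    continuous response is converted to integer richness
    (round(10**logS), floored at 0) and the zero-island log(S+1) rule
    reapplied, reproducing the discreteness of real survey counts.
    ``area_distribution`` is ``uniform`` in log area by default; the
    ``log_skewed`` option concentrates islands at the small end
    (truncated exponential in log area), as real island-size
    distributions do.
    """

    n_islands: int
    true_form: ModelForm
    true_params: SARParams
    log_area_range: tuple[float, float] = (-4.4, 5.0)
    noise_sd: float = 0.05
    integerize: bool = False
    seed: int = 0
    area_distribution: str = "uniform"

    def __post_init__(self) -> None:
        lo, hi = self.log_area_range
        if not lo < hi:
            raise ValueError("log_area_range must satisfy low < high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.area_distribution not in ("uniform", "log_skewed"):
            raise ValueError("area_distribution must be 'uniform' or 'log_skewed'")


def simulate_sar(config: SARSimConfig) -> SARDataset:
    """Draw a reproducible SAR dataset from a known generating model."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.log_area_range
    n = config.n_islands
    if config.area_distribution == "uniform":
        log_area = rng.uniform(lo, hi, size=n)
    else:
        # truncated exponential from the small end: density highest near lo
        span = hi - lo
        draws = rng.exponential(scale=span / 3.0, size=2 * n + 16)
        draws = draws[draws < span][:n]
        while len(draws) < n:
            extra = rng.exponential(scale=span / 3.0, size=n)
            draws = np.concatenate([draws, extra[extra < span]])[:n]
        log_area = lo + draws
    spec = MODEL_SPECS[config.true_form]
    mu = evaluate_model(spec, config.true_params, log_area)
    log_s = mu + rng.normal(0.0, config.noise_sd, size=n)
    if config.integerize:
        richness = np.maximum(np.round(10.0 ** log_s), 0.0).astype(int)
        return SARDataset.from_areas_richness(10.0 ** log_area, richness, taxon="synthetic")
    return SARDataset.from_log_values(log_area, log_s, taxon="synthetic")


@dataclass
class MatrixSimConfig:
    """Configuration for a synthetic presence-absence matrix.

    Structures: ``perfectly_nested`` builds a staircase with strictly
    decreasing distinct marginal totals (NODF 100 for square shapes);
    ``random_ee`` places presences uniformly at ``fill_target``
    percent; ``checkerboard`` alternates 0/1 so all row totals tie and
    all column totals tie (NODF 0 for even dimensions);
    ``noisy_nested`` flips each staircase cell independently with
    probability ``flip_prob``.
    """

    n_species: int
    n_islands: int
    structure: str = "perfectly_nested"
    fill_target: float = 30.0
    flip_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2 or self.n_islands < 2:
            raise ValueError("matrix dimensions must be >= 2")
        if self.structure not in (
            "perfectly_nested",
            "random_ee",
            "checkerboard",
            "noisy_nested",
        ):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.structure == "random_ee" and not 0.0 < self.fill_target < 100.0:
            raise ValueError("fill_target must be in (0, 100)")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")


def _staircase(r: int, c: int) -> np.ndarray:
    """Maximally nested step matrix: row i occupies the first c-i
    columns (floored at 1).  Marginal totals are strictly decreasing
    and distinct whenever the matrix is square."""
    cells = np.zeros((r, c), dtype=np.int8)
    for i in range(r):
        k = max(c - i, 1)
        cells[i, :k] = 1
    return cells


def simulate_matrix(config: MatrixSimConfig) -> PresenceAbsenceMatrix:
    """Draw a reproducible presence-absence matrix of the requested structure."""
    rng = np.random.default_rng(config.seed)
    r, c = config.n_species, config.n_islands
    if config.structure == "perfectly_nested":
        cells = _staircase(r, c)
    elif config.structure == "checkerboard":
        i, j = np.indices((r, c))
        cells = ((i + j) % 2).astype(np.int8)
    elif config.structure == "random_ee":
        total = int(round(config.fill_target / 100.0 * r * c))
        total = min(max(total, 1), r * c - 1)
        flat = np.zeros(r * c, dtype=np.int8)
        flat[rng.choice(r * c, size=total, replace=False)] = 1
        cells = flat.reshape(r, c)
    else:  # noisy_nested
        cells = _staircase(r, c)
        flips = rng.random((r, c)) < config.flip_prob
        cells = np.where(flips, 1 - cells, cells).astype(np.int8)
    return PresenceAbsenceMatrix.from_cells(cells)
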