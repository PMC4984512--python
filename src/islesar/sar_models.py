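"""Species-area model forms for small-island-effect (SIE) analysis.

The species-area relationship (SAR) is fitted in log-log space: the
response is log10 species richness, the predictor log10 island area
(km^2).  Five candidate forms are supported, from the classical
power law (a single line in log-log space) to piecewise forms with
one or two break points ("thresholds"), which is how the SIE -- a
regime on small islands where richness is weakly coupled to area --
is detected and delimited.

Segment membership at a threshold T follows half-open intervals:
the lower segment is ``logA <= T1``, the middle ``T1 < logA <= T2``
and the upper ``logA > T2``.  The two left-horizontal forms are
continuous at their first threshold (a flat plateau joined by a
hinge); the two-slope and three-slope forms allow discontinuities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "ModelForm",
    "SARModelSpec",
    "SARParams",
    "SARDataset",
    "MODEL_SPECS",
    "ALL_FORMS",
    "evaluate_model",
    "count_parameters",
    "transform_richness",
]


class ModelForm(str, Enum):
    """The five candidate SAR forms."""

    POWER = "power"
    TWO_SLOPE = "two_slope"
    LEFT_HORIZONTAL_1 = "left_horizontal_1"
    THREE_SLOPE = "three_slope"
    LEFT_HORIZONTAL_2 = "left_horizontal_2"


@dataclass(frozen=True)
class SARModelSpec:
    """Structural description of one SAR form.

    Attributes
    ----------
    form
        Which of the five forms this is.
    n_coefficients
        Number of fitted intercepts plus slopes (the c's and z's).
    n_thresholds
        Number of break points (the T's), 0-2.
    continuity
        Per-threshold flag; True where the prediction is continuous
        across the break point.
    """

    form: ModelForm
    n_coefficients: int
    n_thresholds: int
    continuity: tuple[bool, ...] = ()


MODEL_SPECS: dict[ModelForm, SARModelSpec] = {
    ModelForm.POWER: SARModelSpec(ModelForm.POWER, 2, 0, ()),
    ModelForm.TWO_SLOPE: SARModelSpec(ModelForm.TWO_SLOPE, 4, 1, (False,)),
    ModelForm.LEFT_HORIZONTAL_1: SARModelSpec(
        ModelForm.LEFT_HORIZONTAL_1, 2, 1, (True,)
    ),
    ModelForm.THREE_SLOPE: SARModelSpec(ModelForm.THREE_SLOPE, 6, 2, (False, False)),
    ModelForm.LEFT_HORIZONTAL_2: SARModelSpec(
        ModelForm.LEFT_HORIZONTAL_2, 4, 2, (True, False)
    ),
}

#: Fitting/selection order used throughout reports.
ALL_FORMS: tuple[ModelForm, ...] = (
    ModelForm.POWER,
    ModelForm.TWO_SLOPE,
    ModelForm.LEFT_HORIZONTAL_1,
    ModelForm.THREE_SLOPE,
    ModelForm.LEFT_HORIZONTAL_2,
)


@dataclass(frozen=True)
class SARParams:
    """Parameter set for one SAR form.

    ``intercepts`` holds c1[, c2[, c3]], ``slopes`` z1[, z2[, z3]] and
    ``thresholds`` T1[, T2] in log10-km^2 units.  The expected counts
    per form are validated against the spec on use.
    """

    intercepts: tuple[float, ...]
    slopes: tuple[float, ...]
    thresholds: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.thresholds) == 2 and not self.thresholds[0] < self.thresholds[1]:
            raise ValueError(
                f"thresholds must be strictly increasing, got {self.thresholds}"
            )


# intercept/slope counts per form (they are equal for all five forms)
_N_LINES = {
    ModelForm.POWER: 1,
    ModelForm.TWO_SLOPE: 2,
    ModelForm.LEFT_HORIZONTAL_1: 1,
    ModelForm.THREE_SLOPE: 3,
    ModelForm.LEFT_HORIZONTAL_2: 2,
}


def _check_params(spec: SARModelSpec, params: SARParams) -> None:
    n_lines = _N_LINES[spec.form]
    if len(params.intercepts) != n_lines or len(params.slopes) != n_lines:
        raise ValueError(
            f"{spec.form.value} expects {n_lines} intercept(s)/slope(s), got "
            f"{len(params.intercepts)}/{len(params.slopes)}"
        )
    if len(params.thresholds) != spec.n_thresholds:
        raise ValueError(
            f"{spec.form.value} expects {spec.n_thresholds} threshold(s), got "
            f"{len(params.thresholds)}"
        )


def evaluate_model(
    spec: SARModelSpec, params: SARParams, log_area: float | np.ndarray
) -> float | np.ndarray:
    """Predicted log10 richness at ``log_area`` under one SAR form.

    The piecewise forms are evaluated exactly as written, with bracket
    indicator terms: e.g. the left-horizontal form with one threshold is
    ``logS = c1 + [logA > T1] * z1 * (logA - T1)``, a plateau at c1
    joined continuously to a line of slope z1 at T1.  For the
    left-horizontal form with two thresholds the plateau intercept c1
    is an unconditional term, so above T2 the prediction is
    ``c1 + c2 + z2*logA``.
    """
    _check_params(spec, params)
    x = np.asarray(log_area, dtype=float)
    c, z, t = params.intercepts, params.slopes, params.thresholds
    form = spec.form
    if form is ModelForm.POWER:
        y = c[0] + z[0] * x
    elif form is ModelForm.LEFT_HORIZONTAL_1:
        y = c[0] + (x > t[0]) * z[0] * (x - t[0])
    elif form is ModelForm.TWO_SLOPE:
        y = np.where(x <= t[0], c[0] + z[0] * x, c[1] + z[1] * x)
    elif form is ModelForm.LEFT_HORIZONTAL_2:
        mid = (x > t[0]) & (x <= t[1])
        y = c[0] + mid * z[0] * (x - t[0]) + (x > t[1]) * (c[1] + z[1] * x)
    elif form is ModelForm.THREE_SLOPE:
        y = np.where(
            x <= t[0],
            c[0] + z[0] * x,
            np.where(x <= t[1], c[1] + z[1] * x, c[2] + z[2] * x),
        )
    else:  # pragma: no cover
        raise ValueError(f"unknown form {form}")
    if np.isscalar(log_area) or np.ndim(log_area) == 0:
        return float(y)
    return y


def count_parameters(spec: SARModelSpec) -> int:
    """Number of estimable parameters K for AIC.

    K counts the regression coefficients, the break points, and one
    residual-variance parameter.  For the five forms this gives
    3 (power), 6 (two-slope), 4 (left-horizontal 1), 9 (three-slope)
    and 7 (left-horizontal 2).
    """
    return spec.n_coefficients + spec.n_thresholds + 1


def transform_richness(
    richness: int | Sequence[int] | np.ndarray, plus_one_all: bool = False
) -> float | np.ndarray:
    """log10 transform of species richness with the zero-island rule.

    Islands with no species record are kept in the regression; their
    richness is transformed as log10(S + 1) = 0 (log 0 is undefined),
    while S >= 1 transforms as log10(S).  With ``plus_one_all`` the
    S + 1 shift is applied to every island instead (non-default).
    """
    s = np.asarray(richness, dtype=float)
    if np.any(s < 0):
        raise ValueError("richness must be non-negative")
    if plus_one_all:
        y = np.log10(s + 1.0)
    else:
        y = np.log10(np.maximum(s, 1.0))
    if np.ndim(richness) == 0:
        return float(y)
    return y


@dataclass
class SARDataset:
    """Paired log-area / log-richness observations for one taxon.

    ``log_richness`` is the regression response.  For observed data it
    is derived from integer richness by :func:`transform_richness`;
    synthetic data may carry a continuous response directly (richness
    is then 10**log_richness).
    """

    island_ids: list[str]
    area_km2: np.ndarray
    richness: np.ndarray
    log_area: np.ndarray = field(default=None)  # type: ignore[assignment]
    log_richness: np.ndarray = field(default=None)  # type: ignore[assignment]
    taxon: str = ""

    def __post_init__(self) -> None:
        self.area_km2 = np.asarray(self.area_km2, dtype=float)
        self.richness = np.asarray(self.richness, dtype=float)
        n = len(self.island_ids)
        if n < 1 or len(self.area_km2) != n or len(self.richness) != n:
            raise ValueError("island_ids, area_km2 and richness must share length >= 1")
        if np.any(self.area_km2 <= 0):
            raise ValueError("all areas must be positive")
        if np.any(self.richness < 0):
            raise ValueError("richness must be non-negative")
        if self.log_area is None:
            self.log_area = np.log10(self.area_km2)
        else:
            self.log_area = np.asarray(self.log_area, dtype=float)
        if self.log_richness is None:
            self.log_richness = transform_richness(self.richness)
        else:
            self.log_richness = np.asarray(self.log_richness, dtype=float)

    @classmethod
    def from_areas_richness(
        cls,
        area_km2: Sequence[float],
        richness: Sequence[int],
        island_ids: Sequence[str] | None = None,
        taxon: str = "",
        plus_one_all: bool = False,
    ) -> "SARDataset":
        area = np.asarray(area_km2, dtype=float)
        rich = np.asarray(richness)
        if island_ids is None:
            island_ids = [f"isl{i:05d}" for i in range(len(area))]
        return cls(
            island_ids=list(island_ids),
            area_km2=area,
            richness=rich.astype(float),
            log_richness=transform_richness(rich, plus_one_all=plus_one_all),
            taxon=taxon,
        )

    @classmethod
    def from_log_values(
        cls,
        log_area: Sequence[float],
        log_richness: Sequence[float],
        island_ids: Sequence[str] | None = None,
        taxon: str = "",
    ) -> "SARDataset":
        """Build a dataset directly from a continuous log-log sample."""
        la = np.asarray(log_area, dtype=float)
        ls = np.asarray(log_richness, dtype=float)
        if island_ids is None:
            island_ids = [f"isl{i:05d}" for i in range(len(la))]
        return cls(
            island_ids=list(island_ids),
            area_km2=10.0 ** la,
            richness=10.0 ** ls,
            log_area=la,
            log_richness=ls,
            taxon=taxon,
        )

    @property
    def n(self) -> int:
        return len(self.island_ids)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n
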