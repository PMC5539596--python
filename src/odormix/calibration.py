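"""Fitting the family model from sensory-panel data.

Two regressions assemble a :class:`~odormix.core.FamilyModel`:

1. the psychophysical law: ordinary least squares of panel intensity on
   ln(OAV), pooled across all odorants of the family (one line per family,
   not per odorant);
2. the mixture slope: through-origin least squares of the mixture's
   intensity on the sum of its unmixed constituents' intensities
   (s = Σxy / Σx²; zero summed intensity must map to zero mixture
   intensity, so the line is constrained through the origin by default).

The interaction coefficient follows as cosα = 2s² − 1. Ratings of 0 are
censored sub-threshold observations and are excluded from the law fit by
default (the law is fitted unclamped).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from .core import (
    FamilyModel,
    Odorant,
    PsychophysicalLaw,
    compute_oav,
    cos_alpha_from_slope,
)
from .registry import Registry

__all__ = [
    "SinglePanelRecord",
    "MixturePanelRecord",
    "LawFit",
    "SlopeFit",
    "CalibrationResult",
    "fit_psychophysical_law",
    "fit_mixture_slope",
    "calibrate_family",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SinglePanelRecord:
    """One panel rating of a single odorant at a known concentration."""

    odorant: str
    concentration: float
    oi: float

    def __post_init__(self) -> None:
        if not (self.concentration > 0):
            raise ValueError("concentration must be positive")
        if self.oi < 0:
            raise ValueError("odor intensity must be non-negative")


@dataclass(frozen=True)
class MixturePanelRecord:
    """Panel ratings of a mixture and of its unmixed constituents."""

    oi_components: Sequence[float]
    oi_mixture: float

    def __post_init__(self) -> None:
        if len(self.oi_components) < 2:
            raise ValueError("a mixture record needs at least two components")
        if any(o < 0 for o in self.oi_components) or self.oi_mixture < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def oi_sum(self) -> float:
        return float(sum(self.oi_components))


@dataclass(frozen=True)
class LawFit:
    """Fitted psychophysical law with OLS diagnostics."""

    law: PsychophysicalLaw
    residual_se: float
    r_squared: float
    n_used: int
    n_excluded: int
    per_odorant: Dict[str, Dict[str, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class SlopeFit:
    """Fitted mixture slope with diagnostics."""

    slope: float
    residual_se: float
    n: int
    intercept: float = 0.0
    through_origin: bool = True


@dataclass(frozen=True)
class CalibrationResult:
    model: FamilyModel
    law_fit: LawFit
    slope_fit: SlopeFit


def _ln_oav(record: SinglePanelRecord, registry: Registry) -> float:
    odorant = registry.get(record.odorant)
    return math.log(compute_oav(record.concentration, odorant))


def fit_psychophysical_law(
    records: Sequence[SinglePanelRecord],
    registry: Registry,
    include_zero_oi: bool = False,
) -> LawFit:
    """Pooled OLS fit of intensity on ln(OAV) across family members.

    Records with an intensity of exactly 0 are censored (the panel cannot
    report how far below threshold a stimulus is) and excluded unless
    ``include_zero_oi``. At least two distinct ln(OAV) values must remain.
    """
    if include_zero_oi:
        used = list(records)
        n_excluded = 0
    else:
        used = [r for r in records if r.oi > 0]
        n_excluded = len(records) - len(used)
        if n_excluded:
            logger.info("excluded %d sub-threshold (OI = 0) records", n_excluded)

    x = np.array([_ln_oav(r, registry) for r in used])
    y = np.array([r.oi for r in used])
    if len(np.unique(x)) < 2:
        raise ValueError(
            "degenerate fit: need at least 2 records with distinct ln(OAV)"
        )
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    dof = max(len(x) - 2, 1)
    residual_se = float(np.sqrt(np.sum(resid**2) / dof))

    per_odorant: Dict[str, Dict[str, float]] = {}
    for name in sorted({r.odorant for r in used}):
        xs = np.array([_ln_oav(r, registry) for r in used if r.odorant == name])
        ys = np.array([r.oi for r in used if r.odorant == name])
        if len(np.unique(xs)) >= 2:
            sub = stats.linregress(xs, ys)
            per_odorant[name] = {
                "k": float(sub.slope),
                "b": float(sub.intercept),
                "r_squared": float(sub.rvalue**2),
                "n": int(len(xs)),
            }

    return LawFit(
        law=PsychophysicalLaw(k=float(res.slope), b=float(res.intercept)),
        residual_se=residual_se,
        r_squared=float(res.rvalue**2),
        n_used=len(used),
        n_excluded=n_excluded,
        per_odorant=per_odorant,
    )


def fit_mixture_slope(
    records: Sequence[MixturePanelRecord],
    through_origin: bool = True,
) -> SlopeFit:
    """Least-squares slope of mixture intensity on summed component intensity.

    Through the origin by default: s = Σxy / Σx². The free-intercept
    variant (``through_origin=False``) is a sensitivity diagnostic only.
    """
    x = np.array([r.oi_sum for r in records], dtype=float)
    y = np.array([r.oi_mixture for r in records], dtype=float)
    if len(x) == 0 or not np.any(x > 0):
        raise ValueError("degenerate fit: need at least one record with OI_sum > 0")
    if through_origin:
        slope = float(np.sum(x * y) / np.sum(x * x))
        intercept = 0.0
        dof = max(len(x) - 1, 1)
    else:
        if len(np.unique(x)) < 2:
            raise ValueError("degenerate fit: free-intercept fit needs 2 distinct sums")
        res = stats.linregress(x, y)
        slope, intercept = float(res.slope), float(res.intercept)
        dof = max(len(x) - 2, 1)
    resid = y - (slope * x + intercept)
    residual_se = float(np.sqrt(np.sum(resid**2) / dof))
    return SlopeFit(
        slope=slope,
        residual_se=residual_se,
        n=len(x),
        intercept=intercept,
        through_origin=through_origin,
    )


def calibrate_family(
    singles: Sequence[SinglePanelRecord],
    mixtures: Sequence[MixturePanelRecord],
    registry: Registry,
    name: str = "",
    through_origin: bool = True,
) -> CalibrationResult:
    """Assemble a FamilyModel from panel data: law fit + slope fit + cosα.

    Family members are the odorants appearing in the singles records.
    """
    law_fit = fit_psychophysical_law(singles, registry)
    slope_fit = fit_mixture_slope(mixtures, through_origin=through_origin)
    members = {
        od.name: od
        for od in (registry.get(r.odorant) for r in singles)
    }
    model = FamilyModel(
        law=law_fit.law,
        cos_alpha=cos_alpha_from_slope(slope_fit.slope),
        members=members,
        name=name,
    )
    return CalibrationResult(model=model, law_fit=law_fit, slope_fit=slope_fit)
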