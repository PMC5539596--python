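"""Closed-form mathematics of the modified vector model (MVM).

The vector model treats the perceived intensity of an odor mixture as the
norm of a vector sum of its components' perceived intensities, with the
angle between component vectors encoding their perceptual interaction:

    OI_ab² = OI_a² + OI_b² + 2·cosα·OI_a·OI_b

cosα ∈ [−1, 1] is the interaction coefficient: +1 is complete additivity,
0 orthogonal (Pythagorean) summation, negative values odor counteraction.
The "modified" part of the model replaces panel-measured component
intensities with a log-linear psychophysical law on the odor activity
value (OAV = C / C_thr):

    OI = k·ln(OAV) + b

so a mixture's intensity follows directly from its constituents' gas-phase
concentrations. Within an odorant family (same functional group / odor
type) a single (k, b) and a single cosα empirically suffice; cosα is tied
to the slope s of the mixture-vs-sum relation OI_mix = s·OI_sum by
cosα = 2s² − 1 (equal-intensity mixing).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "Odorant",
    "PsychophysicalLaw",
    "FamilyModel",
    "OdorSample",
    "OIRScale",
    "compute_oav",
    "oi_single",
    "mixture_oi_binary",
    "mixture_oi_n",
    "cos_alpha_from_measurement",
    "cos_alpha_from_slope",
    "slope_from_cos_alpha",
    "predict_mixture_oi",
    "oirs_concentration",
    "nearest_oirs_level",
]


@dataclass(frozen=True)
class Odorant:
    """A single odorous compound and its odor threshold.

    The threshold (mg/m³) is the panel-detectable minimum concentration
    and is the denominator of the odor activity value.
    """

    name: str
    cas: str
    odor_threshold: float
    abbreviation: str = ""
    family: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("odorant name must be non-empty")
        if not (self.odor_threshold > 0):
            raise ValueError(
                f"odor threshold must be positive, got {self.odor_threshold!r} "
                f"for {self.name}"
            )


@dataclass(frozen=True)
class PsychophysicalLaw:
    """Log-linear intensity law OI = k·ln(OAV) + b for one odorant family."""

    k: float
    b: float

    def __post_init__(self) -> None:
        if not (self.k > 0):
            raise ValueError(f"psychophysical slope k must be positive, got {self.k!r}")

    def __call__(self, ln_oav: float) -> float:
        """Unclamped line evaluation (may be negative below threshold)."""
        return self.k * ln_oav + self.b


@dataclass(frozen=True)
class FamilyModel:
    """A calibrated family: psychophysical law + shared interaction coefficient.

    ``members`` maps odorant names to :class:`Odorant`; lookups also accept
    the registry abbreviation (e.g. ``"A"`` for acetaldehyde).
    """

    law: PsychophysicalLaw
    cos_alpha: float
    members: Mapping[str, Odorant] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        if not (-1.0 <= self.cos_alpha <= 1.0):
            raise ValueError(f"cos_alpha must lie in [-1, 1], got {self.cos_alpha!r}")

    def member(self, key: str) -> Odorant:
        """Resolve an odorant by name or abbreviation.

        Raises :class:`KeyError` naming the odorant if it is not a member.
        """
        if key in self.members:
            return self.members[key]
        for od in self.members.values():
            if od.abbreviation and od.abbreviation == key:
                return od
        raise KeyError(
            f"odorant {key!r} is not a member of family {self.name or '<unnamed>'}"
        )


@dataclass(frozen=True)
class OdorSample:
    """Gas-phase composition of one odor sample: odorant → mg/m³."""

    composition: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.composition:
            raise ValueError("an odor sample needs at least one constituent")
        for name, conc in self.composition.items():
            if conc < 0:
                raise ValueError(f"negative concentration {conc!r} for {name!r}")


@dataclass(frozen=True)
class OIRScale:
    """Odor intensity referencing scale: geometric n-butanol standards.

    Level ``i`` is an aqueous n-butanol solution at
    ``base_concentration · ratio**(i − 1)`` ppm; assessors rate a sample by
    pointing at the level whose smell strength matches.
    """

    base_concentration: float
    ratio: float = 2.0
    n_levels: int = 12

    def __post_init__(self) -> None:
        if not (self.base_concentration > 0):
            raise ValueError("base concentration must be positive")
        if not (self.ratio > 1):
            raise ValueError("ratio must exceed 1")
        if self.n_levels < 2:
            raise ValueError("a scale needs at least 2 levels")


def compute_oav(concentration: float, odorant: Odorant) -> float:
    """Odor activity value OAV = C / C_thr (dimensionless)."""
    if concentration < 0:
        raise ValueError(f"concentration must be non-negative, got {concentration!r}")
    return concentration / odorant.odor_threshold


def oi_single(concentration: float, odorant: Odorant, law: PsychophysicalLaw) -> float:
    """Perceived intensity of a single odorant from its concentration.

    Evaluates OI = k·ln(OAV) + b and clamps negative values to 0:
    sub-threshold stimuli (OAV ≤ exp(−b/k)) are imperceptible. A zero
    concentration returns 0 without evaluating the logarithm.
    """
    oav = compute_oav(concentration, odorant)
    if oav <= 0:
        return 0.0
    return max(0.0, law(math.log(oav)))


def _check_cos_alpha(cos_alpha: float) -> None:
    if not (-1.0 <= cos_alpha <= 1.0):
        raise ValueError(f"cos_alpha must lie in [-1, 1], got {cos_alpha!r}")


def _root_of_clamped(radicand: float) -> float:
    if radicand < 0:
        warnings.warn(
            "mixture radicand below zero (complete odor counteraction); "
            "clamping intensity to 0",
            RuntimeWarning,
            stacklevel=3,
        )
        return 0.0
    return math.sqrt(radicand)


def mixture_oi_binary(oi_a: float, oi_b: float, cos_alpha: float) -> float:
    """Vector-model intensity of a binary mixture.

    sqrt(OI_a² + OI_b² + 2·cosα·OI_a·OI_b), radicand clamped at 0.
    """
    if oi_a < 0 or oi_b < 0:
        raise ValueError("component intensities must be non-negative")
    _check_cos_alpha(cos_alpha)
    return _root_of_clamped(oi_a * oi_a + oi_b * oi_b + 2.0 * cos_alpha * oi_a * oi_b)


def mixture_oi_n(ois: Sequence[float], cos_alpha: float) -> float:
    """Vector-model intensity of an n-component mixture, shared cosα.

    sqrt(Σ OIᵢ² + 2·cosα·Σ_{i<j} OIᵢ·OIⱼ); every pairwise term carries the
    same family interaction coefficient. A single-element list returns its
    element; for n = 2 this coincides with :func:`mixture_oi_binary`.
    """
    if len(ois) == 0:
        raise ValueError("mixture needs at least one component")
    if any(o < 0 for o in ois):
        raise ValueError("component intensities must be non-negative")
    _check_cos_alpha(cos_alpha)
    if len(ois) == 1:
        return float(ois[0])
    total = sum(ois)
    sum_sq = sum(o * o for o in ois)
    # Σ_{i<j} oi·oj == ((Σ oi)² − Σ oi²) / 2
    cross = (total * total - sum_sq) / 2.0
    return _root_of_clamped(sum_sq + 2.0 * cos_alpha * cross)


def cos_alpha_from_measurement(oi_ab: float, oi_a: float, oi_b: float) -> float:
    """Interaction coefficient from a measured pair + mixture intensity.

    Inverts the binary vector model: (OI_ab² − OI_a² − OI_b²)/(2·OI_a·OI_b).
    Both component intensities must be strictly positive.
    """
    if oi_a <= 0 or oi_b <= 0:
        raise ValueError("component intensities must be positive to solve for cos_alpha")
    return (oi_ab * oi_ab - oi_a * oi_a - oi_b * oi_b) / (2.0 * oi_a * oi_b)


def cos_alpha_from_slope(s: float) -> float:
    """Interaction coefficient implied by the mixture slope OI_mix = s·OI_sum.

    Substituting OI_ab = s(OI_a + OI_b) with OI_a = OI_b (equal-intensity
    mixing) into the vector model gives cosα = 2s² − 1.
    """
    if not (0.0 < s <= 1.0):
        raise ValueError(f"mixture slope must lie in (0, 1], got {s!r}")
    return 2.0 * s * s - 1.0


def slope_from_cos_alpha(c: float) -> float:
    """Inverse of :func:`cos_alpha_from_slope`: s = sqrt((1 + cosα)/2)."""
    if not (-1.0 < c <= 1.0):
        raise ValueError(f"cos_alpha must lie in (-1, 1], got {c!r}")
    return math.sqrt((1.0 + c) / 2.0)


def predict_mixture_oi(sample: OdorSample, family: FamilyModel) -> float:
    """Mixture intensity straight from constituent concentrations.

    Each constituent's OI is computed under the family law, then the OIs
    are combined with the family's shared interaction coefficient. All
    constituents must be members of the family.
    """
    ois = [
        oi_single(conc, family.member(name), family.law)
        for name, conc in sample.composition.items()
    ]
    if len(ois) == 1:
        return ois[0]
    return mixture_oi_n(ois, family.cos_alpha)


def oirs_concentration(level: int, scale: OIRScale) -> float:
    """n-Butanol concentration (ppm) of a referencing-scale level."""
    if not (1 <= level <= scale.n_levels):
        raise ValueError(
            f"level must lie in [1, {scale.n_levels}], got {level!r}"
        )
    return scale.base_concentration * scale.ratio ** (level - 1)


def nearest_oirs_level(oi: float, resolution: float) -> float:
    """Quantize a continuous intensity to the assessor reporting grid.

    Rounds to the nearest multiple of ``resolution`` (e.g. 0.5 for
    half-level ratings); exact ties round up.
    """
    if oi < 0:
        raise ValueError("intensity must be non-negative")
    if not (resolution > 0):
        raise ValueError("resolution must be positive")
    return math.floor(oi / resolution + 0.5) * resolution
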