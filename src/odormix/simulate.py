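"""Synthetic psychophysics and sensor-array data generation.

Panel data are generated from the same structure the model assumes: single
odorants get a true intensity from the log-linear law OI = k·lnOAV + b;
mixtures get a true intensity from the vector model with the family's
slope-derived interaction coefficient. Assessor behaviour is emulated as
additive Gaussian noise on the intensity scale (default sd 0.5, the
generally acknowledged scatter of one referencing-scale step), truncated
at 0, quantized to the reporting grid (default half-levels), and averaged
over the panel (default 8 assessors).

Sensor databases are generated from a linear cross-sensitive response
model: signal_j = baseline_j + Σ_i sensitivity_ji · C_i + noise. Mixture
responses are additive in constituents (no sensor-level interaction). All
generators are pure functions of (config, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import math

import numpy as np
import yaml

from .calibration import MixturePanelRecord, SinglePanelRecord
from .core import (
    Odorant,
    OdorSample,
    cos_alpha_from_slope,
    mixture_oi_n,
    nearest_oirs_level,
)
from .enose import SensorSpec, TrainingDatabase

__all__ = [
    "PanelSimConfig",
    "SensorSimConfig",
    "gen_single_odorant_panel",
    "gen_mixture_panel",
    "gen_sensor_training_db",
    "default_sensor_array",
    "default_sample_plan",
]


@dataclass(frozen=True)
class PanelSimConfig:
    """Conditions of a simulated sensory-panel study.

    Defaults mirror the calibration study design: 6 single-odorant samples
    per odorant, 5 mixture samples per combination with intensities spread
    over the referencing scale, 8 assessors with scatter of about half a
    scale level, ratings at half-level resolution.
    """

    k: float
    b: float
    slope: float
    odorants: Tuple[Odorant, ...]
    n_singles: int = 6
    n_mixtures: int = 5
    lnoav_range: Tuple[float, float] = (1.0, 3.5)
    mixture_oi_range: Tuple[float, float] = (1.0, 12.0)
    assessor_sd: float = 0.5
    n_assessors: int = 8
    oirs_resolution: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.assessor_sd < 0:
            raise ValueError("assessor_sd must be non-negative")
        if self.n_assessors < 1:
            raise ValueError("need at least one assessor")
        if not self.odorants:
            raise ValueError("need at least one odorant")
        lo, hi = self.lnoav_range
        if hi < lo:
            raise ValueError("lnoav_range must be increasing")
        if self.k * lo + self.b < 0:
            raise ValueError(
                "lnoav_range extends below the perceivable region "
                f"(k·lnOAV + b = {self.k * lo + self.b:.3g} < 0 at the lower edge)"
            )


def _rate(true_oi: float, cfg: PanelSimConfig, rng: np.random.Generator) -> float:
    """One panel-mean rating of a stimulus with true intensity ``true_oi``."""
    ratings = []
    for _ in range(cfg.n_assessors):
        r = true_oi + (rng.normal(0.0, cfg.assessor_sd) if cfg.assessor_sd > 0 else 0.0)
        r = max(0.0, r)
        if cfg.oirs_resolution > 0:
            r = nearest_oirs_level(r, cfg.oirs_resolution)
        ratings.append(r)
    return float(np.mean(ratings))


def gen_single_odorant_panel(cfg: PanelSimConfig) -> List[SinglePanelRecord]:
    """Simulated single-odorant panel records on a fixed ln(OAV) grid.

    Concentrations are placed so ln(OAV) spans ``cfg.lnoav_range`` with
    ``cfg.n_singles`` points per odorant; the reported intensity is the
    panel-mean rating of the law's true intensity.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = np.linspace(*cfg.lnoav_range, cfg.n_singles)
    records = []
    for od in cfg.odorants:
        for ln_oav in grid:
            conc = od.odor_threshold * math.exp(ln_oav)
            true_oi = cfg.k * ln_oav + cfg.b
            records.append(
                SinglePanelRecord(
                    odorant=od.name,
                    concentration=conc,
                    oi=_rate(true_oi, cfg, rng),
                )
            )
    return records


def gen_mixture_panel(
    cfg: PanelSimConfig,
    arity: int = 2,
    equal_intensity: bool = True,
) -> List[MixturePanelRecord]:
    """Simulated mixture panel records for all arity-sized odorant combos.

    Component intensities are either all equal (the standard design for
    measuring the interaction coefficient), spread evenly over
    ``cfg.mixture_oi_range``, or drawn uniformly from that range. The true
    mixture intensity comes from the vector model with
    cosα = 2·slope² − 1; panel noise is applied to components and mixture
    alike.
    """
    if arity not in (2, 3):
        raise ValueError("mixture arity must be 2 or 3")
    if len(cfg.odorants) < arity:
        raise ValueError(f"need at least {arity} odorants for arity-{arity} mixtures")
    rng = np.random.default_rng(cfg.seed + 1)
    cos_alpha = cos_alpha_from_slope(cfg.slope)
    lo, hi = cfg.mixture_oi_range
    grid = np.linspace(lo, hi, cfg.n_mixtures)
    records = []
    for _combo in itertools.combinations(cfg.odorants, arity):
        for i in range(cfg.n_mixtures):
            if equal_intensity:
                components = [float(grid[i])] * arity
            else:
                components = rng.uniform(lo, hi, size=arity).tolist()
            true_mix = mixture_oi_n(components, cos_alpha)
            records.append(
                MixturePanelRecord(
                    oi_components=tuple(_rate(c, cfg, rng) for c in components),
                    oi_mixture=_rate(true_mix, cfg, rng),
                )
            )
    return records


@dataclass(frozen=True)
class SensorSimConfig:
    """Linear sensor-array simulation settings."""

    array: Tuple[SensorSpec, ...]
    odorant_names: Tuple[str, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.array:
            raise ValueError("need at least one sensor")
        if not self.odorant_names:
            names: List[str] = []
            for spec in self.array:
                for od in spec.sensitivities:
                    if od not in names:
                        names.append(od)
            object.__setattr__(self, "odorant_names", tuple(names))
        for od in self.odorant_names:
            if not any(spec.sensitivities.get(od, 0.0) > 0 for spec in self.array):
                raise ValueError(f"no sensor in the array responds to {od!r}")


def gen_sensor_training_db(
    cfg: SensorSimConfig, samples: Sequence[OdorSample]
) -> TrainingDatabase:
    """Linear cross-sensitive sensor responses for a list of odor samples.

    signal_j = baseline_j + Σ_i sensitivity_ji · C_i + N(0, noise_sd).
    """
    rng = np.random.default_rng(cfg.seed)
    odorants = list(cfg.odorant_names)
    conc = np.zeros((len(samples), len(odorants)))
    for r, sample in enumerate(samples):
        for name, c in sample.composition.items():
            if name not in odorants:
                raise ValueError(f"sample contains odorant {name!r} unknown to the array")
            conc[r, odorants.index(name)] = c
    sens = np.array(
        [[spec.sensitivities.get(od, 0.0) for od in odorants] for spec in cfg.array]
    )
    base = np.array([spec.baseline for spec in cfg.array])
    signals = conc @ sens.T + base
    if cfg.noise_sd > 0:
        signals = signals + rng.normal(0.0, cfg.noise_sd, size=signals.shape)
    return TrainingDatabase(
        signals=signals,
        concentrations=conc,
        sensor_names=[spec.name for spec in cfg.array],
        odorant_names=odorants,
    )


def default_sensor_array(
    path: Optional[Union[str, Path]] = None,
) -> Tuple[SensorSpec, ...]:
    """The packaged seven-sensor synthetic array (see data/sensor_array.yaml)."""
    if path is None:
        source = resources.files("odormix.data").joinpath("sensor_array.yaml")
        with resources.as_file(source) as p:
            spec = yaml.safe_load(p.read_text())
    else:
        spec = yaml.safe_load(Path(path).read_text())
    return tuple(
        SensorSpec(
            name=s["name"],
            baseline=float(s["baseline"]),
            sensitivities={k: float(v) for k, v in s["sensitivities"].items()},
        )
        for s in spec["sensors"]
    )


def default_sample_plan(
    odorants: Sequence[Odorant],
    lnoav_range: Tuple[float, float] = (1.0, 3.5),
    n_single: int = 8,
    n_binary: int = 25,
    n_ternary: int = 50,
    seed: int = 0,
) -> List[OdorSample]:
    """Training-sample plan mirroring the calibration study counts.

    Singles on a ln(OAV) grid per odorant, random binary mixtures per pair,
    random ternary mixtures (for three odorants). Concentrations are set
    via C = threshold · exp(lnOAV).
    """
    rng = np.random.default_rng(seed)
    lo, hi = lnoav_range

    def conc(od: Odorant, ln_oav: float) -> float:
        return od.odor_threshold * math.exp(ln_oav)

    samples: List[OdorSample] = []
    for od in odorants:
        for ln_oav in np.linspace(lo, hi, n_single):
            samples.append(OdorSample({od.name: conc(od, ln_oav)}))
    for a, b in itertools.combinations(odorants, 2):
        for _ in range(n_binary):
            samples.append(
                OdorSample(
                    {
                        a.name: conc(a, rng.uniform(lo, hi)),
                        b.name: conc(b, rng.uniform(lo, hi)),
                    }
                )
            )
    if len(odorants) >= 3:
        for combo in itertools.combinations(odorants, 3):
            for _ in range(n_ternary):
                samples.append(
                    OdorSample(
                        {od.name: conc(od, rng.uniform(lo, hi)) for od in combo}
                    )
                )
    return samples
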