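"""Concentration estimation from gas-sensor-array signals.

The estimator is a fully connected feedforward network (logistic-sigmoid
hidden layers, identity output) regressing min–max-normalized sensor
signals onto min–max-normalized constituent concentrations, mirroring the
back-propagation networks used in e-nose quantitative analysis. Training
delegates to scikit-learn's MLPRegressor; the fitted weights are then held
in a plain forward-pass evaluator so the estimator is deterministic at
prediction time and serializes to a single JSON file (weights +
normalization statistics + odorant order).

The end of the pipeline, :func:`signals_to_oi`, chains the estimator with
a family model: signals → concentrations → OAVs → component intensities →
mixture intensity.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .core import FamilyModel, compute_oav, mixture_oi_n, oi_single

__all__ = [
    "SensorSpec",
    "TrainingDatabase",
    "NormalizationStats",
    "EstimatorConfig",
    "ConcentrationEstimator",
    "EnoseResult",
    "normalize",
    "denormalize",
    "train_estimator",
    "average_relative_error",
    "signals_to_oi",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SensorSpec:
    """Linear response model of one gas sensor.

    ``sensitivities`` maps odorant name → signal units per mg/m³; odorants
    the sensor does not respond to are simply absent (sensitivity 0).
    """

    name: str
    baseline: float
    sensitivities: Mapping[str, float]

    def __post_init__(self) -> None:
        for od, s in self.sensitivities.items():
            if s < 0:
                raise ValueError(f"negative sensitivity {s!r} for {od!r} on {self.name}")


@dataclass
class TrainingDatabase:
    """Paired (sensor signals, reference concentrations) records."""

    signals: np.ndarray
    concentrations: np.ndarray
    sensor_names: List[str]
    odorant_names: List[str]

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.signals.ndim != 2 or self.concentrations.ndim != 2:
            raise ValueError("signals and concentrations must be 2-D")
        if self.signals.shape[0] != self.concentrations.shape[0]:
            raise ValueError("signal and concentration row counts differ")
        if self.signals.shape[1] != len(self.sensor_names):
            raise ValueError("signal column count != number of sensor names")
        if self.concentrations.shape[1] != len(self.odorant_names):
            raise ValueError("concentration column count != number of odorant names")
        if np.any(self.concentrations < 0):
            raise ValueError("negative concentrations in training database")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[0]


@dataclass(frozen=True)
class NormalizationStats:
    """Per-column min/max of a training matrix, for Eq.-style min–max scaling."""

    min: np.ndarray
    max: np.ndarray

    @classmethod
    def from_data(cls, x: np.ndarray) -> "NormalizationStats":
        x = np.asarray(x, dtype=float)
        stats = cls(min=x.min(axis=0), max=x.max(axis=0))
        if np.any(stats.max <= stats.min):
            bad = np.nonzero(stats.max <= stats.min)[0]
            raise ValueError(f"degenerate (constant) column(s) at index {bad.tolist()}")
        return stats


def normalize(x: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """y = (x − MIN) / (MAX − MIN), per column; out-of-range values are
    mapped outside [0, 1] rather than clipped."""
    span = stats.max - stats.min
    if np.any(span <= 0):
        raise ValueError("degenerate normalization: max must exceed min")
    return (np.asarray(x, dtype=float) - stats.min) / span


def denormalize(y: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Exact inverse of :func:`normalize`."""
    span = stats.max - stats.min
    if np.any(span <= 0):
        raise ValueError("degenerate normalization: max must exceed min")
    return np.asarray(y, dtype=float) * span + stats.min


@dataclass(frozen=True)
class EstimatorConfig:
    """Network architecture and training settings.

    Defaults follow the selected e-nose configuration: five hidden layers
    of twenty neurons, logistic hidden activations, identity output. The
    optimizer is seeded Adam; L-BFGS is selectable but stalls on deep
    logistic stacks.
    """

    hidden_layers: int = 5
    neurons_per_layer: int = 20
    optimizer: str = "adam"
    max_iterations: int = 20000
    learning_rate: float = 1e-3
    tol: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_layers < 1 or self.neurons_per_layer < 1:
            raise ValueError("layer and neuron counts must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def _logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class ConcentrationEstimator:
    """Trained signals → concentrations regressor.

    Holds layer weights/biases (logistic hidden layers, identity output)
    plus the min–max statistics of both sides of the training database and
    the odorant output order.
    """

    weights: List[np.ndarray]
    biases: List[np.ndarray]
    signal_stats: NormalizationStats
    conc_stats: NormalizationStats
    sensor_names: List[str]
    odorant_names: List[str]
    config: EstimatorConfig = field(default_factory=EstimatorConfig)

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_names)

    def _forward(self, xn: np.ndarray) -> np.ndarray:
        a = xn
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = _logistic(a @ w + b)
        return a @ self.weights[-1] + self.biases[-1]

    def predict_matrix(self, signals: np.ndarray) -> np.ndarray:
        """Concentration matrix (samples × odorants) from a signal matrix.

        Normalizes, runs the forward pass, denormalizes, clamps negative
        concentrations to 0.
        """
        signals = np.atleast_2d(np.asarray(signals, dtype=float))
        if signals.shape[1] != self.n_sensors:
            raise ValueError(
                f"expected {self.n_sensors} sensor signals, got {signals.shape[1]}"
            )
        yn = self._forward(normalize(signals, self.signal_stats))
        return np.maximum(denormalize(yn, self.conc_stats), 0.0)

    def predict_concentrations(self, signals: Sequence[float]) -> Dict[str, float]:
        """Odorant → mg/m³ for a single sensor-signal vector."""
        row = self.predict_matrix(np.asarray(signals, dtype=float).reshape(1, -1))[0]
        return dict(zip(self.odorant_names, row.tolist()))

    def save(self, path: Union[str, Path]) -> None:
        payload = {
            "format": "odormix-estimator-v1",
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "signal_stats": {
                "min": self.signal_stats.min.tolist(),
                "max": self.signal_stats.max.tolist(),
            },
            "conc_stats": {
                "min": self.conc_stats.min.tolist(),
                "max": self.conc_stats.max.tolist(),
            },
            "sensor_names": self.sensor_names,
            "odorant_names": self.odorant_names,
            "config": self.config.__dict__,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ConcentrationEstimator":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "odormix-estimator-v1":
            raise ValueError(f"{path}: not an odormix estimator file")
        return cls(
            weights=[np.array(w) for w in payload["weights"]],
            biases=[np.array(b) for b in payload["biases"]],
            signal_stats=NormalizationStats(
                min=np.array(payload["signal_stats"]["min"]),
                max=np.array(payload["signal_stats"]["max"]),
            ),
            conc_stats=NormalizationStats(
                min=np.array(payload["conc_stats"]["min"]),
                max=np.array(payload["conc_stats"]["max"]),
            ),
            sensor_names=list(payload["sensor_names"]),
            odorant_names=list(payload["odorant_names"]),
            config=EstimatorConfig(**payload["config"]),
        )


def train_estimator(
    db: TrainingDatabase, config: Optional[EstimatorConfig] = None
) -> ConcentrationEstimator:
    """Fit the feedforward regressor on a training database.

    Both sides of the database are min–max normalized per column before
    training; the statistics are stored in the returned estimator so later
    predictions are normalized identically and outputs are rescaled back
    to mg/m³. Training is reproducible given ``config.seed``.
    """
    from sklearn.neural_network import MLPRegressor

    config = config or EstimatorConfig()
    if not (np.all(np.isfinite(db.signals)) and np.all(np.isfinite(db.concentrations))):
        raise ValueError("training database contains non-finite values")
    if db.n_samples < 2:
        warnings.warn(
            "training database has a single sample; the fit is underdetermined",
            RuntimeWarning,
        )
        # min == max per column; widen artificially so normalization is defined
        eps = 1.0
        signal_stats = NormalizationStats(
            min=db.signals.min(axis=0) - eps, max=db.signals.max(axis=0) + eps
        )
        conc_stats = NormalizationStats(
            min=db.concentrations.min(axis=0) - eps,
            max=db.concentrations.max(axis=0) + eps,
        )
    else:
        signal_stats = NormalizationStats.from_data(db.signals)
        conc_stats = NormalizationStats.from_data(db.concentrations)

    xn = normalize(db.signals, signal_stats)
    yn = normalize(db.concentrations, conc_stats)
    if yn.shape[1] == 1:
        yn = yn.ravel()

    mlp = MLPRegressor(
        hidden_layer_sizes=(config.neurons_per_layer,) * config.hidden_layers,
        activation="logistic",
        solver=config.optimizer,
        alpha=1e-8,
        learning_rate_init=config.learning_rate,
        max_iter=config.max_iterations,
        tol=config.tol,
        n_iter_no_change=200,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", category=ConvergenceWarning)
        mlp.fit(xn, yn)
    logger.info("estimator trained: %d iterations, loss %.3e", mlp.n_iter_, mlp.loss_)

    weights = [np.array(w) for w in mlp.coefs_]
    biases = [np.array(b) for b in mlp.intercepts_]
    return ConcentrationEstimator(
        weights=weights,
        biases=biases,
        signal_stats=signal_stats,
        conc_stats=conc_stats,
        sensor_names=list(db.sensor_names),
        odorant_names=list(db.odorant_names),
        config=config,
    )


def average_relative_error(predicted: np.ndarray, reference: np.ndarray) -> float:
    """ARE in percent: mean of |pred − ref| / ref over entries with ref > 0.

    Entries with a zero reference are excluded (relative error undefined
    there); the exclusion count is logged. Raises if no positive reference
    entries remain.
    """
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: predicted {predicted.shape} vs reference {reference.shape}"
        )
    mask = reference > 0
    n_excluded = int(mask.size - mask.sum())
    if not np.any(mask):
        raise ValueError("no positive reference entries to compare against")
    if n_excluded:
        logger.info("ARE: excluded %d zero-reference entries", n_excluded)
    return float(
        100.0 * np.mean(np.abs(predicted[mask] - reference[mask]) / reference[mask])
    )


@dataclass(frozen=True)
class ConstituentBreakdown:
    odorant: str
    concentration: float
    oav: float
    oi: float


@dataclass(frozen=True)
class EnoseResult:
    """Mixture intensity plus the per-constituent chain that produced it."""

    oi: float
    constituents: Tuple[ConstituentBreakdown, ...]


def signals_to_oi(
    signals: Sequence[float],
    estimator: ConcentrationEstimator,
    family: FamilyModel,
) -> EnoseResult:
    """Full e-nose pipeline: signals → concentrations → mixture intensity."""
    for name in estimator.odorant_names:
        family.member(name)  # raises KeyError if not covered by the model
    concs = estimator.predict_concentrations(signals)
    breakdown = []
    ois = []
    for name in estimator.odorant_names:
        od = family.member(name)
        c = concs[name]
        oi = oi_single(c, od, family.law)
        breakdown.append(
            ConstituentBreakdown(
                odorant=name, concentration=c, oav=compute_oav(c, od), oi=oi
            )
        )
        ois.append(oi)
    total = ois[0] if len(ois) == 1 else mixture_oi_n(ois, family.cos_alpha)
    return EnoseResult(oi=total, constituents=tuple(breakdown))
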