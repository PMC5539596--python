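"""CSV/YAML/JSON round-tripping for panel data, samples, sensor databases
and calibrated family models.

Schemas (all long-format CSV):

* singles panel:  sample_id, odorant, concentration_mg_m3, oi
* mixtures panel: sample_id, role (``component``/``mixture``), oi
* compositions:   sample_id, odorant, concentration_mg_m3
* sensor database: sample_id, one column per sensor, then ``conc_<odorant>``
  columns
* family model: YAML with k, b, slope, cos_alpha (slope-derived), member
  odorants with thresholds, and fit diagnostics
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationResult, MixturePanelRecord, SinglePanelRecord
from .core import FamilyModel, Odorant, OdorSample, PsychophysicalLaw, slope_from_cos_alpha
from .enose import TrainingDatabase

__all__ = [
    "read_singles_csv",
    "write_singles_csv",
    "read_mixtures_csv",
    "write_mixtures_csv",
    "read_samples_csv",
    "write_samples_csv",
    "read_training_db_csv",
    "write_training_db_csv",
    "write_family_model",
    "load_family_model",
    "write_fit_report",
]

PathLike = Union[str, Path]


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} CSV missing column(s): {', '.join(missing)}")


def read_singles_csv(path: PathLike) -> List[SinglePanelRecord]:
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "odorant", "concentration_mg_m3", "oi"], "singles")
    return [
        SinglePanelRecord(
            odorant=str(r.odorant),
            concentration=float(r.concentration_mg_m3),
            oi=float(r.oi),
        )
        for r in df.itertuples(index=False)
    ]


def write_singles_csv(path: PathLike, records: Sequence[SinglePanelRecord]) -> None:
    pd.DataFrame(
        {
            "sample_id": [f"s{i + 1}" for i in range(len(records))],
            "odorant": [r.odorant for r in records],
            "concentration_mg_m3": [r.concentration for r in records],
            "oi": [r.oi for r in records],
        }
    ).to_csv(path, index=False)


def read_mixtures_csv(path: PathLike) -> List[MixturePanelRecord]:
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "role", "oi"], "mixtures")
    records = []
    for sid, group in df.groupby("sample_id", sort=False):
        components = group.loc[group["role"] == "component", "oi"].tolist()
        mixture = group.loc[group["role"] == "mixture", "oi"].tolist()
        if len(mixture) != 1:
            raise ValueError(
                f"mixtures CSV: sample {sid!r} needs exactly one 'mixture' row"
            )
        records.append(
            MixturePanelRecord(
                oi_components=tuple(float(c) for c in components),
                oi_mixture=float(mixture[0]),
            )
        )
    return records


def write_mixtures_csv(path: PathLike, records: Sequence[MixturePanelRecord]) -> None:
    rows = []
    for i, rec in enumerate(records):
        sid = f"m{i + 1}"
        for c in rec.oi_components:
            rows.append({"sample_id": sid, "role": "component", "oi": c})
        rows.append({"sample_id": sid, "role": "mixture", "oi": rec.oi_mixture})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_samples_csv(path: PathLike) -> List[Tuple[str, OdorSample]]:
    """Compositions in long format → ordered (sample_id, OdorSample) pairs."""
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "odorant", "concentration_mg_m3"], "samples")
    out = []
    for sid, group in df.groupby("sample_id", sort=False):
        comp = {
            str(r.odorant): float(r.concentration_mg_m3)
            for r in group.itertuples(index=False)
        }
        out.append((str(sid), OdorSample(comp)))
    return out


def write_samples_csv(
    path: PathLike, samples: Sequence[Tuple[str, OdorSample]]
) -> None:
    rows = []
    for sid, sample in samples:
        for od, c in sample.composition.items():
            rows.append({"sample_id": sid, "odorant": od, "concentration_mg_m3": c})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_training_db_csv(path: PathLike, db: TrainingDatabase) -> None:
    data: Dict[str, object] = {"sample_id": [f"t{i + 1}" for i in range(db.n_samples)]}
    for j, s in enumerate(db.sensor_names):
        data[s] = db.signals[:, j]
    for j, od in enumerate(db.odorant_names):
        data[f"conc_{od}"] = db.concentrations[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def read_training_db_csv(path: PathLike) -> TrainingDatabase:
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id"], "training database")
    conc_cols = [c for c in df.columns if c.startswith("conc_")]
    sensor_cols = [c for c in df.columns if c != "sample_id" and c not in conc_cols]
    if not conc_cols or not sensor_cols:
        raise ValueError(
            "training database CSV needs sensor columns and conc_<odorant> columns"
        )
    return TrainingDatabase(
        signals=df[sensor_cols].to_numpy(dtype=float),
        concentrations=df[conc_cols].to_numpy(dtype=float),
        sensor_names=sensor_cols,
        odorant_names=[c[len("conc_"):] for c in conc_cols],
    )


def write_family_model(
    path: PathLike,
    model: FamilyModel,
    result: Optional[CalibrationResult] = None,
) -> None:
    payload: Dict[str, object] = {
        "name": model.name,
        "k": float(model.law.k),
        "b": float(model.law.b),
        "slope": float(slope_from_cos_alpha(model.cos_alpha)),
        "cos_alpha": float(model.cos_alpha),
        "members": [
            {
                "name": od.name,
                "abbreviation": od.abbreviation,
                "cas": od.cas,
                "odor_threshold_mg_m3": float(od.odor_threshold),
                "family": od.family,
            }
            for od in model.members.values()
        ],
    }
    if result is not None:
        payload["diagnostics"] = {
            "law": {
                "residual_se": result.law_fit.residual_se,
                "r_squared": result.law_fit.r_squared,
                "n_used": result.law_fit.n_used,
                "n_excluded": result.law_fit.n_excluded,
                "per_odorant": result.law_fit.per_odorant,
            },
            "mixture_slope": {
                "residual_se": result.slope_fit.residual_se,
                "n": result.slope_fit.n,
                "through_origin": result.slope_fit.through_origin,
            },
        }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_family_model(path: PathLike) -> FamilyModel:
    payload = yaml.safe_load(Path(path).read_text())
    members = {
        m["name"]: Odorant(
            name=m["name"],
            cas=str(m.get("cas", "")),
            odor_threshold=float(m["odor_threshold_mg_m3"]),
            abbreviation=str(m.get("abbreviation", "") or ""),
            family=str(m.get("family", "") or ""),
        )
        for m in payload["members"]
    }
    return FamilyModel(
        law=PsychophysicalLaw(k=float(payload["k"]), b=float(payload["b"])),
        cos_alpha=float(payload["cos_alpha"]),
        members=members,
        name=str(payload.get("name", "")),
    )


def write_fit_report(path: PathLike, result: CalibrationResult) -> None:
    report = {
        "k": result.law_fit.law.k,
        "b": result.law_fit.law.b,
        "law_residual_se": result.law_fit.residual_se,
        "law_r_squared": result.law_fit.r_squared,
        "law_n_used": result.law_fit.n_used,
        "law_n_excluded": result.law_fit.n_excluded,
        "per_odorant": result.law_fit.per_odorant,
        "mixture_slope": result.slope_fit.slope,
        "mixture_slope_residual_se": result.slope_fit.residual_se,
        "mixture_n": result.slope_fit.n,
        "through_origin": result.slope_fit.through_origin,
        "cos_alpha": result.model.cos_alpha,
    }
    Path(path).write_text(json.dumps(report, indent=2))
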