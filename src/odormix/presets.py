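"""Preset family models (aldehydes, esters) shipped with the package.

Each preset stores the fitted psychophysical law (k, b), the mixture slope
s of OI_mix = s·OI_sum, and the family's referencing scale. The interaction
coefficient is always derived from the slope (cosα = 2s² − 1) when the
preset is loaded, never stored.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, Optional, Union

import yaml

from .core import FamilyModel, OIRScale, PsychophysicalLaw, cos_alpha_from_slope
from .registry import Registry, load_registry

__all__ = ["available_presets", "load_preset", "preset_oirs"]


def _read_presets(path: Optional[Union[str, Path]] = None) -> dict:
    if path is None:
        source = resources.files("odormix.data").joinpath("family_presets.yaml")
        with resources.as_file(source) as p:
            text = p.read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def available_presets(path: Optional[Union[str, Path]] = None) -> list:
    return sorted(_read_presets(path))


def load_preset(
    name: str,
    registry: Optional[Registry] = None,
    path: Optional[Union[str, Path]] = None,
) -> FamilyModel:
    """Build a FamilyModel from a shipped (or user) preset file."""
    presets = _read_presets(path)
    if name not in presets:
        raise KeyError(
            f"unknown family preset {name!r}; available: {', '.join(sorted(presets))}"
        )
    entry = presets[name]
    registry = registry or load_registry()
    members = {m: registry.get(m) for m in entry["members"]}
    return FamilyModel(
        law=PsychophysicalLaw(k=float(entry["k"]), b=float(entry["b"])),
        cos_alpha=cos_alpha_from_slope(float(entry["slope"])),
        members=members,
        name=name,
    )


def preset_oirs(name: str, path: Optional[Union[str, Path]] = None) -> OIRScale:
    """The odor intensity referencing scale a preset family was rated on."""
    presets = _read_presets(path)
    entry = presets[name]["oirs"]
    return OIRScale(
        base_concentration=float(entry["base_concentration"]),
        ratio=float(entry["ratio"]),
        n_levels=int(entry["n_levels"]),
    )
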