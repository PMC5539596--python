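"""Odorant registry: names, CAS numbers, odor thresholds, family tags.

The packaged registry ships panel-measured odor thresholds for the eight
odorants the model family presets were calibrated on (three aldehydes,
five esters). Users can load their own registry CSV with the same columns
(name, abbreviation, cas, odor_threshold_mg_m3, family) or extend a loaded
registry with :meth:`Registry.add`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Union

import pandas as pd

from .core import Odorant

__all__ = ["Registry", "load_registry", "REGISTRY_COLUMNS"]

REGISTRY_COLUMNS = ["name", "abbreviation", "cas", "odor_threshold_mg_m3", "family"]


class Registry:
    """Mapping from odorant name (or abbreviation) to :class:`Odorant`."""

    def __init__(self, odorants: Optional[List[Odorant]] = None) -> None:
        self._by_name: Dict[str, Odorant] = {}
        self._by_abbrev: Dict[str, Odorant] = {}
        for od in odorants or []:
            self.add(od)

    def add(self, odorant: Odorant) -> None:
        if odorant.name in self._by_name:
            raise ValueError(f"duplicate odorant name {odorant.name!r}")
        if odorant.abbreviation and odorant.abbreviation in self._by_abbrev:
            raise ValueError(f"duplicate abbreviation {odorant.abbreviation!r}")
        self._by_name[odorant.name] = odorant
        if odorant.abbreviation:
            self._by_abbrev[odorant.abbreviation] = odorant

    def get(self, key: str) -> Odorant:
        """Resolve by full name first, then by abbreviation."""
        if key in self._by_name:
            return self._by_name[key]
        if key in self._by_abbrev:
            return self._by_abbrev[key]
        raise KeyError(f"odorant {key!r} not in registry")

    def __contains__(self, key: str) -> bool:
        return key in self._by_name or key in self._by_abbrev

    def __iter__(self) -> Iterator[Odorant]:
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    def family(self, family: str) -> List[Odorant]:
        return [od for od in self if od.family == family]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": od.name,
                    "abbreviation": od.abbreviation,
                    "cas": od.cas,
                    "odor_threshold_mg_m3": od.odor_threshold,
                    "family": od.family,
                }
                for od in self
            ]
        )


def load_registry(path: Optional[Union[str, Path]] = None) -> Registry:
    """Load a registry CSV; with no path, the packaged default thresholds."""
    if path is None:
        source = resources.files("odormix.data").joinpath("odorants.csv")
        with resources.as_file(source) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"registry CSV missing column(s): {', '.join(missing)}")
    reg = Registry()
    for row in df.itertuples(index=False):
        reg.add(
            Odorant(
                name=str(row.name),
                cas=str(row.cas),
                odor_threshold=float(row.odor_threshold_mg_m3),
                abbreviation="" if pd.isna(row.abbreviation) else str(row.abbreviation),
                family="" if pd.isna(row.family) else str(row.family),
            )
        )
    return reg
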