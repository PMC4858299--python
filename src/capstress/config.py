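"""YAML run configuration mirroring the morphology / crystal / run schema.

Schema (all keys optional; defaults are the printed study conditions)::

    morphology:
      cap_thickness: 0.091      # mm
      lumen_area: 5.77          # mm^2
      core_arc: 84.65           # degrees
      core_area: 2.22           # mm^2
      stenosis_severity: 0.7053
      wall_thickness: null      # mm; null -> derived
    crystals:
      - location: shoulder      # shoulder | halfway | center
        length_um: 269.1
        thickness_um: 3.0
        expansion_um: 2.0
    pressure_kpa: 14.6
    refinement: 1
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .fem import PRESSURE_KPA
from .geometry import CrystalSpec, MorphologyParams


@dataclass
class RunConfig:
    morphology: MorphologyParams = field(default_factory=MorphologyParams)
    crystals: tuple[CrystalSpec, ...] = ()
    pressure_kpa: float = PRESSURE_KPA
    refinement: int = 1


def crystal_from_dict(d: dict) -> CrystalSpec:
    return CrystalSpec(
        location=d["location"],
        length=d.get("length_um", 269.1) * 1e-3,
        thickness=d.get("thickness_um", 3.0) * 1e-3,
        expansion_d=d.get("expansion_um", 2.0),
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    morph = MorphologyParams(**raw.get("morphology", {}))
    crystals = tuple(crystal_from_dict(c) for c in raw.get("crystals", []))
    return RunConfig(
        morphology=morph,
        crystals=crystals,
        pressure_kpa=float(raw.get("pressure_kpa", PRESSURE_KPA)),
        refinement=int(raw.get("refinement", 1)),
    )
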