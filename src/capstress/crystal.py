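"""Cholesterol-crystal loading: material assignment and eigenstrain.

Crystal growth by ``d`` micrometres in the thickness (radial) direction is
modeled as a stress-free eigenstrain eps* = d / thickness in the crystal
band, the thermal-expansion analogy: a free crystal would expand by exactly
``d``, while an embedded one loads the surrounding cap through its own
stiffness.  Eigenstrain forces are exactly proportional to ``d``, so
superposition applies across expansion magnitudes and crystals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fem import CRYSTAL, IsotropicMaterial
from .geometry import CrystalSpec, QuadMesh


@dataclass
class CrystalLoad:
    """Element set + local eigenstrain + crystal material for one crystal."""

    elements: np.ndarray
    eigenstrain: np.ndarray  # (3,): (eps_rr, eps_tt, gamma_rt) in the polar frame
    material: IsotropicMaterial = CRYSTAL


def place_crystal(mesh: QuadMesh, spec: CrystalSpec) -> np.ndarray:
    """Element indices of the crystal band at ``spec.location``.

    The mesh must have been built with a crystal slot at that location
    (crystals change the discretization tagging, not the node layout).
    """
    try:
        elems = mesh.crystal_elements[spec.location]
    except KeyError:
        raise KeyError(
            f"mesh has no crystal band at '{spec.location}'; rebuild the mesh "
            f"with this crystal in its spec list"
        ) from None
    if len(elems) == 0:
        raise KeyError(f"crystal band at '{spec.location}' is empty")
    return elems


def expansion_to_eigenstrain(spec: CrystalSpec) -> np.ndarray:
    """Local eigenstrain vector for a thickness-direction expansion.

    eps*_rr = expansion_d / thickness (expansion_d in um, thickness in mm);
    tangential and shear components are zero.
    """
    d_mm = spec.expansion_d * 1e-3
    return np.array([d_mm / spec.thickness, 0.0, 0.0])


def make_crystal_load(mesh: QuadMesh, spec: CrystalSpec, E_scale: float = 1.0) -> CrystalLoad:
    """Bundle placement, eigenstrain and (optionally rescaled) material."""
    elems = place_crystal(mesh, spec)
    mat = CRYSTAL if E_scale == 1.0 else replace(CRYSTAL, E=CRYSTAL.E * E_scale)
    return CrystalLoad(elements=elems, eigenstrain=expansion_to_eigenstrain(spec), material=mat)


def eigenstrain_map(mesh: QuadMesh, loads: list[CrystalLoad]) -> dict[int, np.ndarray]:
    """Per-element local eigenstrains for the solver's load case."""
    out: dict[int, np.ndarray] = {}
    for load in loads:
        for e in load.elements:
            out[int(e)] = load.eigenstrain
    return out
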