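"""Idealized atherosclerotic coronary cross-section and its Q8 mesh.

The model is a concentric half cross-section: a circular lumen inside an
annular vessel, a soft necrotic core shaped as an annular sector abluminal of
the thin fibrous cap, and the fibrous plaque filling the remaining annulus
between lumen and the outer arterial wall.  All dimensions derive in closed
form from the printed morphometrics: lumen area, cap thickness, core arc and
area, and the area-stenosis severity (which pins the outer vessel radius via
the reference external-elastic-membrane area).

Cholesterol crystals are thin tangential bands of elements occupying the
abluminal-most sub-layer of the cap (the cap-core interface), at one of three
angular stations measured from the cap center on the symmetry axis:
``center`` (0), ``halfway`` (half the half-core-arc) and ``shoulder`` (the
core-arc end).

Units: mm for lengths, mm^2 for areas, degrees for angles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import quad8
from .vtkio import write_vtk

#: printed fibrous-cap thickness range, mm
CAP_THICKNESS_RANGE_MM = (0.025, 0.370)

#: angular stations as fractions of the half-core-arc off the symmetry line
CRYSTAL_LOCATIONS = {"center": 0.0, "halfway": 0.5, "shoulder": 1.0}


class GeometryError(ValueError):
    """Raised when the printed morphometrics cannot be realized geometrically."""


class MeshValidationError(ValueError):
    """Raised by :func:`validate_mesh` when a mesh invariant is violated."""


@dataclass(frozen=True)
class MorphologyParams:
    """Morphometric parameters of the idealized cross-section.

    Defaults are the printed population means.  ``relative_core_area``,
    ``relative_core_thickness`` are retained as reported diagnostics; the
    geometry is pinned by the primary parameters (lumen area, cap thickness,
    core arc/area, stenosis severity).  ``wall_thickness`` (media+adventitia
    outside the plaque bed) defaults to the gap between the core outer radius
    and the vessel outer radius; pass a value to override.
    """

    cap_thickness: float = 0.091  # mm
    lumen_area: float = 5.77  # mm^2
    core_arc: float = 84.65  # degrees
    core_area: float = 2.22  # mm^2
    relative_core_area: float = 0.1917
    relative_core_thickness: float = 0.4941
    stenosis_severity: float = 0.7053
    wall_thickness: float | None = None  # mm

    def __post_init__(self) -> None:
        for name in ("cap_thickness", "lumen_area", "core_area"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("relative_core_area", "relative_core_thickness", "stenosis_severity"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if not 0 < self.core_arc < 360:
            raise ValueError("core_arc must lie in (0, 360) degrees")
        if self.wall_thickness is not None and self.wall_thickness <= 0:
            raise ValueError("wall_thickness must be > 0")


@dataclass(frozen=True)
class DerivedGeometry:
    """Radii (mm) derived from :class:`MorphologyParams` in closed form."""

    lumen_radius: float
    core_inner_radius: float
    core_outer_radius: float
    vessel_outer_radius: float
    reference_area: float  # EEM area, pi * vessel_outer_radius^2
    plaque_outer_radius: float  # plaque/artery interface radius

    def __post_init__(self) -> None:
        if not (
            0
            < self.lumen_radius
            < self.core_inner_radius
            < self.core_outer_radius
            <= self.plaque_outer_radius
            < self.vessel_outer_radius
        ):
            raise GeometryError("radii must satisfy lumen < core_in < core_out <= plaque_out < vessel_out")


@dataclass(frozen=True)
class CrystalSpec:
    """One cholesterol crystal: placement, plate dimensions and expansion.

    ``expansion_d`` is the crystallization growth in the thickness (radial)
    direction, in micrometres; dimensions are the measured cohort means.
    """

    location: str
    length: float = 0.2691  # mm
    thickness: float = 0.0030  # mm
    expansion_d: float = 2.0  # um

    def __post_init__(self) -> None:
        if self.location not in CRYSTAL_LOCATIONS:
            raise ValueError(f"location must be one of {sorted(CRYSTAL_LOCATIONS)}")
        if not self.length > self.thickness > 0:
            raise ValueError("need length > thickness > 0")
        if self.expansion_d < 0:
            raise ValueError("expansion_d must be >= 0")


@dataclass
class EdgeGroup:
    """Quadratic boundary edges: node triples (end, mid, end) + parent elements."""

    nodes: np.ndarray  # (n_edges, 3)
    elements: np.ndarray  # (n_edges,)


@dataclass
class QuadMesh:
    """Half-model mesh of 8-node serendipity quadrilaterals."""

    nodes: np.ndarray  # (N, 2) mm
    elements: np.ndarray  # (E, 8) node indices, corners then midsides, CCW
    region: np.ndarray  # (E,) in {artery, plaque, core, crystal}
    edge_groups: dict[str, EdgeGroup]
    geometry: DerivedGeometry | None = None
    params: MorphologyParams | None = None
    d_theta: float | None = None  # angular element width, radians
    crystal_elements: dict[str, np.ndarray] = field(default_factory=dict)
    crystal_specs: dict[str, CrystalSpec] = field(default_factory=dict)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_coords(self) -> np.ndarray:
        """Node coordinates gathered per element, shape (E, 8, 2)."""
        return self.nodes[self.elements]

    def to_vtk(self, path) -> None:
        write_vtk(path, self.nodes, self.elements, cell_data={"region": self.region})


def derive_geometry(params: MorphologyParams) -> DerivedGeometry:
    """Closed-form radii from the printed morphometrics.

    * lumen radius from the lumen area;
    * core inner radius = lumen radius + cap thickness;
    * core outer radius from inverting the annular-sector area
      (arc/360) * pi * (r_out^2 - r_in^2) = core_area;
    * vessel outer radius from area stenosis
      1 - lumen_area / (pi * r_vessel^2) = stenosis_severity.
    """
    r_lumen = math.sqrt(params.lumen_area / math.pi)
    r_core_in = r_lumen + params.cap_thickness
    r_core_out = math.sqrt(r_core_in**2 + params.core_area * 360.0 / (params.core_arc * math.pi))
    reference_area = params.lumen_area / (1.0 - params.stenosis_severity)
    r_vessel = math.sqrt(reference_area / math.pi)
    if params.wall_thickness is None:
        r_plaque_out = r_core_out
    else:
        r_plaque_out = r_vessel - params.wall_thickness
    if not r_core_out <= r_plaque_out < r_vessel:
        raise GeometryError(
            "core area is unachievable for the given arc and radii: the core "
            f"annulus (outer radius {r_core_out:.4f} mm) does not fit inside the "
            f"plaque bed (outer radius {r_plaque_out:.4f} mm, vessel {r_vessel:.4f} mm)"
        )
    return DerivedGeometry(
        lumen_radius=r_lumen,
        core_inner_radius=r_core_in,
        core_outer_radius=r_core_out,
        vessel_outer_radius=r_vessel,
        reference_area=reference_area,
        plaque_outer_radius=r_plaque_out,
    )


def geometry_diagnostics(params: MorphologyParams, geom: DerivedGeometry | None = None) -> dict:
    """Achieved relative core metrics, reported as diagnostics (not constraints)."""
    geom = geom or derive_geometry(params)
    plaque_bed_area = geom.reference_area - params.lumen_area
    core_thickness = geom.core_outer_radius - geom.core_inner_radius
    plaque_thickness = geom.plaque_outer_radius - geom.lumen_radius
    return {
        "relative_core_area_achieved": params.core_area / plaque_bed_area,
        "relative_core_thickness_achieved": core_thickness / plaque_thickness,
        "wall_thickness": geom.vessel_outer_radius - geom.plaque_outer_radius,
    }


# ---------------------------------------------------------------------------
# structured annulus meshing


def _structured_annulus(radial_bands, theta_boundaries):
    """Structured polar mesh of stacked annular bands over a column grid.

    ``radial_bands`` is a list of (r0, r1, n_layers, band_name); bands must be
    contiguous.  ``theta_boundaries`` is the (possibly non-uniform) array of
    column-edge angles in radians, starting at 0.  Returns (nodes, elements,
    band_of_ring, ring_idx, col_idx, edge_groups).  Midside nodes are placed
    on the circular arcs so element edges follow the annulus boundaries
    exactly (to quadratic order).
    """
    r_half = [radial_bands[0][0]]
    band_of_ring: list[str] = []
    for r0, r1, nlay, name in radial_bands:
        if abs(r0 - r_half[-1]) > 1e-12:
            raise GeometryError("radial bands must be contiguous")
        for k in range(nlay):
            r_half.append(r0 + (r1 - r0) * (2 * k + 1) / (2 * nlay))
            r_half.append(r0 + (r1 - r0) * (2 * k + 2) / (2 * nlay))
            band_of_ring.append(name)
    r_half = np.asarray(r_half)
    nr = len(band_of_ring)
    theta_boundaries = np.asarray(theta_boundaries, dtype=float)
    nt = len(theta_boundaries) - 1
    span = float(theta_boundaries[-1])
    th_half = np.empty(2 * nt + 1)
    th_half[0::2] = theta_boundaries
    th_half[1::2] = 0.5 * (theta_boundaries[:-1] + theta_boundaries[1:])

    node_id = -np.ones((2 * nr + 1, 2 * nt + 1), dtype=int)
    coords = []
    nid = 0
    for i in range(2 * nr + 1):
        for j in range(2 * nt + 1):
            if i % 2 == 1 and j % 2 == 1:
                continue  # serendipity: no interior-center nodes
            r, th = r_half[i], th_half[j]
            x, y = r * math.cos(th), r * math.sin(th)
            if j == 0 or (j == 2 * nt and abs(span - math.pi) < 1e-14):
                y = 0.0  # snap symmetry-line nodes exactly onto the axis
            node_id[i, j] = nid
            coords.append((x, y))
            nid += 1
    nodes = np.array(coords)

    elements = np.empty((nr * nt, 8), dtype=int)
    ring_idx = np.empty(nr * nt, dtype=int)
    col_idx = np.empty(nr * nt, dtype=int)
    e = 0
    for i in range(nr):
        for j in range(nt):
            I, J = 2 * i, 2 * j
            elements[e] = [
                node_id[I, J],
                node_id[I + 2, J],
                node_id[I + 2, J + 2],
                node_id[I, J + 2],
                node_id[I + 1, J],
                node_id[I + 2, J + 1],
                node_id[I + 1, J + 2],
                node_id[I, J + 1],
            ]
            ring_idx[e], col_idx[e] = i, j
            e += 1

    def _edges(rows_i, const_axis):
        out_nodes, out_elems = [], []
        if const_axis == "inner":
            for j in range(nt):
                out_nodes.append([node_id[0, 2 * j], node_id[0, 2 * j + 1], node_id[0, 2 * j + 2]])
                out_elems.append(j)
        elif const_axis == "outer":
            for j in range(nt):
                out_nodes.append(
                    [node_id[2 * nr, 2 * j], node_id[2 * nr, 2 * j + 1], node_id[2 * nr, 2 * j + 2]]
                )
                out_elems.append((nr - 1) * nt + j)
        return EdgeGroup(np.array(out_nodes), np.array(out_elems))

    sym_nodes, sym_elems = [], []
    for i in range(nr):
        sym_nodes.append([node_id[2 * i, 0], node_id[2 * i + 1, 0], node_id[2 * i + 2, 0]])
        sym_elems.append(i * nt)
        sym_nodes.append([node_id[2 * i, 2 * nt], node_id[2 * i + 1, 2 * nt], node_id[2 * i + 2, 2 * nt]])
        sym_elems.append(i * nt + nt - 1)
    edge_groups = {
        "lumen_surface": _edges(None, "inner"),
        "outer_boundary": _edges(None, "outer"),
        "symmetry_line": EdgeGroup(np.array(sym_nodes), np.array(sym_elems)),
    }
    return nodes, elements, band_of_ring, ring_idx, col_idx, edge_groups


def annulus_mesh(
    inner_radius: float,
    outer_radius: float,
    n_radial: int,
    n_theta: int,
    region: str = "plaque",
    span: float = math.pi,
) -> QuadMesh:
    """Plain half-annulus mesh (benchmark geometry, e.g. the Lame cylinder)."""
    nodes, elements, _, _, _, edge_groups = _structured_annulus(
        [(inner_radius, outer_radius, n_radial, region)], np.linspace(0.0, span, n_theta + 1)
    )
    return QuadMesh(
        nodes=nodes,
        elements=elements,
        region=np.full(len(elements), region, dtype="<U8"),
        edge_groups=edge_groups,
        d_theta=span / n_theta,
    )


def _crystal_columns(
    spec: CrystalSpec, geom: DerivedGeometry, half_arc_rad: float, col_centers: np.ndarray
) -> np.ndarray:
    """Column indices covered by a crystal band in the slot ring."""
    n_theta = len(col_centers)
    r_mid = geom.core_inner_radius - spec.thickness / 2.0
    width = r_mid * (col_centers[1] - col_centers[0])
    alpha = CRYSTAL_LOCATIONS[spec.location] * half_arc_rad
    if spec.location == "center":
        # the crystal straddles the symmetry line; the half model carries half of it
        n_cols = max(1, math.ceil((spec.length / 2.0) / width))
        start = 0
    else:
        n_cols = max(1, math.ceil(spec.length / width))
        center_col = int(np.argmin(np.abs(col_centers - alpha)))
        start = center_col - (n_cols - 1) // 2
    start = max(0, min(start, n_theta - n_cols))
    return np.arange(start, start + n_cols)


def build_half_model(
    params: MorphologyParams | None = None,
    crystals: tuple[CrystalSpec, ...] | list[CrystalSpec] = (),
    refinement: int = 1,
) -> QuadMesh:
    """Mesh the half cross-section (180 degrees) with graded radial bands.

    Radial bands (lumen outward): inner cap, a one-element-thick crystal slot
    ring at the abluminal cap face, the core band, an optional outer plaque
    band (when ``wall_thickness`` is overridden) and the arterial wall.  At
    ``refinement=1`` the default morphometrics give 72 x 17 = 1224 elements.
    The slot ring exists in every mesh so that control and crystal scenarios
    share an identical discretization; outside crystal bands it is plaque.
    """
    if refinement < 1:
        raise ValueError("refinement must be >= 1")
    params = params or MorphologyParams()
    geom = derive_geometry(params)

    locations = [c.location for c in crystals]
    if len(set(locations)) != len(locations):
        raise GeometryError("crystal locations must be distinct")
    thicknesses = {c.thickness for c in crystals}
    if len(thicknesses) > 1:
        raise GeometryError("all crystals in one mesh must share a thickness (one slot ring)")
    t_slot = thicknesses.pop() if thicknesses else CrystalSpec("shoulder").thickness
    if t_slot >= params.cap_thickness:
        raise GeometryError(
            f"crystal thickness {t_slot} mm exceeds the cap layer budget ({params.cap_thickness} mm)"
        )

    k = refinement
    r_l, r_ci, r_co = geom.lumen_radius, geom.core_inner_radius, geom.core_outer_radius
    r_pa, r_v = geom.plaque_outer_radius, geom.vessel_outer_radius
    bands = [
        (r_l, r_ci - t_slot, 2 * k, "cap"),
        (r_ci - t_slot, r_ci, 1, "slot"),
        (r_ci, r_co, 8 * k, "core_band"),
    ]
    outer_total = 6 * k
    if r_pa > r_co + 1e-12:
        n_pl = max(1, round(outer_total * (r_pa - r_co) / (r_v - r_co)))
        n_art = max(1, outer_total - n_pl)
        bands.append((r_co, r_pa, n_pl, "plaque_out"))
        bands.append((r_pa, r_v, n_art, "artery_band"))
    else:
        bands.append((r_co, r_v, outer_total, "artery_band"))

    n_theta = 72 * k
    d_theta = math.pi / n_theta
    # a column boundary is aligned with the core-arc edge so the core sector
    # is angle-exact for any printed or sampled arc
    half_arc = math.radians(params.core_arc / 2.0)
    n_core_cols = min(n_theta - 1, max(1, round(half_arc / d_theta)))
    boundaries = np.concatenate(
        [
            np.linspace(0.0, half_arc, n_core_cols + 1),
            np.linspace(half_arc, math.pi, n_theta - n_core_cols + 1)[1:],
        ]
    )
    nodes, elements, band_of_ring, ring_idx, col_idx, edge_groups = _structured_annulus(
        bands, boundaries
    )

    col_centers = 0.5 * (boundaries[:-1] + boundaries[1:])
    spans = {c.location: _crystal_columns(c, geom, half_arc, col_centers) for c in crystals}
    claimed: set[int] = set()
    for loc, cols in spans.items():
        if claimed & set(cols.tolist()):
            raise GeometryError("crystal bands overlap; move the crystals apart or refine the mesh")
        claimed |= set(cols.tolist())

    band_arr = np.array([band_of_ring[i] for i in ring_idx])
    theta_mid = col_centers[col_idx]
    region = np.full(len(elements), "plaque", dtype="<U8")
    region[(band_arr == "core_band") & (theta_mid < half_arc)] = "core"
    region[band_arr == "artery_band"] = "artery"

    crystal_elements: dict[str, np.ndarray] = {}
    slot = band_arr == "slot"
    for loc, cols in spans.items():
        in_band = slot & np.isin(col_idx, cols)
        region[in_band] = "crystal"
        crystal_elements[loc] = np.flatnonzero(in_band)

    return QuadMesh(
        nodes=nodes,
        elements=elements,
        region=region,
        edge_groups=edge_groups,
        geometry=geom,
        params=params,
        d_theta=d_theta,
        crystal_elements=crystal_elements,
        crystal_specs={c.location: c for c in crystals},
    )


# ---------------------------------------------------------------------------
# validation


@dataclass
class MeshDiagnostics:
    min_jacobian: float
    total_area: float
    total_area_error: float | None
    region_areas: dict[str, float]
    region_area_errors: dict[str, float]
    negative_jacobian_elements: list[int]
    nonconforming_edges: list[tuple[int, int]]

    @property
    def ok(self) -> bool:
        return (
            self.min_jacobian > 0
            and not self.nonconforming_edges
            and all(abs(v) <= 0.02 for v in self.region_area_errors.values())
        )


def validate_mesh(mesh: QuadMesh, raise_on_fail: bool = True) -> MeshDiagnostics:
    """Check mesh invariants: positive Jacobians, conformity, region areas.

    Region areas are compared with their closed-form targets (half-model:
    half the printed core area, etc.) when the mesh carries its generating
    geometry; tolerance 2% per region.
    """
    if mesh.nodes is None or len(mesh.elements) == 0:
        raise MeshValidationError("empty mesh")
    coords = mesh.element_coords()
    _, detJ = quad8.jacobians(coords)
    bad = np.flatnonzero(detJ.min(axis=1) <= 0).tolist()
    areas = quad8.element_areas(coords)

    region_areas = {tag: float(areas[mesh.region == tag].sum()) for tag in np.unique(mesh.region)}
    region_errors: dict[str, float] = {}
    total_error = None
    if mesh.geometry is not None and mesh.params is not None:
        g, p = mesh.geometry, mesh.params
        total_target = math.pi * (g.vessel_outer_radius**2 - g.lumen_radius**2) / 2.0
        total_error = (float(areas.sum()) - total_target) / total_target
        targets = {
            "core": p.core_area / 2.0,
            "artery": math.pi * (g.vessel_outer_radius**2 - g.plaque_outer_radius**2) / 2.0,
        }
        targets["plaque"] = total_target - targets["core"] - targets["artery"]
        meshed_plaque = region_areas.get("plaque", 0.0) + region_areas.get("crystal", 0.0)
        for tag, target in targets.items():
            meshed = meshed_plaque if tag == "plaque" else region_areas.get(tag, 0.0)
            region_errors[tag] = (meshed - target) / target

    # conformity: every shared corner pair must map to a single midside node
    edge_mid: dict[tuple[int, int], int] = {}
    nonconforming: list[tuple[int, int]] = []
    for conn in mesh.elements:
        for c0, m, c1 in conn[quad8.EDGES]:
            key = (min(c0, c1), max(c0, c1))
            if key in edge_mid and edge_mid[key] != m:
                nonconforming.append(key)
            edge_mid[key] = m

    diag = MeshDiagnostics(
        min_jacobian=float(detJ.min()),
        total_area=float(areas.sum()),
        total_area_error=total_error,
        region_areas=region_areas,
        region_area_errors=region_errors,
        negative_jacobian_elements=bad,
        nonconforming_edges=nonconforming,
    )
    if raise_on_fail and not diag.ok:
        parts = []
        if bad:
            parts.append(f"non-positive Jacobian in elements {bad[:10]}")
        if nonconforming:
            parts.append(f"non-conforming edges {nonconforming[:10]}")
        for tag, err in diag.region_area_errors.items():
            if abs(err) > 0.02:
                parts.append(f"region {tag} area off target by {100 * err:.2f}%")
        raise MeshValidationError("; ".join(parts) or "mesh validation failed")
    return diag
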