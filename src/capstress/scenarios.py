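"""Scenario roster, PCS extraction and the expansion/pressure/stiffness sweeps.

Peak circumferential stress (PCS) is the rupture-risk surrogate: the maximum
hoop stress over fibrous-cap recovery points — plaque-region nodes radially
between the lumen surface and the core, angularly within the core-arc span
plus one element margin.  Interface nodes (cap/core, cap/crystal) carry a
cap-side value because stress averaging never crosses regions.

The eight-scenario roster: crystal-free control, three single-crystal cases
(shoulder, halfway, center), three two-crystal cases and one three-crystal
case, each crystal expanding 2 um unless stated otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import fem
from .crystal import eigenstrain_map, make_crystal_load
from .fem import (
    CRYSTAL,
    DEFAULT_MATERIALS,
    MMHG_TO_KPA,
    PRESSURE_KPA,
    DisplacementField,
    StaticSolver,
    StressField,
    pressure_load,
    recover_stress,
)
from .geometry import CrystalSpec, MorphologyParams, QuadMesh, build_half_model

#: default expansion (um) for the location-comparison and multi-crystal cases
DEFAULT_EXPANSION_UM = 2.0

#: default expansion sweep grid, um
DEFAULT_D_GRID = tuple(np.linspace(0.0, 400.0, 21))

#: default pressure sweep, kPa (printed 70 and 200 mmHg endpoints)
DEFAULT_PRESSURES_KPA = tuple(MMHG_TO_KPA[m] for m in (70, 90, 110, 130, 150, 170, 200))

#: default crystal-stiffness factors: -50% to +1000% of 100 kPa
DEFAULT_E_FACTORS = (0.5, 1.0, 2.0, 5.0, 11.0)


@dataclass(frozen=True)
class Scenario:
    name: str
    params: MorphologyParams = field(default_factory=MorphologyParams)
    crystals: tuple[CrystalSpec, ...] = ()
    pressure: float = PRESSURE_KPA  # kPa
    crystal_E_scale: float = 1.0
    refinement: int = 1


@dataclass
class PCSResult:
    pcs: float  # kPa
    r_mm: float
    theta_deg: float
    region: str
    node: int
    percent_change_vs_control: float | None = None


@dataclass
class ScenarioResult:
    scenario: Scenario
    pcs: PCSResult
    stress: StressField
    displacements: DisplacementField
    mesh: QuadMesh


@dataclass
class SweepResult:
    x: np.ndarray
    pcs: np.ndarray
    slope: float
    intercept: float
    relative_residual: float
    argmax_constant: bool
    locations: list[tuple[float, float]]  # (r_mm, theta_deg) per point


def extract_pcs(mesh: QuadMesh, stress: StressField) -> PCSResult:
    """Maximum sigma_tt over the cap search domain; arg-max location."""
    geom, params = mesh.geometry, mesh.params
    if geom is None or params is None or mesh.d_theta is None:
        raise ValueError("PCS extraction needs a mesh built from morphology parameters")
    half_arc = params.core_arc / 2.0
    margin = math.degrees(mesh.d_theta)
    mask = (
        (stress.region == "plaque")
        & (stress.r >= geom.lumen_radius - 1e-9)
        & (stress.r <= geom.core_inner_radius + 1e-9)
        & (stress.theta_deg <= half_arc + margin + 1e-12)
    )
    if not mask.any():
        raise ValueError("no cap recovery points found")
    idx = np.flatnonzero(mask)
    best = idx[np.argmax(stress.sigma[idx, 1])]
    return PCSResult(
        pcs=float(stress.sigma[best, 1]),
        r_mm=float(stress.r[best]),
        theta_deg=float(stress.theta_deg[best]),
        region=str(stress.region[best]),
        node=int(stress.node_index[best]),
    )


def percent_change(pcs: float, control_pcs: float) -> float:
    """100 * (pcs - control) / control."""
    if control_pcs <= 0:
        raise ValueError("control PCS must be > 0")
    return 100.0 * (pcs - control_pcs) / control_pcs


def _materials_for(scale: float) -> dict:
    mats = dict(DEFAULT_MATERIALS)
    if scale != 1.0:
        mats["crystal"] = replace(CRYSTAL, E=CRYSTAL.E * scale)
    return mats


def run_scenario(s: Scenario, control_pcs: float | None = None) -> ScenarioResult:
    """Build the mesh, assign materials, load, solve and extract PCS."""
    mesh = build_half_model(s.params, s.crystals, s.refinement)
    loads = [make_crystal_load(mesh, c, s.crystal_E_scale) for c in s.crystals]
    eig = eigenstrain_map(mesh, loads)
    solver = StaticSolver(mesh, _materials_for(s.crystal_E_scale))
    f = pressure_load(mesh, s.pressure) + solver.operator.eigenstrain_force(eig)
    u = DisplacementField(u=solver.solve(f))
    stress = recover_stress(mesh, None, u, eigenstrains=eig, operator=solver.operator)
    pcs = extract_pcs(mesh, stress)
    if control_pcs is not None:
        pcs.percent_change_vs_control = percent_change(pcs.pcs, control_pcs)
    return ScenarioResult(scenario=s, pcs=pcs, stress=stress, displacements=u, mesh=mesh)


def crystal_collocated(mesh: QuadMesh, location: str, pcs: PCSResult) -> bool:
    """Is the PCS arg-max within one element width of the crystal band?"""
    elems = mesh.crystal_elements[location]
    crystal_nodes = np.unique(mesh.elements[elems])
    d = np.min(np.hypot(*(mesh.nodes[crystal_nodes] - mesh.nodes[int(pcs.node)]).T))
    width = mesh.geometry.core_inner_radius * mesh.d_theta
    return bool(d <= 1.5 * width)


def default_scenarios(
    params: MorphologyParams | None = None,
    expansion_d: float = DEFAULT_EXPANSION_UM,
    pressure: float = PRESSURE_KPA,
    refinement: int = 1,
) -> list[Scenario]:
    """The eight-scenario roster in its fixed reporting order."""
    params = params or MorphologyParams()

    def spec(loc: str) -> CrystalSpec:
        return CrystalSpec(location=loc, expansion_d=expansion_d)

    combos = [
        ("control", ()),
        ("shoulder", ("shoulder",)),
        ("halfway", ("halfway",)),
        ("center", ("center",)),
        ("shoulder+halfway", ("shoulder", "halfway")),
        ("halfway+center", ("halfway", "center")),
        ("shoulder+center", ("shoulder", "center")),
        ("three_crystals", ("shoulder", "halfway", "center")),
    ]
    return [
        Scenario(
            name=name,
            params=params,
            crystals=tuple(spec(l) for l in locs),
            pressure=pressure,
            refinement=refinement,
        )
        for name, locs in combos
    ]


# ---------------------------------------------------------------------------
# sweeps


def _sweep_solver(scenario: Scenario):
    """Shared factorization + unit loads for sweeps over d or pressure."""
    mesh = build_half_model(scenario.params, scenario.crystals, scenario.refinement)
    solver = StaticSolver(mesh, _materials_for(scenario.crystal_E_scale))
    f_pressure_unit = pressure_load(mesh, 1.0)
    unit_specs = [replace(c, expansion_d=1.0) for c in scenario.crystals]
    loads = [make_crystal_load(mesh, c, scenario.crystal_E_scale) for c in unit_specs]
    eig_unit = eigenstrain_map(mesh, loads)
    f_eig_unit = solver.operator.eigenstrain_force(eig_unit)
    return mesh, solver, f_pressure_unit, eig_unit, f_eig_unit


def _fit(x: np.ndarray, pcs: np.ndarray, locations) -> SweepResult:
    slope, intercept = np.polyfit(x, pcs, 1)
    fit = slope * x + intercept
    scale = max(np.max(np.abs(pcs)), 1e-30)
    rel = float(np.max(np.abs(pcs - fit)) / scale)
    argmax_constant = len({(round(r, 9), round(t, 9)) for r, t in locations}) == 1
    return SweepResult(
        x=np.asarray(x, dtype=float),
        pcs=pcs,
        slope=float(slope),
        intercept=float(intercept),
        relative_residual=rel,
        argmax_constant=argmax_constant,
        locations=list(locations),
    )


def expansion_sweep(
    location: str = "shoulder",
    d_values=DEFAULT_D_GRID,
    pressure: float = PRESSURE_KPA,
    params: MorphologyParams | None = None,
    refinement: int = 1,
) -> SweepResult:
    """PCS versus crystal expansion d (um) for one crystal; least-squares slope.

    By superposition PCS(d) is exactly affine as long as the arg-max stays at
    one spatial point; ``argmax_constant`` reports whether it did.
    """
    d_values = np.asarray(list(d_values), dtype=float)
    if len(d_values) < 2 or len(np.unique(d_values)) < 2:
        raise ValueError("need at least two distinct expansion values")
    scenario = Scenario(
        name=f"sweep-{location}",
        params=params or MorphologyParams(),
        crystals=(CrystalSpec(location=location),),
        pressure=pressure,
        refinement=refinement,
    )
    mesh, solver, f_p1, eig_unit, f_e1 = _sweep_solver(scenario)
    f_p = pressure * f_p1
    pcs_vals, locations = [], []
    for d in d_values:
        u = DisplacementField(solver.solve(f_p + d * f_e1))
        eig = {e: d * v for e, v in eig_unit.items()}
        stress = recover_stress(mesh, None, u, eigenstrains=eig, operator=solver.operator)
        res = extract_pcs(mesh, stress)
        pcs_vals.append(res.pcs)
        locations.append((res.r_mm, res.theta_deg))
    return _fit(d_values, np.array(pcs_vals), locations)


@dataclass
class PressureSweepResult:
    pressures_kpa: np.ndarray
    pcs_with_crystal: np.ndarray
    pcs_baseline: np.ndarray  # same model, expansion 0
    collocated: list[bool]
    locations: list[tuple[float, float]]


def pressure_sweep(
    scenario: Scenario | None = None,
    pressures_kpa=DEFAULT_PRESSURES_KPA,
) -> PressureSweepResult:
    """PCS versus luminal pressure, with the scenario's crystals and at d = 0."""
    scenario = scenario or Scenario(
        name="pressure-sweep", crystals=(CrystalSpec("shoulder", expansion_d=DEFAULT_EXPANSION_UM),)
    )
    pressures = np.asarray(list(pressures_kpa), dtype=float)
    mesh, solver, f_p1, eig_unit, f_e1 = _sweep_solver(scenario)
    # per-element d: crystals may in principle carry distinct expansions
    f_e = np.zeros_like(f_e1)
    eig = {}
    for c in scenario.crystals:
        loads = [make_crystal_load(mesh, replace(c, expansion_d=1.0), scenario.crystal_E_scale)]
        em = eigenstrain_map(mesh, loads)
        f_e += c.expansion_d * solver.operator.eigenstrain_force(em)
        eig.update({e: c.expansion_d * v for e, v in em.items()})
    pcs_with, pcs_base, colloc, locs = [], [], [], []
    for P in pressures:
        u = DisplacementField(solver.solve(P * f_p1 + f_e))
        stress = recover_stress(mesh, None, u, eigenstrains=eig, operator=solver.operator)
        res = extract_pcs(mesh, stress)
        pcs_with.append(res.pcs)
        locs.append((res.r_mm, res.theta_deg))
        if scenario.crystals:
            colloc.append(
                any(crystal_collocated(mesh, c.location, res) for c in scenario.crystals)
            )
        u0 = DisplacementField(solver.solve(P * f_p1))
        stress0 = recover_stress(mesh, None, u0, eigenstrains=None, operator=solver.operator)
        pcs_base.append(extract_pcs(mesh, stress0).pcs)
    return PressureSweepResult(
        pressures_kpa=pressures,
        pcs_with_crystal=np.array(pcs_with),
        pcs_baseline=np.array(pcs_base),
        collocated=colloc,
        locations=locs,
    )


def sensitivity_sweep(
    scenarios: list[Scenario] | None = None,
    factors=DEFAULT_E_FACTORS,
) -> tuple[float, pd.DataFrame]:
    """Max relative PCS deviation (%) under crystal-stiffness scaling.

    For every scenario, the crystal Young's modulus is scaled by each factor
    and the deviation 100 |PCS(f) - PCS(1)| / PCS(1) recorded; returns the
    maximum over factors and scenarios plus the full table.
    """
    scenarios = scenarios if scenarios is not None else default_scenarios()
    factors = list(factors)
    if 1.0 not in factors:
        factors = [1.0] + factors
    rows = []
    for s in scenarios:
        base = run_scenario(replace(s, crystal_E_scale=1.0)).pcs.pcs
        sweep_factors = factors if s.crystals else [1.0]  # no crystal: E-scale is a no-op
        for fct in sweep_factors:
            pcs = base if fct == 1.0 else run_scenario(replace(s, crystal_E_scale=fct)).pcs.pcs
            rows.append(
                {
                    "scenario": s.name,
                    "factor": fct,
                    "pcs_kpa": pcs,
                    "deviation_pct": 100.0 * abs(pcs - base) / base,
                }
            )
    table = pd.DataFrame(rows)
    return float(table["deviation_pct"].max()), table


def run_all(
    params: MorphologyParams | None = None,
    expansion_d: float = DEFAULT_EXPANSION_UM,
    pressure: float = PRESSURE_KPA,
    refinement: int = 1,
    out_dir=None,
) -> pd.DataFrame:
    """Run the eight-scenario roster; one CSV row per scenario.

    Per-scenario failures are caught and reported in the table rather than
    aborting the batch.  Output is deterministic for identical inputs.
    """
    scenarios = default_scenarios(params, expansion_d, pressure, refinement)
    rows = []
    control_pcs: float | None = None
    results: list[ScenarioResult | None] = []
    for s in scenarios:
        try:
            res = run_scenario(s, control_pcs=control_pcs)
            if s.name == "control":
                control_pcs = res.pcs.pcs
            rows.append(
                {
                    "scenario": s.name,
                    "pcs_kpa": res.pcs.pcs,
                    "pcs_r_mm": res.pcs.r_mm,
                    "pcs_theta_deg": res.pcs.theta_deg,
                    "pct_change": res.pcs.percent_change_vs_control
                    if res.pcs.percent_change_vs_control is not None
                    else 0.0,
                    "error": "",
                }
            )
            results.append(res)
        except Exception as exc:  # keep the batch alive, report the failure
            rows.append(
                {
                    "scenario": s.name,
                    "pcs_kpa": float("nan"),
                    "pcs_r_mm": float("nan"),
                    "pcs_theta_deg": float("nan"),
                    "pct_change": float("nan"),
                    "error": f"{type(exc).__name__}: {exc}",
                }
            )
            results.append(None)
    table = pd.DataFrame(rows)
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "results.csv", index=False, float_format="%.8g")
        for res in results:
            if res is not None:
                fem.export_fields(
                    out / f"field_{res.scenario.name.replace('+', '_')}.vtk",
                    res.mesh,
                    res.displacements,
                    res.stress,
                )
    return table
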