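"""Plane-strain linear elasticity on Q8 meshes with polar-orthotropic tissue.

The vessel wall and fibrous plaque are transversely isotropic about the
radial axis (isotropy plane = circumferential/axial), with their stiffness
axes following the polar frame about the lumen center; the necrotic core and
cholesterol crystals are isotropic.  Loading combines a constant luminal
pressure (work-equivalent nodal forces on the quadratic lumen edges) and
stress-free eigenstrains in crystal elements (the thermal-expansion analogy
for crystal growth).  The discrete system is symmetric positive definite
after symmetry constraints and is solved by a sparse direct factorization
with fixed ordering, so results are deterministic across runs.

Units: mm, kPa, giving nodal forces in mN per unit (mm) thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import quad8
from .geometry import QuadMesh
from .vtkio import write_vtk

#: printed mean intracoronary pressure, 110 mmHg
PRESSURE_KPA = 14.6

#: printed mmHg -> kPa pairs used in the pressure sweep (70 and 200 are the
#: printed endpoints; interior values follow the same conversion at one decimal)
MMHG_TO_KPA = {70: 9.3, 90: 12.0, 110: 14.6, 130: 17.3, 150: 20.0, 170: 22.7, 200: 26.6}

REGION_CODES = {"artery": 0, "plaque": 1, "core": 2, "crystal": 3}
_CODE_NAMES = {v: k for k, v in REGION_CODES.items()}


class SingularSystemError(RuntimeError):
    pass


@dataclass(frozen=True)
class TransverselyIsotropicMaterial:
    """Linear elastic solid, isotropic in the theta-z plane, axis along r."""

    E_r: float  # kPa
    E_theta: float  # kPa
    E_z: float  # kPa
    nu_rtheta: float
    nu_thetaz: float
    G_rtheta: float  # kPa

    def __post_init__(self) -> None:
        if min(self.E_r, self.E_theta, self.E_z, self.G_rtheta) <= 0:
            raise ValueError("moduli must be > 0")


@dataclass(frozen=True)
class IsotropicMaterial:
    E: float  # kPa
    nu: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("E must be > 0")
        if not -1 < self.nu < 0.5:
            raise ValueError("nu must lie in (-1, 0.5)")


Material = TransverselyIsotropicMaterial | IsotropicMaterial

# Table of tissue constants used throughout (kPa)
PLAQUE = TransverselyIsotropicMaterial(E_r=50.0, E_theta=1000.0, E_z=1000.0, nu_rtheta=0.01, nu_thetaz=0.27, G_rtheta=500.0)
ARTERY = TransverselyIsotropicMaterial(E_r=10.0, E_theta=100.0, E_z=100.0, nu_rtheta=0.01, nu_thetaz=0.27, G_rtheta=50.0)
NECROTIC_CORE = IsotropicMaterial(E=1.0, nu=0.49)
CRYSTAL = IsotropicMaterial(E=100.0, nu=0.49)

DEFAULT_MATERIALS: dict[str, Material] = {
    "plaque": PLAQUE,
    "artery": ARTERY,
    "core": NECROTIC_CORE,
    "crystal": CRYSTAL,
}


def compliance_matrix(material: Material) -> np.ndarray:
    """Full 3D compliance in Voigt order (rr, tt, zz, tz, rz, rt).

    The unlisted constants follow from transverse isotropy about r:
    nu_rz = nu_rtheta, G_rz = G_rtheta, G_thetaz = E_theta / (2 (1 + nu_thetaz));
    compliance symmetry then gives nu_thetar = nu_rtheta * E_theta / E_r.
    """
    if isinstance(material, IsotropicMaterial):
        E, nu = material.E, material.nu
        Er = Et = Ez = E
        nu_rt = nu_tz = nu
        G_rt = G_rz = G_tz = E / (2 * (1 + nu))
    else:
        Er, Et, Ez = material.E_r, material.E_theta, material.E_z
        nu_rt, nu_tz = material.nu_rtheta, material.nu_thetaz
        G_rt = G_rz = material.G_rtheta
        G_tz = Et / (2 * (1 + nu_tz))
    S = np.zeros((6, 6))
    S[0, 0], S[1, 1], S[2, 2] = 1 / Er, 1 / Et, 1 / Ez
    S[0, 1] = S[1, 0] = -nu_rt / Er
    S[0, 2] = S[2, 0] = -nu_rt / Er  # nu_rz = nu_rtheta
    S[1, 2] = S[2, 1] = -nu_tz / Et
    S[3, 3], S[4, 4], S[5, 5] = 1 / G_tz, 1 / G_rz, 1 / G_rt
    return S


def plane_strain_D(material: Material) -> tuple[np.ndarray, np.ndarray]:
    """In-plane 3x3 stiffness (local r-theta frame) plus the sigma_zz row.

    Builds the 3D compliance, checks positive definiteness, inverts, and
    extracts the plane-strain (eps_z = 0) blocks relating
    (eps_rr, eps_tt, gamma_rt) to (sigma_rr, sigma_tt, sigma_rt) and sigma_zz.
    """
    S = compliance_matrix(material)
    try:
        np.linalg.cholesky(S)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"compliance matrix of {material} is not positive definite") from exc
    C = np.linalg.inv(S)
    idx = [0, 1, 5]
    return C[np.ix_(idx, idx)], C[2, idx]


def strain_rotation(theta: np.ndarray) -> np.ndarray:
    """Voigt strain transformation global (x, y) -> local (r, theta).

    theta is the polar angle of the local radial axis; output shape
    theta.shape + (3, 3) acting on (eps_xx, eps_yy, gamma_xy).
    """
    c, s = np.cos(theta), np.sin(theta)
    T = np.empty(np.shape(theta) + (3, 3))
    T[..., 0, 0], T[..., 0, 1], T[..., 0, 2] = c * c, s * s, c * s
    T[..., 1, 0], T[..., 1, 1], T[..., 1, 2] = s * s, c * c, -c * s
    T[..., 2, 0], T[..., 2, 1], T[..., 2, 2] = -2 * c * s, 2 * c * s, c * c - s * s
    return T


@dataclass
class LoadCase:
    """Pressure on the lumen surface plus crystal eigenstrains.

    ``eigenstrains`` maps element index -> local (rr, tt, rt) stress-free
    strain in the polar frame.  ``extra_fixed`` appends (node, component)
    Dirichlet constraints to the default symmetry set; ``use_symmetry=False``
    drops the default set entirely (benchmarks supply their own constraints).
    """

    pressure: float = PRESSURE_KPA  # kPa
    eigenstrains: dict[int, np.ndarray] = field(default_factory=dict)
    extra_fixed: list[tuple[int, int]] = field(default_factory=list)
    use_symmetry: bool = True
    pressure_group: str = "lumen_surface"

    def __post_init__(self) -> None:
        if self.pressure < 0:
            raise ValueError("pressure must be >= 0")


@dataclass
class DisplacementField:
    u: np.ndarray  # (N, 2), mm


@dataclass
class StressField:
    """Region-wise nodal (or element-center) stresses in cylindrical components."""

    node_index: np.ndarray  # (M,) node id, or element id for center recovery
    region: np.ndarray  # (M,) region tag
    x: np.ndarray
    y: np.ndarray
    r: np.ndarray  # mm, about the lumen center
    theta_deg: np.ndarray  # degrees off the symmetry axis
    sigma: np.ndarray  # (M, 4): sigma_rr, sigma_tt, sigma_rt, sigma_zz (kPa)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "node": self.node_index,
                "region": self.region,
                "x_mm": self.x,
                "y_mm": self.y,
                "r_mm": self.r,
                "theta_deg": self.theta_deg,
                "sigma_rr": self.sigma[:, 0],
                "sigma_tt": self.sigma[:, 1],
                "sigma_rt": self.sigma[:, 2],
                "sigma_zz": self.sigma[:, 3],
            }
        )


# ---------------------------------------------------------------------------
# element-level kernels (vectorized over a stack of elements)


class Operator:
    """Per-mesh cache of B-matrices, local frames and constitutive tensors."""

    def __init__(self, mesh: QuadMesh, materials: dict[str, Material] | None = None):
        self.mesh = mesh
        self.materials = dict(DEFAULT_MATERIALS if materials is None else materials)
        coords = mesh.element_coords()
        self.dN_xy, self.detJ = quad8.cartesian_gradients(coords)
        if np.any(self.detJ <= 0):
            bad = np.flatnonzero(self.detJ.min(axis=1) <= 0)
            raise ValueError(f"singular/inverted Jacobian in elements {bad[:10].tolist()}")
        gp_xy = np.einsum("ga,eaj->egj", quad8.N_GP, coords)
        self.theta_gp = np.arctan2(gp_xy[..., 1], gp_xy[..., 0])

        E = len(mesh.elements)
        self.D_loc = np.empty((E, 3, 3))
        self.zrow = np.empty((E, 3))
        for tag in np.unique(mesh.region):
            if tag not in self.materials:
                raise KeyError(f"no material supplied for region '{tag}'")
            D, z = plane_strain_D(self.materials[tag])
            mask = mesh.region == tag
            self.D_loc[mask] = D
            self.zrow[mask] = z

        self.T = strain_rotation(self.theta_gp)  # (E, 9, 3, 3)
        self.D_glob = np.einsum("egki,ekl,eglj->egij", self.T, self.D_loc, self.T)

        B = np.zeros((E, 9, 3, 16))
        B[..., 0, 0::2] = self.dN_xy[..., 0]
        B[..., 1, 1::2] = self.dN_xy[..., 1]
        B[..., 2, 0::2] = self.dN_xy[..., 1]
        B[..., 2, 1::2] = self.dN_xy[..., 0]
        self.B = B

        self.edofs = np.empty((E, 16), dtype=int)
        self.edofs[:, 0::2] = 2 * mesh.elements
        self.edofs[:, 1::2] = 2 * mesh.elements + 1
        self.ndof = 2 * len(mesh.nodes)

    def element_stiffness_blocks(self) -> np.ndarray:
        DB = np.einsum("egkl,eglj->egkj", self.D_glob, self.B)
        Ke = np.einsum("g,eg,egki,egkj->eij", quad8.WEIGHT_2D, self.detJ, self.B, DB)
        return Ke

    def stiffness_matrix(self) -> sp.csr_matrix:
        Ke = self.element_stiffness_blocks()
        rows = np.repeat(self.edofs[:, :, None], 16, axis=2)
        cols = np.repeat(self.edofs[:, None, :], 16, axis=1)
        K = sp.coo_matrix((Ke.ravel(), (rows.ravel(), cols.ravel())), shape=(self.ndof, self.ndof))
        return K.tocsr()

    def eigenstrain_force(self, eigenstrains: dict[int, np.ndarray]) -> np.ndarray:
        """Equivalent nodal forces int B^T D eps* over the listed elements."""
        f = np.zeros(self.ndof)
        if not eigenstrains:
            return f
        elems = np.fromiter(eigenstrains.keys(), dtype=int)
        eps = np.array([np.asarray(eigenstrains[e], dtype=float) for e in elems])  # (n, 3) local
        sig_loc = np.einsum("eij,ej->ei", self.D_loc[elems], eps)
        sig_glob = np.einsum("egki,ek->egi", self.T[elems], sig_loc)
        fe = np.einsum(
            "g,eg,egki,egk->ei", quad8.WEIGHT_2D, self.detJ[elems], self.B[elems], sig_glob
        )
        np.add.at(f, self.edofs[elems], fe)
        return f

    def gp_strains(self, u: np.ndarray) -> np.ndarray:
        """Global-frame strains at the Gauss points, (E, 9, 3)."""
        ue = u.reshape(-1)[self.edofs]
        return np.einsum("egij,ej->egi", self.B, ue)

    def gp_stresses(
        self, u: np.ndarray, eigenstrains: dict[int, np.ndarray] | None = None
    ) -> np.ndarray:
        """Cylindrical stresses (rr, tt, rt, zz) at the Gauss points, (E, 9, 4)."""
        eps_loc = np.einsum("egij,egj->egi", self.T, self.gp_strains(u))
        if eigenstrains:
            for e, star in eigenstrains.items():
                eps_loc[e] -= np.asarray(star, dtype=float)  # stress = D (eps - eps*)
        sig = np.empty(eps_loc.shape[:2] + (4,))
        sig[..., :3] = np.einsum("eij,egj->egi", self.D_loc, eps_loc)
        sig[..., 3] = np.einsum("ei,egi->eg", self.zrow, eps_loc)
        return sig


def element_stiffness(
    coords: np.ndarray, material: Material, origin: tuple[float, float] = (0.0, 0.0)
) -> np.ndarray:
    """16x16 stiffness of a single Q8 element (polar material axes about origin)."""
    coords = np.asarray(coords, dtype=float) - np.asarray(origin)
    mesh = QuadMesh(
        nodes=coords,
        elements=np.arange(8, dtype=int)[None, :],
        region=np.array(["plaque"]),
        edge_groups={},
    )
    op = Operator(mesh, {"plaque": material})
    return op.element_stiffness_blocks()[0]


def pressure_load(mesh: QuadMesh, pressure: float, group: str = "lumen_surface") -> np.ndarray:
    """Work-equivalent nodal forces for constant normal pressure on an edge group.

    The traction points into the solid (pressure compresses the surface);
    orientation is resolved against the parent element centroid, so the same
    routine serves the lumen or any other boundary.
    """
    f = np.zeros(2 * len(mesh.nodes))
    if pressure == 0.0:
        return f
    eg = mesh.edge_groups[group]
    for edge_nodes, parent in zip(eg.nodes, eg.elements):
        xy = mesh.nodes[edge_nodes]  # (3, 2) end, mid, end
        centroid = mesh.nodes[mesh.elements[parent]].mean(axis=0)
        for xi, w in zip(quad8.GAUSS_1D, quad8.WEIGHT_1D):
            N = quad8.edge_shape(xi)
            dN = quad8.edge_shape_gradient(xi)
            pos = N @ xy
            tang = dN @ xy
            jac = float(np.hypot(*tang))
            if jac <= 0 or not np.isfinite(jac):
                raise ValueError(f"degenerate boundary edge with nodes {edge_nodes.tolist()}")
            normal = np.array([tang[1], -tang[0]]) / jac
            if np.dot(normal, centroid - pos) < 0:
                normal = -normal
            for a, n_a in enumerate(N):
                f[2 * edge_nodes[a] : 2 * edge_nodes[a] + 2] += w * n_a * pressure * normal * jac
    return f


def eigenstrain_load(
    mesh: QuadMesh,
    eigenstrains: dict[int, np.ndarray],
    materials: dict[str, Material] | None = None,
    operator: Operator | None = None,
) -> np.ndarray:
    op = operator or Operator(mesh, materials)
    return op.eigenstrain_force(eigenstrains)


def default_constraints(mesh: QuadMesh) -> list[tuple[int, int]]:
    """Symmetry conditions of the half model.

    Nodes on the symmetry line move only radially (u_y = 0).  Those
    constraints leave the rigid translation along the symmetry axis
    unconstrained, so one u_x pin is added at the outer-boundary symmetry
    node; for symmetric loads its reaction is at round-off level.
    """
    sym = np.unique(mesh.edge_groups["symmetry_line"].nodes)
    fixed = [(int(n), 1) for n in sym]
    pin = int(sym[np.argmax(mesh.nodes[sym, 0])])
    fixed.append((pin, 0))
    return fixed


class StaticSolver:
    """Factorized stiffness for one mesh + material assignment.

    Reused across right-hand sides (pressure and expansion sweeps share the
    factorization exactly; the physics is linear, so this is not an
    approximation).
    """

    def __init__(
        self,
        mesh: QuadMesh,
        materials: dict[str, Material] | None = None,
        constraints: list[tuple[int, int]] | None = None,
    ):
        self.mesh = mesh
        self.operator = Operator(mesh, materials)
        self.K = self.operator.stiffness_matrix()
        if constraints is None:
            constraints = default_constraints(mesh)
        if not constraints:
            raise SingularSystemError("no constraints: rigid-body modes are unconstrained")
        self.fixed_dofs = np.unique([2 * n + c for n, c in constraints])
        self.free = np.ones(self.operator.ndof, dtype=bool)
        self.free[self.fixed_dofs] = False
        K_ff = self.K[self.free][:, self.free].tocsc()
        self._lu = splu(K_ff, permc_spec="COLAMD")
        dmin = np.abs(self._lu.U.diagonal()).min()
        dmax = np.abs(self._lu.U.diagonal()).max()
        if not np.isfinite(dmin) or dmin <= 1e-14 * dmax:
            raise SingularSystemError(
                "stiffness matrix is numerically singular after constraints; "
                "a rigid-body mode is likely unconstrained"
            )

    def solve(self, f: np.ndarray) -> np.ndarray:
        """Displacements (N, 2) for a global load vector; residual-checked."""
        u = np.zeros(self.operator.ndof)
        u[self.free] = self._lu.solve(f[self.free])
        if not np.all(np.isfinite(u)):
            raise SingularSystemError("solver produced non-finite displacements")
        fnorm = np.linalg.norm(f[self.free])
        if fnorm > 0:
            res = np.linalg.norm(self.K[self.free][:, self.free] @ u[self.free] - f[self.free])
            if res > 1e-10 * fnorm:
                raise SingularSystemError(f"relative residual {res / fnorm:.2e} exceeds 1e-10")
        return u.reshape(-1, 2)

    def reactions(self, u: np.ndarray, f: np.ndarray) -> np.ndarray:
        """Residual K u - f, nonzero only at constrained dofs (the reactions)."""
        return self.K @ u.reshape(-1) - f


def build_load(
    mesh: QuadMesh, load_case: LoadCase, operator: Operator
) -> np.ndarray:
    f = pressure_load(mesh, load_case.pressure, load_case.pressure_group)
    f += operator.eigenstrain_force(load_case.eigenstrains)
    return f


def solve(
    mesh: QuadMesh,
    materials: dict[str, Material] | None = None,
    load_case: LoadCase | None = None,
) -> DisplacementField:
    """Assemble, constrain and solve one static load case."""
    load_case = load_case or LoadCase()
    constraints = default_constraints(mesh) if load_case.use_symmetry else []
    constraints = constraints + list(load_case.extra_fixed)
    solver = StaticSolver(mesh, materials, constraints)
    f = build_load(mesh, load_case, solver.operator)
    return DisplacementField(u=solver.solve(f))


def recover_stress(
    mesh: QuadMesh,
    materials: dict[str, Material] | None,
    displacements: DisplacementField | np.ndarray,
    eigenstrains: dict[int, np.ndarray] | None = None,
    operator: Operator | None = None,
    at: str = "nodes",
) -> StressField:
    """Cylindrical stresses at nodes (region-averaged) or element centers.

    Gauss-point stresses are extrapolated to nodes with the standard
    biquadratic scheme and averaged only among elements of the same region:
    material interfaces (cap/core, cap/crystal) keep one value per side, so
    interfacial peaks are not smeared.
    """
    op = operator or Operator(mesh, materials)
    u = displacements.u if isinstance(displacements, DisplacementField) else displacements
    gp_sig = op.gp_stresses(u, eigenstrains)

    if at == "centers":
        center = gp_sig[:, 4, :]  # Gauss point at (0, 0)
        xy = np.einsum("a,eaj->ej", quad8.shape_functions(0.0, 0.0), mesh.element_coords())
        r = np.hypot(xy[:, 0], xy[:, 1])
        th = np.degrees(np.arctan2(xy[:, 1], xy[:, 0]))
        return StressField(
            node_index=np.arange(len(mesh.elements)),
            region=mesh.region.copy(),
            x=xy[:, 0],
            y=xy[:, 1],
            r=r,
            theta_deg=th,
            sigma=center,
        )

    nodal = np.einsum("ag,egc->eac", quad8.EXTRAPOLATION, gp_sig)  # (E, 8, 4)
    rc = np.array([REGION_CODES[t] for t in mesh.region])
    keys = (mesh.elements * 4 + rc[:, None]).ravel()
    uniq, inv = np.unique(keys, return_inverse=True)
    sums = np.zeros((len(uniq), 4))
    np.add.at(sums, inv, nodal.reshape(-1, 4))
    counts = np.bincount(inv)
    avg = sums / counts[:, None]
    node_idx = uniq // 4
    region = np.array([_CODE_NAMES[c] for c in uniq % 4], dtype="<U8")
    xy = mesh.nodes[node_idx]
    r = np.hypot(xy[:, 0], xy[:, 1])
    th = np.degrees(np.arctan2(xy[:, 1], xy[:, 0]))
    return StressField(
        node_index=node_idx,
        region=region,
        x=xy[:, 0],
        y=xy[:, 1],
        r=r,
        theta_deg=th,
        sigma=avg,
    )


def export_fields(path, mesh: QuadMesh, displacements: DisplacementField, stress: StressField) -> None:
    """VTK export with nodal stress arrays (region-max-magnitude at interfaces)."""
    n = len(mesh.nodes)
    point = {
        "displacement": displacements.u,
    }
    names = ["sigma_rr", "sigma_tt", "sigma_rt", "sigma_zz"]
    arrays = {name: np.zeros(n) for name in names}
    order = np.argsort(np.abs(stress.sigma[:, 1]))  # larger |s_tt| wins at interfaces
    for i in order:
        nd = stress.node_index[i]
        for j, name in enumerate(names):
            arrays[name][nd] = stress.sigma[i, j]
    point.update(arrays)
    write_vtk(path, mesh.nodes, mesh.elements, cell_data={"region": mesh.region}, point_data=point)
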