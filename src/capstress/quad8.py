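"""8-node serendipity quadrilateral (Q8) reference-element machinery.

Shape functions, 3x3 Gauss-Legendre quadrature, isoparametric Jacobians and
the Gauss-point -> node stress extrapolation matrix shared by the mesher and
the solver.

Node ordering convention (counterclockwise): corners 0-3 at natural
coordinates (-1,-1), (1,-1), (1,1), (-1,1), then midsides 4-7 on edges
0-1, 1-2, 2-3, 3-0.
"""

from __future__ import annotations

import numpy as np

# natural coordinates of the 8 nodes
NODE_XI = np.array(
    [
        [-1.0, -1.0],
        [1.0, -1.0],
        [1.0, 1.0],
        [-1.0, 1.0],
        [0.0, -1.0],
        [1.0, 0.0],
        [0.0, 1.0],
        [-1.0, 0.0],
    ]
)

# edges as (corner, midside, corner) local indices
EDGES = np.array([[0, 4, 1], [1, 5, 2], [2, 6, 3], [3, 7, 0]])

_G = np.sqrt(3.0 / 5.0)
GAUSS_1D = np.array([-_G, 0.0, _G])
WEIGHT_1D = np.array([5.0, 8.0, 5.0]) / 9.0

# 9 Gauss points ordered as index 3*i + j with xi = GAUSS_1D[i], eta = GAUSS_1D[j]
GAUSS_2D = np.array([[x, e] for x in GAUSS_1D for e in GAUSS_1D])
WEIGHT_2D = np.array([wx * we for wx in WEIGHT_1D for we in WEIGHT_1D])


def shape_functions(xi: float, eta: float) -> np.ndarray:
    """Serendipity shape functions N_a(xi, eta), shape (8,)."""
    N = np.empty(8)
    for a in range(4):
        xa, ea = NODE_XI[a]
        N[a] = 0.25 * (1 + xi * xa) * (1 + eta * ea) * (xi * xa + eta * ea - 1)
    for a in range(4, 8):
        xa, ea = NODE_XI[a]
        if xa == 0.0:
            N[a] = 0.5 * (1 - xi**2) * (1 + eta * ea)
        else:
            N[a] = 0.5 * (1 + xi * xa) * (1 - eta**2)
    return N


def shape_gradients(xi: float, eta: float) -> np.ndarray:
    """Derivatives dN_a/d(xi, eta), shape (8, 2)."""
    dN = np.empty((8, 2))
    for a in range(4):
        xa, ea = NODE_XI[a]
        dN[a, 0] = 0.25 * xa * (1 + eta * ea) * (2 * xi * xa + eta * ea)
        dN[a, 1] = 0.25 * ea * (1 + xi * xa) * (xi * xa + 2 * eta * ea)
    for a in range(4, 8):
        xa, ea = NODE_XI[a]
        if xa == 0.0:
            dN[a, 0] = -xi * (1 + eta * ea)
            dN[a, 1] = 0.5 * (1 - xi**2) * ea
        else:
            dN[a, 0] = 0.5 * xa * (1 - eta**2)
            dN[a, 1] = -eta * (1 + xi * xa)
    return dN


# tabulated at the 9 Gauss points: (9, 8) and (9, 8, 2)
N_GP = np.array([shape_functions(x, e) for x, e in GAUSS_2D])
DN_GP = np.array([shape_gradients(x, e) for x, e in GAUSS_2D])


def _lagrange3(t: float) -> np.ndarray:
    """1D quadratic Lagrange basis through the Gauss abscissae {-g, 0, g}."""
    g = _G
    return np.array([t * (t - g) / (2 * g**2), 1 - t**2 / g**2, t * (t + g) / (2 * g**2)])


def _extrapolation_matrix() -> np.ndarray:
    """(8, 9) matrix mapping 9 Gauss-point values to the 8 element nodes.

    The Gauss-point field is interpolated biquadratically and evaluated at the
    node natural coordinates (standard stress-smoothing extrapolation).
    """
    M = np.empty((8, 9))
    for a in range(8):
        lx = _lagrange3(NODE_XI[a, 0])
        le = _lagrange3(NODE_XI[a, 1])
        M[a] = np.array([lx[i] * le[j] for i in range(3) for j in range(3)])
    return M


EXTRAPOLATION = _extrapolation_matrix()


def jacobians(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Jacobian matrices and determinants at the 9 Gauss points.

    Parameters
    ----------
    coords : (..., 8, 2) element node coordinates.

    Returns
    -------
    J : (..., 9, 2, 2) with J[..., i, j] = d x_j / d xi_i,
    detJ : (..., 9)
    """
    J = np.einsum("gai,...aj->...gij", DN_GP, coords)
    detJ = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
    return J, detJ


def inv22(J: np.ndarray) -> np.ndarray:
    """Inverse of a stack of 2x2 matrices (closed form)."""
    det = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
    inv = np.empty_like(J)
    inv[..., 0, 0] = J[..., 1, 1]
    inv[..., 1, 1] = J[..., 0, 0]
    inv[..., 0, 1] = -J[..., 0, 1]
    inv[..., 1, 0] = -J[..., 1, 0]
    return inv / det[..., None, None]


def cartesian_gradients(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cartesian shape-function gradients at the Gauss points.

    Returns (dN_xy, detJ) with dN_xy of shape (..., 9, 8, 2):
    dN_xy[..., g, a, j] = dN_a/dx_j at Gauss point g.
    """
    J, detJ = jacobians(coords)
    invJT = np.swapaxes(inv22(J), -1, -2)
    dN_xy = np.einsum("gai,...gij->...gaj", DN_GP, invJT)
    return dN_xy, detJ


def element_areas(coords: np.ndarray) -> np.ndarray:
    """Gauss-integrated areas of a stack of elements, shape (...)."""
    _, detJ = jacobians(coords)
    return np.einsum("g,...g->...", WEIGHT_2D, detJ)


# quadratic edge (3 nodes at xi = -1, 0, 1)
def edge_shape(xi: float) -> np.ndarray:
    return np.array([xi * (xi - 1) / 2, 1 - xi**2, xi * (xi + 1) / 2])


def edge_shape_gradient(xi: float) -> np.ndarray:
    return np.array([(2 * xi - 1) / 2, -2 * xi, (2 * xi + 1) / 2])
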