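"""P1 axisymmetric finite-element primitives shared by the solvers.

Linear triangles with 2*pi*r volume weighting: element gradients are constant,
so stiffness integrals evaluated with the centroid radius are exact, and the
lumped mass / load weights use the exact first moments
int(phi_i * r) dA = A/12 * (2 r_i + r_j + r_k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .mesh import Mesh

TWO_PI = 2.0 * np.pi


@dataclass
class FemSpace:
    """Precomputed element geometry for repeated assembly on one mesh."""

    mesh: Mesh
    area: np.ndarray  # (M,) element areas
    grad_r: np.ndarray  # (M,3) d(phi_i)/dr
    grad_z: np.ndarray  # (M,3) d(phi_i)/dz
    volume: np.ndarray  # (M,) 2*pi*rbar*A
    node_weights: np.ndarray  # (M,3) exact 2*pi*int(phi_i r)dA
    stiff_shape: np.ndarray  # (M,3,3) unit-coefficient stiffness blocks
    rows: np.ndarray  # (M*9,) COO row indices
    cols: np.ndarray  # (M*9,) COO col indices

    @property
    def n_nodes(self) -> int:
        return self.mesh.n_nodes


def build_space(mesh: Mesh) -> FemSpace:
    tri = mesh.triangles
    p = mesh.nodes[tri]
    r, z = p[..., 0], p[..., 1]
    area = mesh.element_areas
    nxt = np.roll(np.arange(3), -1)
    prv = np.roll(np.arange(3), 1)
    grad_r = (z[:, nxt] - z[:, prv]) / (2.0 * area)[:, None]
    grad_z = (r[:, prv] - r[:, nxt]) / (2.0 * area)[:, None]
    rbar = r.mean(axis=1)
    volume = TWO_PI * rbar * area
    node_weights = TWO_PI * (area[:, None] / 12.0) * (r + 3.0 * rbar[:, None])
    stiff_shape = (
        grad_r[:, :, None] * grad_r[:, None, :] + grad_z[:, :, None] * grad_z[:, None, :]
    ) * volume[:, None, None]
    rows = np.repeat(tri, 3, axis=1).ravel()
    cols = np.tile(tri, (1, 3)).ravel()
    return FemSpace(
        mesh=mesh,
        area=area,
        grad_r=grad_r,
        grad_z=grad_z,
        volume=volume,
        node_weights=node_weights,
        stiff_shape=stiff_shape,
        rows=rows,
        cols=cols,
    )


def assemble_stiffness(space: FemSpace, coef: np.ndarray, elements: np.ndarray | None = None) -> sp.csr_matrix:
    """Assemble sum_e coef_e * int(grad phi_i . grad phi_j) 2 pi r dA."""
    n = space.n_nodes
    coef = np.asarray(coef)
    if elements is None:
        blocks = coef[:, None, None] * space.stiff_shape
        rows, cols = space.rows, space.cols
    else:
        blocks = coef[elements][:, None, None] * space.stiff_shape[elements]
        rows = space.rows.reshape(-1, 9)[elements].ravel()
        cols = space.cols.reshape(-1, 9)[elements].ravel()
    K = sp.coo_matrix((blocks.ravel(), (rows, cols)), shape=(n, n))
    return K.tocsr()


def lumped_mass(space: FemSpace, coef: np.ndarray, elements: np.ndarray | None = None) -> np.ndarray:
    """Diagonal of the lumped mass matrix with per-element coefficient."""
    tri = space.mesh.triangles
    w = space.node_weights
    coef = np.asarray(coef)
    if elements is not None:
        tri, w, coef = tri[elements], w[elements], coef[elements]
    out = np.zeros(space.n_nodes)
    np.add.at(out, tri.ravel(), (coef[:, None] * w).ravel())
    return out


def element_load(space: FemSpace, density: np.ndarray, elements: np.ndarray | None = None) -> np.ndarray:
    """Nodal load vector from a per-element volumetric source density."""
    return lumped_mass(space, density, elements)


def edge_weights(mesh: Mesh, edges: np.ndarray) -> np.ndarray:
    """Lumped axisymmetric surface weights per edge node: 2 pi int(phi r) ds.

    Row-summed (lumped) so Robin terms only add to the diagonal, preserving
    the M-matrix structure of the thermal system.
    """
    if len(edges) == 0:
        return np.zeros((0, 2))
    pa, pb = mesh.nodes[edges[:, 0]], mesh.nodes[edges[:, 1]]
    length = np.hypot(*(pb - pa).T)
    ra, rb = pa[:, 0], pb[:, 0]
    wa = TWO_PI * length * (2.0 * ra + rb) / 6.0
    wb = TWO_PI * length * (ra + 2.0 * rb) / 6.0
    return np.column_stack([wa, wb])


def solve_dirichlet(K: sp.spmatrix, rhs: np.ndarray, fixed: np.ndarray, fixed_values: np.ndarray):
    """Solve K x = rhs with Dirichlet values on ``fixed`` nodes.

    Returns the full solution vector (complex if K or rhs are complex).
    """
    n = K.shape[0]
    x = np.zeros(n, dtype=np.result_type(K.dtype, rhs.dtype, fixed_values.dtype))
    x[fixed] = fixed_values
    free = np.setdiff1d(np.arange(n), fixed, assume_unique=False)
    K = K.tocsc()
    b = rhs[free] - K[:, fixed][free] @ x[fixed]
    lu = splu(K[free][:, free])
    x[free] = lu.solve(b)
    return x
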