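"""Minimal P1 finite-element assembly on triangulations.

Supports planar triangulations (coordinates in R^2) and surface
triangulations embedded in R^3 (the closing-sliver strip of the cone's
lateral boundary); in the surface case the element matrices are computed in
each triangle's local metric, which is exactly the Laplace-Beltrami
discretization for piecewise-flat geometry.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def p1_matrices(nodes: np.ndarray, tris: np.ndarray):
    """Consistent mass and stiffness matrices for P1 elements.

    Parameters
    ----------
    nodes : (m, 2) or (m, 3) float array of vertex coordinates.
    tris : (nt, 3) int array of vertex indices.

    Returns
    -------
    M, K : scipy.sparse.csr_matrix, shape (m, m)
        Consistent mass matrix and stiffness (Dirichlet-energy) matrix.
    areas : (nt,) element areas.
    """
    nodes = np.asarray(nodes, dtype=float)
    tris = np.asarray(tris, dtype=np.int64)
    x0 = nodes[tris[:, 0]]
    e1 = nodes[tris[:, 1]] - x0
    e2 = nodes[tris[:, 2]] - x0

    g11 = np.einsum("ij,ij->i", e1, e1)
    g12 = np.einsum("ij,ij->i", e1, e2)
    g22 = np.einsum("ij,ij->i", e2, e2)
    det = g11 * g22 - g12 ** 2
    if np.any(det <= 0):
        raise ValueError("degenerate triangle in mesh")
    areas = 0.5 * np.sqrt(det)

    # Gradients of barycentric coordinates in the local metric:
    # for lam1, lam2 the contravariant components follow from inv(G);
    # lam0 = 1 - lam1 - lam2.  K_ij = area * <grad lam_i, grad lam_j>.
    inv11 = g22 / det
    inv12 = -g12 / det
    inv22 = g11 / det
    # <grad lam_a, grad lam_b> for a,b in {1,2} is inv(G)_{ab}
    k11 = inv11
    k12 = inv12
    k22 = inv22
    k01 = -(k11 + k12)
    k02 = -(k12 + k22)
    k00 = -(k01 + k02)

    nt = len(tris)
    Kloc = np.empty((nt, 3, 3))
    Kloc[:, 0, 0] = k00
    Kloc[:, 0, 1] = Kloc[:, 1, 0] = k01
    Kloc[:, 0, 2] = Kloc[:, 2, 0] = k02
    Kloc[:, 1, 1] = k11
    Kloc[:, 1, 2] = Kloc[:, 2, 1] = k12
    Kloc[:, 2, 2] = k22
    Kloc *= areas[:, None, None]

    Mloc = (areas[:, None, None] / 12.0) * (np.ones((3, 3)) + np.eye(3))

    rows = np.repeat(tris, 3, axis=1).reshape(nt, 3, 3)
    cols = np.repeat(tris[:, None, :], 3, axis=1)
    m = len(nodes)
    K = sp.coo_matrix((Kloc.ravel(), (rows.ravel(), cols.ravel())),
                      shape=(m, m)).tocsr()
    M = sp.coo_matrix((Mloc.ravel(), (rows.ravel(), cols.ravel())),
                      shape=(m, m)).tocsr()
    return M, K, areas


def lumped_mass(M: sp.spmatrix) -> np.ndarray:
    """Row-sum mass lumping (positive for P1 on non-degenerate meshes)."""
    return np.asarray(M.sum(axis=1)).ravel()
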