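"""P1 tetrahedral finite-element assembly on a :class:`~ivtpk.meshing.VolumeMesh`.

Provides the operators needed by the Darcy and transport solvers: stiffness,
lumped mass, convection (cellwise-constant velocity), boundary mass matrices
weighted by the normal velocity, and boundary load vectors.  All matrices are
scipy CSR.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .geometry import SurfaceTag
from .meshing import VolumeMesh

__all__ = ["basis_gradients", "stiffness_matrix", "lumped_mass",
           "convection_matrix", "boundary_normal_velocity",
           "boundary_robin_matrix", "boundary_load", "tag_vertices",
           "vertex_boundary_areas", "cell_gradients"]


def basis_gradients(mesh: VolumeMesh) -> np.ndarray:
    """Gradients of the four P1 basis functions per cell, shape (n_cells, 4, 3)."""
    v = mesh.points[mesh.cells]                      # (nc, 4, 3)
    e = v[:, 1:] - v[:, 0:1]                         # edge matrix rows
    inv = np.linalg.inv(e)                           # (nc, 3, 3)
    g = np.transpose(inv, (0, 2, 1))                 # grads of lambda_1..3
    g0 = -g.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g], axis=1)


def stiffness_matrix(mesh: VolumeMesh, coeff: float = 1.0,
                     grads: np.ndarray | None = None) -> sp.csr_matrix:
    """Assemble ``coeff * ∫ ∇φ_i·∇φ_j``."""
    g = basis_gradients(mesh) if grads is None else grads
    vols = mesh.cell_volumes
    local = coeff * np.einsum("kid,kjd,k->kij", g, g, vols)
    rows = np.repeat(mesh.cells, 4, axis=1).ravel()
    cols = np.tile(mesh.cells, (1, 4)).ravel()
    n = mesh.n_points
    return sp.coo_matrix((local.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def lumped_mass(mesh: VolumeMesh) -> np.ndarray:
    """Diagonal (lumped) mass vector: per-vertex volume share."""
    return mesh.lumped_volumes()


def convection_matrix(mesh: VolumeMesh, velocity: np.ndarray,
                      grads: np.ndarray | None = None) -> sp.csr_matrix:
    """Assemble ``∫ (u·∇φ_j) φ_i`` with cellwise-constant velocity (n_cells, 3)."""
    g = basis_gradients(mesh) if grads is None else grads
    u_dot_grad = np.einsum("kd,kjd->kj", velocity, g)       # (nc, 4)
    w = mesh.cell_volumes / 4.0
    local = w[:, None, None] * np.broadcast_to(u_dot_grad[:, None, :],
                                               (mesh.n_cells, 4, 4))
    rows = np.repeat(mesh.cells, 4, axis=1).ravel()
    cols = np.tile(mesh.cells, (1, 4)).ravel()
    n = mesh.n_points
    return sp.coo_matrix((local.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def boundary_normal_velocity(mesh: VolumeMesh,
                             velocity: np.ndarray) -> np.ndarray:
    """Outward normal velocity u·n per boundary facet from the adjacent cell."""
    _, normals = mesh.face_areas_normals()
    return np.einsum("fd,fd->f", velocity[mesh.face_cells], normals)


def boundary_robin_matrix(mesh: VolumeMesh, face_weights: np.ndarray,
                          face_mask: np.ndarray) -> sp.csr_matrix:
    """Assemble ``∫_Γ w φ_i φ_j`` over the masked boundary facets.

    ``face_weights`` is a per-facet coefficient (e.g. u·n); uses the exact
    P1 facet mass matrix A/12 · (1 + δ_ij).
    """
    areas, _ = mesh.face_areas_normals()
    faces = mesh.boundary_faces[face_mask]
    w = (face_weights * areas)[face_mask] / 12.0
    local = w[:, None, None] * (np.ones((3, 3)) + np.eye(3))
    rows = np.repeat(faces, 3, axis=1).ravel()
    cols = np.tile(faces, (1, 3)).ravel()
    n = mesh.n_points
    return sp.coo_matrix((local.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def boundary_load(mesh: VolumeMesh, face_values: np.ndarray,
                  face_mask: np.ndarray) -> np.ndarray:
    """Assemble ``∫_Γ g φ_i`` with facet-constant g over masked facets."""
    areas, _ = mesh.face_areas_normals()
    b = np.zeros(mesh.n_points)
    faces = mesh.boundary_faces[face_mask]
    contrib = (face_values * areas)[face_mask] / 3.0
    for k in range(3):
        np.add.at(b, faces[:, k], contrib)
    return b


def tag_vertices(mesh: VolumeMesh, tags) -> np.ndarray:
    """Sorted unique vertex indices lying on facets with any of the given tags."""
    tags = [int(t) for t in np.atleast_1d(tags)]
    mask = np.isin(mesh.face_tags, tags)
    return np.unique(mesh.boundary_faces[mask])


def vertex_boundary_areas(mesh: VolumeMesh) -> np.ndarray:
    """Per-vertex share of boundary area (a third of each adjacent facet)."""
    areas, _ = mesh.face_areas_normals()
    w = np.zeros(mesh.n_points)
    for k in range(3):
        np.add.at(w, mesh.boundary_faces[:, k], areas / 3.0)
    return w


def cell_gradients(mesh: VolumeMesh, field: np.ndarray,
                   grads: np.ndarray | None = None) -> np.ndarray:
    """Cellwise-constant gradient of a P1 vertex field, shape (n_cells, 3)."""
    g = basis_gradients(mesh) if grads is None else grads
    return np.einsum("kjd,kj->kd", g, field[mesh.cells])
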