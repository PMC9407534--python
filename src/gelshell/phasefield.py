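"""Vertex-based damage (phase-field) equation on the mesh graph.

The discrete equation at vertex i reads

    (4 l (1 - K) Wbar+_i / Gc + 1) p_i
        + 4 l^2 (1 / a_i) sum_j w_ij (p_i - p_j) = 1,

with cotangent edge weights w_ij and barycentric vertex areas a_i.  Rows
are multiplied through by a_i so the assembled system is symmetric:

    A_ii = a_i (4 l (1 - K) Wbar+_i / Gc + 1) + 4 l^2 sum_j w_ij,
    A_ij = -4 l^2 w_ij,          b_i = a_i.

p = 1 means intact material, p = 0 fully broken.  Irreversibility is
enforced through a per-element history field: the running maximum of the
tensile driving energy is what enters the equation, so p never heals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix, diags
from scipy.sparse.linalg import spsolve

from .errors import AssemblyError, LinearSolveError
from .graph import GraphOperators, graph_operators
from .mesh import TriMesh, triangle_areas


@dataclass(frozen=True)
class PhaseFieldParams:
    """Length scale ell, fracture energy per unit area gc, residual k_res."""

    ell: float
    gc: float
    k_res: float = 1e-4

    def __post_init__(self):
        if self.ell <= 0:
            raise ValueError("ell must be positive")
        if self.gc <= 0:
            raise ValueError("gc must be positive")
        if not 0 < self.k_res < 1:
            raise ValueError("k_res must lie in (0, 1)")

    def homogeneous_p(self, w_plus):
        """Closed-form uniform solution 1 / (1 + 4 l (1-K) W+ / Gc)."""
        return 1.0 / (
            1.0 + 4.0 * self.ell * (1.0 - self.k_res) * np.asarray(w_plus) / self.gc
        )


def update_history(H: np.ndarray, elem_w_plus: np.ndarray) -> np.ndarray:
    """Running maximum of the per-element tensile driving energy."""
    if H.shape != np.shape(elem_w_plus):
        raise ValueError("history and energy arrays must have the same shape")
    return np.maximum(H, elem_w_plus)


def vertex_driving_energy(
    mesh: TriMesh, elem_w_plus, element_mask=None
) -> np.ndarray:
    """Area-weighted transfer of per-element W+ to vertices.

    vertex value = sum over incident enabled elements of (area/3 * W+)
    divided by the same sum of area/3; vertices with no enabled incident
    element get 0.
    """
    elem_w_plus = np.asarray(elem_w_plus, dtype=np.float64)
    if len(elem_w_plus) != mesh.n_triangles:
        raise ValueError("elem_w_plus must have one entry per element")
    tris = mesh.triangles
    w = elem_w_plus
    if element_mask is not None:
        tris = tris[element_mask]
        w = w[element_mask]
    num = np.zeros(mesh.n_vertices)
    den = np.zeros(mesh.n_vertices)
    if len(tris):
        a3 = triangle_areas(mesh.vertices, tris) / 3.0
        for k in range(3):
            np.add.at(num, tris[:, k], a3 * w)
            np.add.at(den, tris[:, k], a3)
    out = np.zeros(mesh.n_vertices)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def assemble_phase_system(
    ops: GraphOperators, vertex_w: np.ndarray, params: PhaseFieldParams
):
    """Symmetrized linear system (A, b) on the active vertex set.

    Returns (A, b, active) where ``active`` are the vertex indices with
    positive area; A and b are restricted to them.
    """
    active = ops.active_vertices()
    a = ops.vertex_areas[active]
    w = np.asarray(vertex_w, dtype=np.float64)[active]
    if np.any(w < 0):
        raise AssemblyError("negative driving energy")
    L = ops.laplacian[active][:, active]
    coeff = 4.0 * params.ell * (1.0 - params.k_res) / params.gc
    D = a * (coeff * w + 1.0)
    A = (diags(D) + 4.0 * params.ell**2 * L).tocsr()
    if not np.all(np.isfinite(A.data)):
        bad_row = int(A.nonzero()[0][~np.isfinite(A.data)][0])
        raise AssemblyError(f"non-finite matrix entry at vertex {active[bad_row]}")
    b = a.copy()
    return A, b, active


def solve_phase(A: csr_matrix, b: np.ndarray, clamp: bool = True):
    """Direct sparse solve of A p = b with residual check and [0,1] clamp.

    Returns (p, info) where info records the relative residual and how many
    entries were clamped.
    """
    p = spsolve(A.tocsc(), b)
    res = np.linalg.norm(A @ p - b)
    bnorm = np.linalg.norm(b)
    rel = res / bnorm if bnorm > 0 else res
    if not np.all(np.isfinite(p)) or rel > 1e-8:
        raise LinearSolveError(
            f"phase-field solve failed (relative residual {rel:.3e})"
        )
    n_clamped = 0
    if clamp:
        # count only violations beyond roundoff
        n_clamped = int(np.sum((p < -1e-12) | (p > 1.0 + 1e-12)))
        p = np.clip(p, 0.0, 1.0)
    return p, {"residual": float(rel), "n_clamped": n_clamped}


class PhaseFieldProblem:
    """Phase solve restricted to the phase-field-enabled element regions.

    Vertices not incident to any enabled element carry p = 1.  Natural
    (do-nothing) boundary conditions apply on all boundaries, including the
    region interface.
    """

    def __init__(
        self,
        mesh: TriMesh,
        params: PhaseFieldParams,
        element_mask=None,
        clamp: bool = True,
        clamp_negative_weights: bool = False,
    ):
        self.mesh = mesh
        self.params = params
        self.element_mask = (
            np.ones(mesh.n_triangles, dtype=bool)
            if element_mask is None
            else np.asarray(element_mask, dtype=bool)
        )
        self.clamp = clamp
        self.ops = graph_operators(
            mesh, self.element_mask, clamp_negative=clamp_negative_weights
        )
        self.last_info = None

    def solve(self, elem_history: np.ndarray) -> np.ndarray:
        w = vertex_driving_energy(self.mesh, elem_history, self.element_mask)
        A, b, active = assemble_phase_system(self.ops, w, self.params)
        p_active, info = solve_phase(A, b, clamp=self.clamp)
        self.last_info = info
        p = np.ones(self.mesh.n_vertices)
        p[active] = p_active
        return p
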