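"""Discrete-geometry operators on the mesh graph.

The triangle mesh doubles as a weighted undirected graph whose edge weights
are the classical cotangent weights and whose vertex measures are barycentric
areas (one third of each incident triangle).  These feed the vertex-based
damage equation: the term sum_j w_ij (p_i - p_j) is the graph Laplacian
applied to p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix, diags

from .errors import GeometryError
from .mesh import TriMesh, triangle_areas

_ANGLE_TOL = 1e-9


@dataclass
class GraphOperators:
    """Cotangent edge weights and barycentric vertex areas.

    ``weights`` is a symmetric sparse matrix with w_ij on the off-diagonals;
    ``vertex_areas`` is the (n,) array of barycentric areas.  Vertices not
    touched by any contributing element have zero area.
    """

    weights: csr_matrix
    vertex_areas: np.ndarray

    def weight(self, i: int, j: int) -> float:
        return float(self.weights[i, j])

    @property
    def laplacian(self) -> csr_matrix:
        """L = D - W so that (L p)_i = sum_j w_ij (p_i - p_j)."""
        d = np.asarray(self.weights.sum(axis=1)).ravel()
        return (diags(d) - self.weights).tocsr()

    def active_vertices(self) -> np.ndarray:
        return np.flatnonzero(self.vertex_areas > 0)


def _corner_cotangents(vertices, triangles):
    """(m, 3) cotangents of the corner angles, corner k opposite edge k."""
    p = vertices[triangles]  # (m, 3, 3)
    cots = np.empty((len(triangles), 3))
    for k in range(3):
        a = p[:, (k + 1) % 3] - p[:, k]
        b = p[:, (k + 2) % 3] - p[:, k]
        cross = np.linalg.norm(np.cross(a, b), axis=1)
        dot = np.einsum("ij,ij->i", a, b)
        ang = np.arctan2(cross, dot)
        if np.any(ang < _ANGLE_TOL) or np.any(ang > np.pi - _ANGLE_TOL):
            bad = int(
                np.flatnonzero((ang < _ANGLE_TOL) | (ang > np.pi - _ANGLE_TOL))[0]
            )
            raise GeometryError(
                f"triangle {bad} has a corner angle within {_ANGLE_TOL} of 0/pi"
            )
        cots[:, k] = dot / cross
    return cots


def cotangent_weights(
    mesh: TriMesh, element_mask=None, clamp_negative: bool = False
) -> csr_matrix:
    """Symmetric sparse matrix of cotangent edge weights.

    For each edge (i, j): w_ij = 1/2 * sum over incident triangles of the
    cotangent of the angle opposite the edge.  Interior edges accumulate two
    cotangents, boundary edges one.  Negative weights (obtuse opposite
    angles) are kept unless ``clamp_negative``.
    """
    tris = mesh.triangles if element_mask is None else mesh.triangles[element_mask]
    n = mesh.n_vertices
    if len(tris) == 0:
        return csr_matrix((n, n))
    cots = _corner_cotangents(mesh.vertices, tris)
    rows, cols, vals = [], [], []
    for k in range(3):
        i = tris[:, (k + 1) % 3]
        j = tris[:, (k + 2) % 3]
        w = 0.5 * cots[:, k]
        rows.append(i)
        cols.append(j)
        vals.append(w)
        rows.append(j)
        cols.append(i)
        vals.append(w)
    W = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    if clamp_negative:
        W.data = np.maximum(W.data, 0.0)
        W.eliminate_zeros()
    return W


def vertex_areas(mesh: TriMesh, element_mask=None) -> np.ndarray:
    """Barycentric vertex areas: a_i = sum of incident triangle areas / 3."""
    tris = mesh.triangles if element_mask is None else mesh.triangles[element_mask]
    out = np.zeros(mesh.n_vertices)
    if len(tris) == 0:
        return out
    a3 = triangle_areas(mesh.vertices, tris) / 3.0
    for k in range(3):
        np.add.at(out, tris[:, k], a3)
    return out


def graph_operators(
    mesh: TriMesh, element_mask=None, clamp_negative: bool = False
) -> GraphOperators:
    return GraphOperators(
        weights=cotangent_weights(mesh, element_mask, clamp_negative),
        vertex_areas=vertex_areas(mesh, element_mask),
    )


def mean_edge_length(mesh: TriMesh, element_mask=None) -> float:
    """Mean edge length over the selected elements."""
    tris = mesh.triangles if element_mask is None else mesh.triangles[element_mask]
    if len(tris) == 0:
        return 0.0
    v = mesh.vertices
    total = 0.0
    for k in range(3):
        e = v[tris[:, (k + 1) % 3]] - v[tris[:, k]]
        total += np.linalg.norm(e, axis=1).sum()
    return float(total / (3 * len(tris)))


def critical_edge_length(mesh: TriMesh, element_mask=None, q=0.1) -> float:
    """Effective element size in the refined (critical) zone.

    Graded meshes concentrate small elements where cracks are expected; the
    q-quantile of all edge lengths is used as the representative size there.
    """
    tris = mesh.triangles if element_mask is None else mesh.triangles[element_mask]
    if len(tris) == 0:
        return 0.0
    v = mesh.vertices
    lens = np.concatenate(
        [
            np.linalg.norm(v[tris[:, (k + 1) % 3]] - v[tris[:, k]], axis=1)
            for k in range(3)
        ]
    )
    return float(np.quantile(lens, q))
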