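"""Triangle surface mesh data model with OFF/OBJ readers.

The mesh is the carrier for everything else in the package: reference
geometry, connectivity, named node sets used by boundary conditions and
reaction-force reporting, a per-element material region label, and a
per-element shell thickness.  All meshes live in 3D Cartesian coordinates;
planar generators place their output in the z = 0 plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import GeometryError, MeshFormatError, TopologyError

_MIN_AREA = 1e-12

DEFAULT_REGION = "default"


def triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Reference areas of all triangles."""
    p0 = vertices[triangles[:, 0]]
    e1 = vertices[triangles[:, 1]] - p0
    e2 = vertices[triangles[:, 2]] - p0
    return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


def triangle_normals(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Unit normals following the winding orientation."""
    p0 = vertices[triangles[:, 0]]
    n = np.cross(vertices[triangles[:, 1]] - p0, vertices[triangles[:, 2]] - p0)
    norms = np.linalg.norm(n, axis=1)
    return n / np.maximum(norms, 1e-300)[:, None]


@dataclass
class TriMesh:
    """Validated triangle surface mesh (manifold with boundary).

    Attributes
    ----------
    vertices : (n, 3) float array of reference coordinates.
    triangles : (m, 3) int array of vertex indices.
    node_sets : named vertex-index collections.
    element_region : (m,) array of region labels (strings).
    thickness : (m,) array of shell thicknesses, all > 0.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    node_sets: dict = field(default_factory=dict)
    element_region: np.ndarray | None = None
    thickness: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (n, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshFormatError("triangles must be an (m, 3) array")
        m = len(self.triangles)
        if self.element_region is None:
            self.element_region = np.full(m, DEFAULT_REGION, dtype=object)
        else:
            self.element_region = np.asarray(self.element_region, dtype=object)
        if self.thickness is None:
            self.thickness = np.ones(m)
        else:
            self.thickness = np.broadcast_to(
                np.asarray(self.thickness, dtype=np.float64), (m,)
            ).copy()
        self.node_sets = {
            k: np.asarray(v, dtype=np.int64) for k, v in self.node_sets.items()
        }
        self.validate()

    # -- basic queries -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def areas(self) -> np.ndarray:
        return triangle_areas(self.vertices, self.triangles)

    def total_area(self) -> float:
        return float(self.areas().sum())

    def directed_edges(self) -> np.ndarray:
        """(3m, 2) array of directed edges in winding order."""
        t = self.triangles
        return np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])

    def unique_edges(self) -> np.ndarray:
        """(k, 2) sorted unique undirected edges."""
        e = np.sort(self.directed_edges(), axis=1)
        return np.unique(e, axis=0)

    def edge_face_count(self):
        """Unique undirected edges and the number of incident faces each."""
        e = np.sort(self.directed_edges(), axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq, counts

    def boundary_edges(self) -> np.ndarray:
        uniq, counts = self.edge_face_count()
        return uniq[counts == 1]

    def boundary_loops(self) -> list:
        """Boundary loops as lists of vertex indices (cyclic order)."""
        edges = self.boundary_edges()
        if len(edges) == 0:
            return []
        adj: dict[int, list[int]] = {}
        for a, b in edges:
            adj.setdefault(int(a), []).append(int(b))
            adj.setdefault(int(b), []).append(int(a))
        unvisited = {(min(a, b), max(a, b)) for a, b in edges}
        loops = []
        while unvisited:
            a, b = next(iter(unvisited))
            loop = [a]
            prev, cur = None, a
            while True:
                nxts = [v for v in adj[cur] if v != prev]
                # at a pinch vertex pick any continuation with an unused edge
                nxt = None
                for v in nxts:
                    if (min(cur, v), max(cur, v)) in unvisited:
                        nxt = v
                        break
                if nxt is None:
                    break
                unvisited.discard((min(cur, nxt), max(cur, nxt)))
                if nxt == loop[0]:
                    break
                loop.append(nxt)
                prev, cur = cur, nxt
            loops.append(loop)
        return loops

    def vertex_adjacency(self):
        """Sparse symmetric vertex adjacency matrix."""
        e = self.unique_edges()
        n = self.n_vertices
        data = np.ones(2 * len(e))
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()

    def n_connected_components(self) -> int:
        ncomp, _ = connected_components(self.vertex_adjacency(), directed=False)
        return int(ncomp)

    # -- validation ----------------------------------------------------

    def validate(self):
        n = self.n_vertices
        t = self.triangles
        if t.size and (t.min() < 0 or t.max() >= n):
            raise TopologyError(
                f"triangle references vertex index outside [0, {n})"
            )
        same = (t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])
        if same.any():
            bad = int(np.flatnonzero(same)[0])
            raise TopologyError(f"triangle {bad} has repeated vertices")
        areas = self.areas()
        small = areas <= _MIN_AREA
        if small.any():
            bad = int(np.flatnonzero(small)[0])
            raise GeometryError(
                f"triangle {bad} is degenerate (area {areas[bad]:.3e})"
            )
        # manifold-with-boundary: each undirected edge in <= 2 faces
        _, counts = self.edge_face_count()
        if counts.size and counts.max() > 2:
            raise TopologyError(
                "non-manifold edge shared by more than 2 triangles"
            )
        # consistent winding: each *directed* edge used at most once
        de = self.directed_edges()
        uniq_d = np.unique(de, axis=0)
        if len(uniq_d) != len(de):
            raise TopologyError("inconsistent winding across a shared edge")
        if (self.thickness <= 0).any():
            raise GeometryError("element thickness must be positive")
        for name, idx in self.node_sets.items():
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise TopologyError(f"node set {name!r} references bad index")

    # -- misc ----------------------------------------------------------

    def region_mask(self, region: str) -> np.ndarray:
        return self.element_region == region

    def copy(self) -> "TriMesh":
        return TriMesh(
            vertices=self.vertices.copy(),
            triangles=self.triangles.copy(),
            node_sets={k: v.copy() for k, v in self.node_sets.items()},
            element_region=self.element_region.copy(),
            thickness=self.thickness.copy(),
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _tokens(path):
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                yield line


def read_off(path) -> TriMesh:
    lines = list(_tokens(path))
    if not lines:
        raise MeshFormatError(f"{path}: empty file")
    idx = 0
    header = lines[idx].split()
    if header[0].upper() == "OFF":
        idx += 1
        if len(header) > 1:
            counts = header[1:4]
        else:
            counts = lines[idx].split()[:3]
            idx += 1
    else:
        counts = header[:3]
        idx += 1
    try:
        nv, nf = int(counts[0]), int(counts[1])
    except (ValueError, IndexError) as exc:
        raise MeshFormatError(f"{path}: bad OFF counts line") from exc
    if len(lines) < idx + nv + nf:
        raise MeshFormatError(f"{path}: truncated OFF file")
    try:
        verts = np.array(
            [[float(x) for x in lines[idx + i].split()[:3]] for i in range(nv)]
        )
    except ValueError as exc:
        raise MeshFormatError(f"{path}: bad vertex line") from exc
    idx += nv
    faces = []
    for i in range(nf):
        parts = lines[idx + i].split()
        try:
            k = int(parts[0])
            face = [int(x) for x in parts[1 : 1 + k]]
        except (ValueError, IndexError) as exc:
            raise MeshFormatError(f"{path}: bad face line {i}") from exc
        if k != 3:
            raise MeshFormatError(
                f"{path}: face {i} has {k} vertices; triangles only"
            )
        faces.append(face)
    return TriMesh(vertices=verts, triangles=np.array(faces, dtype=np.int64))


def read_obj(path) -> TriMesh:
    verts, faces = [], []
    for line in _tokens(path):
        parts = line.split()
        if parts[0] == "v":
            try:
                verts.append([float(x) for x in parts[1:4]])
            except ValueError as exc:
                raise MeshFormatError(f"{path}: bad vertex line") from exc
        elif parts[0] == "f":
            refs = parts[1:]
            if len(refs) != 3:
                raise MeshFormatError(
                    f"{path}: face with {len(refs)} vertices; triangles only"
                )
            face = []
            for r in refs:
                tok = r.split("/")[0]
                try:
                    i = int(tok)
                except ValueError as exc:
                    raise MeshFormatError(f"{path}: bad face token {r!r}") from exc
                face.append(i - 1 if i > 0 else len(verts) + i)
            faces.append(face)
    if not verts or not faces:
        raise MeshFormatError(f"{path}: no vertices or faces found")
    return TriMesh(
        vertices=np.array(verts), triangles=np.array(faces, dtype=np.int64)
    )


def read_mesh(path, fmt: str | None = None) -> TriMesh:
    """Read an OFF or OBJ triangle mesh; format inferred from suffix."""
    if fmt is None:
        fmt = str(path).rsplit(".", 1)[-1].lower()
    if fmt == "off":
        return read_off(path)
    if fmt == "obj":
        return read_obj(path)
    raise MeshFormatError(f"unsupported mesh format {fmt!r}")


def write_off(mesh: TriMesh, path):
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_triangles} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
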