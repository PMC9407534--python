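"""Parametric triangle-mesh generators for the bundled scenarios.

All generators are deterministic for a fixed parameter set (no randomized
point placement in the default layouts), return validated :class:`TriMesh`
objects, and populate the node sets the load schedules refer to.  Planar
meshes are placed in the z = 0 plane.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import MeshingError
from .mesh import DEFAULT_REGION, TriMesh

_TOL = 1e-9


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _march(
    a: float, b: float, h_min: float, h_max: float, growth: float,
    plateau: float = 0.0,
):
    """Coordinates from a to b: spacing h_min within ``plateau`` of a, then
    geometric growth up to h_max."""
    pts = [a]
    h = h_min
    x = a
    sgn = 1.0 if b > a else -1.0
    while abs(b - x) > 1.5 * h:
        x += sgn * h
        pts.append(x)
        if abs(x - a) >= plateau:
            h = min(h * growth, h_max)
    if abs(b - pts[-1]) < 0.4 * h_min and len(pts) > 1:
        pts.pop()
    pts.append(b)
    return pts


def _graded_axis(lo, hi, focus, h_min, h_max, growth=1.3, plateau=0.0):
    """Sorted coordinates spanning [lo, hi] containing focus exactly."""
    if focus <= lo + _TOL:
        return np.array(_march(lo, hi, h_min, h_max, growth, plateau))
    if focus >= hi - _TOL:
        return np.array(_march(hi, lo, h_min, h_max, growth, plateau)[::-1])
    left = _march(focus, lo, h_min, h_max, growth, plateau)[::-1]
    right = _march(focus, hi, h_min, h_max, growth, plateau)
    return np.array(left[:-1] + right)


def _symmetric_axis(lo, hi, h_min, h_max, growth=1.3, plateau=0.0):
    """Axis over [lo, hi], mirror-symmetric about the midpoint (included)."""
    mid = 0.5 * (lo + hi)
    upper = np.array(_march(mid, hi, h_min, h_max, growth, plateau))
    lower = (2.0 * mid - upper[1:])[::-1]
    return np.concatenate([lower, upper])


def _prune_unused(vertices, triangles, node_sets):
    used = np.zeros(len(vertices), dtype=bool)
    used[triangles.ravel()] = True
    remap = -np.ones(len(vertices), dtype=np.int64)
    remap[used] = np.arange(used.sum())
    tris = remap[triangles]
    sets = {}
    for name, idx in node_sets.items():
        idx = np.asarray(idx, dtype=np.int64)
        kept = idx[used[idx]]
        sets[name] = remap[kept]
    return vertices[used], tris, sets


def _grid_quads_to_tris(vid, mirror_rows=None):
    """Triangulate a structured vertex-id grid vid[i, j] (i fast along x).

    ``mirror_rows``: boolean per cell-row (j index); rows flagged True use the
    mirrored diagonal so that meshes built with :func:`_symmetric_axis` are
    exactly mirror-symmetric.
    """
    ni, nj = vid.shape
    tris = []
    for j in range(nj - 1):
        flip = bool(mirror_rows[j]) if mirror_rows is not None else False
        for i in range(ni - 1):
            v00, v10 = vid[i, j], vid[i + 1, j]
            v01, v11 = vid[i, j + 1], vid[i + 1, j + 1]
            if not flip:
                tris.append((v00, v10, v11))
                tris.append((v00, v11, v01))
            else:
                tris.append((v00, v10, v01))
                tris.append((v10, v11, v01))
    return np.array(tris, dtype=np.int64)


# ---------------------------------------------------------------------------
# notched plate (SENT)
# ---------------------------------------------------------------------------


def gen_notched_plate(
    length: float,
    width: float,
    notch_length: float,
    target_h: float,
    growth: float = 1.3,
    thickness: float = 1.0,
) -> TriMesh:
    """Rectangular strip with a single mid-height edge notch (true slit).

    The slit runs from the left edge (x = 0) at y = width/2 to the notch
    tip at x = notch_length; nodes along it are duplicated so the two slit
    faces are topologically disconnected.  The mesh is graded toward the
    tip (grid spacing <= target_h / 1.4 there) and is exactly
    mirror-symmetric about y = width/2.
    """
    if not 0.0 < notch_length < length / 2.0:
        raise ValueError("require 0 < notch_length < length/2")
    if target_h <= 0:
        raise ValueError("target_h must be positive")
    h_min = target_h / 1.6
    h_max = max(h_min, min(length, width) / 8.0)
    plateau = 3.0 * target_h  # constant-size zone around the notch tip
    xs = _graded_axis(0.0, length, notch_length, h_min, h_max, growth, plateau)
    ys = _symmetric_axis(0.0, width, h_min, h_max, growth, plateau)
    nx, ny = len(xs), len(ys)
    if nx < 3 or ny < 3:
        raise MeshingError("grading produced too few grid lines")
    j_mid = int(np.argmin(np.abs(ys - width / 2.0)))
    assert abs(ys[j_mid] - width / 2.0) < _TOL

    X, Y = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    vid = np.arange(nx * ny, dtype=np.int64).reshape(nx, ny)
    ycell = 0.5 * (ys[:-1] + ys[1:])
    mirror_rows = ycell > width / 2.0
    tris = _grid_quads_to_tris(vid, mirror_rows)

    # duplicate slit nodes (strictly left of the tip) for the lower face
    slit_cols = np.flatnonzero(xs < notch_length - _TOL)
    slit_ids = vid[slit_cols, j_mid]
    dup_ids = np.arange(len(verts), len(verts) + len(slit_ids), dtype=np.int64)
    verts = np.vstack([verts, verts[slit_ids]])
    dup_of = dict(zip(slit_ids.tolist(), dup_ids.tolist()))
    cent_y = verts[tris].mean(axis=1)[:, 1]
    lower = cent_y < width / 2.0
    for e in np.flatnonzero(lower):
        for k in range(3):
            v = int(tris[e, k])
            if v in dup_of:
                tris[e, k] = dup_of[v]

    tip_id = int(vid[int(np.argmin(np.abs(xs - notch_length))), j_mid])
    node_sets = {
        "left": np.flatnonzero(np.abs(verts[:, 0]) < _TOL),
        "right": np.flatnonzero(np.abs(verts[:, 0] - length) < _TOL),
        "bottom": np.flatnonzero(np.abs(verts[:, 1]) < _TOL),
        "top": np.flatnonzero(np.abs(verts[:, 1] - width) < _TOL),
        "notch_tip": np.array([tip_id], dtype=np.int64),
    }
    return TriMesh(
        vertices=verts,
        triangles=tris,
        node_sets=node_sets,
        element_region=np.full(len(tris), DEFAULT_REGION, dtype=object),
        thickness=np.full(len(tris), float(thickness)),
    )


# ---------------------------------------------------------------------------
# perforated sphere patch
# ---------------------------------------------------------------------------


def gen_perforated_sphere_patch(
    R: float,
    r_hole: float,
    n_holes: int,
    symmetry: str = "octant",
    target_h: float = 0.05,
    hole_colatitude: float = math.pi / 4,
    thickness: float = 0.02,
) -> TriMesh:
    """Spherical patch (octant or quadrant) with circular perforations.

    The patch covers colatitude theta in [0, pi/2] and azimuth phi in
    [0, pi/2] (octant) or [0, pi] (quadrant).  Holes are cut by removing
    triangles whose centroid lies within geodesic distance ``r_hole`` of a
    hole center; centers sit on the ``hole_colatitude`` circle, evenly
    spaced in azimuth.
    """
    if symmetry not in ("octant", "quadrant"):
        raise ValueError("symmetry must be 'octant' or 'quadrant'")
    if not 0 < r_hole < R / 10.0:
        raise ValueError("require 0 < r_hole < R/10")
    if n_holes < 1:
        raise ValueError("n_holes must be >= 1")
    phi_max = math.pi / 2 if symmetry == "octant" else math.pi
    n_theta = max(8, math.ceil((math.pi / 2) * R / target_h))
    n_phi = max(8, math.ceil(phi_max * R / target_h))
    thetas = np.linspace(0.0, math.pi / 2, n_theta + 1)
    phis = np.linspace(0.0, phi_max, n_phi + 1)

    rho = r_hole / R  # angular hole radius
    centers_ang = [
        (hole_colatitude, phi_max * (k + 0.5) / n_holes) for k in range(n_holes)
    ]

    def _unit(theta, phi):
        return np.array(
            [
                math.sin(theta) * math.cos(phi),
                math.sin(theta) * math.sin(phi),
                math.cos(theta),
            ]
        )

    centers = np.array([_unit(t, p) for t, p in centers_ang])
    for a in range(n_holes):
        for b in range(a + 1, n_holes):
            gap = math.acos(np.clip(centers[a] @ centers[b], -1, 1))
            if gap < 2.2 * rho:
                raise MeshingError(
                    f"holes {a} and {b} overlap (separation {gap:.3f} rad)"
                )
        edge_margin = min(
            centers_ang[a][1], phi_max - centers_ang[a][1], centers_ang[a][0]
        ) * math.sin(max(centers_ang[a][0], 1e-6))
        if edge_margin < 1.5 * rho:
            raise MeshingError(f"hole {a} too close to the patch boundary")

    # vertices: pole + (n_theta x (n_phi+1)) grid
    verts = [np.array([0.0, 0.0, R])]
    vid = np.zeros((n_theta + 1, n_phi + 1), dtype=np.int64)
    vid[0, :] = 0
    for i in range(1, n_theta + 1):
        for j in range(n_phi + 1):
            vid[i, j] = len(verts)
            verts.append(R * _unit(thetas[i], phis[j]))
    verts = np.array(verts)

    tris = []
    for j in range(n_phi):
        tris.append((0, vid[1, j], vid[1, j + 1]))
    for i in range(1, n_theta):
        for j in range(n_phi):
            v00, v10 = vid[i, j], vid[i + 1, j]
            v01, v11 = vid[i, j + 1], vid[i + 1, j + 1]
            tris.append((v00, v10, v11))
            tris.append((v00, v11, v01))
    tris = np.array(tris, dtype=np.int64)

    cent = verts[tris].mean(axis=1)
    cent_u = cent / np.linalg.norm(cent, axis=1)[:, None]
    keep = np.ones(len(tris), dtype=bool)
    for k in range(n_holes):
        d = np.arccos(np.clip(cent_u @ centers[k], -1, 1))
        cut = d < rho
        if not cut.any():
            raise MeshingError(
                f"target_h too coarse to resolve hole {k} (no triangle cut)"
            )
        keep &= ~cut
    tris = tris[keep]

    theta_v = np.arccos(np.clip(verts[:, 2] / R, -1, 1))
    node_sets = {
        "pole": np.flatnonzero(theta_v <= thetas[2] + _TOL),
        "equator": np.flatnonzero(np.abs(verts[:, 2]) < R * 1e-9),
        "symmetry_y0": np.flatnonzero(np.abs(verts[:, 1]) < R * 1e-9),
        "symmetry_x0": np.flatnonzero(
            np.abs(verts[:, 0]) < R * 1e-9
            if symmetry == "octant"
            else np.zeros(len(verts), dtype=bool)
        ),
    }
    node_sets["symmetry_edges"] = np.unique(
        np.concatenate([node_sets["symmetry_y0"], node_sets["symmetry_x0"]])
    )
    verts, tris, node_sets = _prune_unused(verts, tris, node_sets)
    return TriMesh(
        vertices=verts,
        triangles=tris,
        node_sets=node_sets,
        element_region=np.full(len(tris), DEFAULT_REGION, dtype=object),
        thickness=np.full(len(tris), float(thickness)),
    )


# ---------------------------------------------------------------------------
# fibered strip
# ---------------------------------------------------------------------------


def gen_fiber_strip(
    length: float,
    width: float,
    thickness: float,
    n_fibers: int,
    n_crosslinks: int = 3,
    target_h: float = 0.05,
) -> TriMesh:
    """Planar lattice of longitudinal fibers tied by transverse crosslinks.

    Fibers and gaps alternate with equal width ``width / (2 n_fibers - 1)``;
    crosslink bands of the same width sit at evenly spaced interior x
    positions.  Node sets: "left", "right", "center".
    """
    if n_fibers < 2:
        raise ValueError("n_fibers must be >= 2")
    if n_crosslinks < 1:
        raise ValueError("n_crosslinks must be >= 1")
    fw = width / (2 * n_fibers - 1)
    if target_h >= fw:
        raise ValueError("target_h must be smaller than the fiber width")
    nx = max(2, math.ceil(length / target_h))
    ny = max(2, math.ceil(width / target_h))
    xs = np.linspace(0.0, length, nx + 1)
    ys = np.linspace(0.0, width, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    vid = np.arange(X.size, dtype=np.int64).reshape(nx + 1, ny + 1)
    tris = _grid_quads_to_tris(vid)

    cent = verts[tris].mean(axis=1)
    in_fiber = np.zeros(len(tris), dtype=bool)
    for i in range(n_fibers):
        lo, hi = 2 * i * fw, (2 * i + 1) * fw
        in_fiber |= (cent[:, 1] >= lo - _TOL) & (cent[:, 1] <= hi + _TOL)
    in_cross = np.zeros(len(tris), dtype=bool)
    xcs = [length * (k + 1) / (n_crosslinks + 1) for k in range(n_crosslinks)]
    for xc in xcs:
        in_cross |= np.abs(cent[:, 0] - xc) <= fw / 2 + _TOL
    keep = in_fiber | in_cross
    if not keep.any():
        raise MeshingError("fiber layout kept no elements")
    tris = tris[keep]

    node_sets = {
        "left": np.flatnonzero(np.abs(verts[:, 0]) < _TOL),
        "right": np.flatnonzero(np.abs(verts[:, 0] - length) < _TOL),
        "center": np.flatnonzero(np.abs(verts[:, 0] - length / 2) <= fw / 2 + _TOL),
    }
    verts, tris, node_sets = _prune_unused(verts, tris, node_sets)
    mesh = TriMesh(
        vertices=verts,
        triangles=tris,
        node_sets=node_sets,
        element_region=np.full(len(tris), DEFAULT_REGION, dtype=object),
        thickness=np.full(len(tris), float(thickness)),
    )
    if mesh.n_connected_components() != 1:
        raise MeshingError("fiber lattice is not a single connected component")
    return mesh


# ---------------------------------------------------------------------------
# curved cap with bonded patch region
# ---------------------------------------------------------------------------


def gen_cap_with_patch(
    R_major: float,
    R_minor: float,
    patch_angle: float,
    target_h: float,
    cap_angle: float = math.pi / 2,
    thickness: float = 0.02,
) -> TriMesh:
    """Ellipsoidal cap with a central "hydrogel" patch on a "substrate".

    The cap is the surface x = R_major sin(t) cos(phi), y = R_major sin(t)
    sin(phi), z = R_minor cos(t) for t in [0, cap_angle], closed in phi.
    Elements whose parametric colatitude midpoint is below ``patch_angle``
    get region "hydrogel"; the rest get "substrate".  Node set: "rim".
    """
    if not 0.0 < patch_angle < math.pi / 2:
        raise ValueError("require 0 < patch_angle < pi/2")
    if patch_angle >= cap_angle:
        raise ValueError("patch_angle must be smaller than cap_angle")
    arc = cap_angle * math.sqrt((R_major**2 + R_minor**2) / 2.0)
    n_theta = max(6, math.ceil(arc / target_h))
    n_phi = max(8, math.ceil(2 * math.pi * R_major / target_h))
    thetas = np.linspace(0.0, cap_angle, n_theta + 1)
    phis = np.linspace(0.0, 2 * math.pi, n_phi, endpoint=False)

    verts = [np.array([0.0, 0.0, R_minor])]
    vid = np.zeros((n_theta + 1, n_phi), dtype=np.int64)
    for i in range(1, n_theta + 1):
        st, ct = math.sin(thetas[i]), math.cos(thetas[i])
        for j in range(n_phi):
            vid[i, j] = len(verts)
            verts.append(
                np.array(
                    [
                        R_major * st * math.cos(phis[j]),
                        R_major * st * math.sin(phis[j]),
                        R_minor * ct,
                    ]
                )
            )
    verts = np.array(verts)

    tris, tri_theta = [], []
    for j in range(n_phi):
        jn = (j + 1) % n_phi
        tris.append((0, vid[1, j], vid[1, jn]))
        tri_theta.append(0.5 * (thetas[0] + thetas[1]))
    for i in range(1, n_theta):
        tmid = 0.5 * (thetas[i] + thetas[i + 1])
        for j in range(n_phi):
            jn = (j + 1) % n_phi
            tris.append((vid[i, j], vid[i + 1, j], vid[i + 1, jn]))
            tris.append((vid[i, j], vid[i + 1, jn], vid[i, jn]))
            tri_theta += [tmid, tmid]
    tris = np.array(tris, dtype=np.int64)
    tri_theta = np.array(tri_theta)
    region = np.where(tri_theta < patch_angle, "hydrogel", "substrate").astype(
        object
    )
    if (region == "hydrogel").sum() == 0 or (region == "substrate").sum() == 0:
        raise MeshingError("patch_angle leaves an empty region")

    node_sets = {
        "rim": vid[n_theta, :].copy(),
        "pole": np.array([0], dtype=np.int64),
    }
    return TriMesh(
        vertices=verts,
        triangles=tris,
        node_sets=node_sets,
        element_region=region,
        thickness=np.full(len(tris), float(thickness)),
    )


# ---------------------------------------------------------------------------
# icosphere (closed test surface)
# ---------------------------------------------------------------------------


def gen_icosphere(radius: float = 1.0, subdivisions: int = 2) -> TriMesh:
    """Closed, boundary-free sphere mesh by icosahedron subdivision."""
    t = (1.0 + math.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, t, 0], [1, t, 0], [-1, -t, 0], [1, -t, 0],
            [0, -1, t], [0, 1, t], [0, -1, -t], [0, 1, -t],
            [t, 0, -1], [t, 0, 1], [-t, 0, -1], [-t, 0, 1],
        ],
        dtype=np.float64,
    )
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [v / np.linalg.norm(v) for v in verts]
    for _ in range(subdivisions):
        cache: dict = {}
        new_faces = []

        def midpoint(a, b):
            key = (min(a, b), max(a, b))
            if key not in cache:
                m = verts[a] + verts[b]
                verts.append(m / np.linalg.norm(m))
                cache[key] = len(verts) - 1
            return cache[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    verts = np.array(verts) * radius
    return TriMesh(vertices=verts, triangles=np.array(faces, dtype=np.int64))


GENERATORS = {
    "notched_plate": gen_notched_plate,
    "perforated_sphere_patch": gen_perforated_sphere_patch,
    "fiber_strip": gen_fiber_strip,
    "cap_with_patch": gen_cap_with_patch,
    "icosphere": gen_icosphere,
}
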