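"""Membrane (constant-strain triangle) mechanics on curved surfaces.

Each triangle carries a reference orthonormal tangent frame.  The current
deformation enters through the 3x2 matrix M mapping reference tangent
coordinates to current edge vectors; its two singular values are the
in-plane principal stretches.  The through-thickness stretch lambda_3 is
closed by the plane-stress condition dW/dlambda_3 = 0 (solved by a
vectorized safeguarded bisection), so the element energy is a function of M
alone and nodal forces follow from the envelope theorem:

    dE/dx = area * t * (dW/dM) (Dref^-1)^T  scattered to the three nodes.

An optional discrete-hinge bending energy (quadratic in the dihedral-angle
change, degraded like the tensile membrane part) can be switched on to
stabilize compressive scenarios; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constitutive import (
    HydrogelMaterial,
    OgdenMaterial,
    degradation,
    dogden_dlambda,
    dsplit_dlambda,
    ogden_energy_principal,
    split_energy_principal,
)
from .errors import GeometryError, RootBracketError
from .mesh import TriMesh

_L3_LO, _L3_HI = 1e-3, 1e3
_BISECT_ITERS = 60


# ---------------------------------------------------------------------------
# quadrature and frames
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThicknessRule:
    """Gauss rule through the shell thickness; weights sum to t."""

    n_gauss: int = 3

    def __post_init__(self):
        if self.n_gauss < 1:
            raise ValueError("n_gauss must be >= 1")

    def points_weights(self, t: float):
        if self.n_gauss == 1:
            return np.array([0.0]), np.array([float(t)])
        z, w = np.polynomial.legendre.leggauss(self.n_gauss)
        return 0.5 * t * z, 0.5 * t * w


@dataclass
class ElementFrames:
    """Reference tangent bases and inverted in-plane edge matrices."""

    tangent: np.ndarray  # (m, 3, 2)
    normal: np.ndarray  # (m, 3)
    Dinv: np.ndarray  # (m, 2, 2)
    area: np.ndarray  # (m,)


def build_frames(mesh: TriMesh) -> ElementFrames:
    v = mesh.vertices
    t = mesh.triangles
    e1 = v[t[:, 1]] - v[t[:, 0]]
    e2 = v[t[:, 2]] - v[t[:, 0]]
    n = np.cross(e1, e2)
    n_norm = np.linalg.norm(n, axis=1)
    if np.any(n_norm < 1e-14):
        bad = int(np.flatnonzero(n_norm < 1e-14)[0])
        raise GeometryError(f"reference triangle {bad} is degenerate")
    normal = n / n_norm[:, None]
    t1 = e1 / np.linalg.norm(e1, axis=1)[:, None]
    t2 = np.cross(normal, t1)
    tangent = np.stack([t1, t2], axis=2)  # (m, 3, 2)
    # in-plane edge matrix D = [[e1.t1, e2.t1], [0, e2.t2]]
    d11 = np.einsum("ij,ij->i", e1, t1)
    d12 = np.einsum("ij,ij->i", e2, t1)
    d22 = np.einsum("ij,ij->i", e2, t2)
    det = d11 * d22
    Dinv = np.empty((len(t), 2, 2))
    Dinv[:, 0, 0] = d22 / det
    Dinv[:, 0, 1] = -d12 / det
    Dinv[:, 1, 0] = 0.0
    Dinv[:, 1, 1] = d11 / det
    return ElementFrames(
        tangent=tangent, normal=normal, Dinv=Dinv, area=0.5 * n_norm
    )


def membrane_matrix(frames: ElementFrames, positions, triangles) -> np.ndarray:
    """Current 3x2 membrane deformation matrices M = C Dref^-1."""
    c1 = positions[triangles[:, 1]] - positions[triangles[:, 0]]
    c2 = positions[triangles[:, 2]] - positions[triangles[:, 0]]
    C = np.stack([c1, c2], axis=2)  # (m, 3, 2)
    return C @ frames.Dinv


# ---------------------------------------------------------------------------
# plane-stress thickness stretch
# ---------------------------------------------------------------------------


def _ps_residual_hydrogel(l3, s1, s2, g, mu, chi):
    """d(degraded W)/dlambda_3 at fixed in-plane stretches; g = g(p)."""
    J = s1 * s2 * l3
    iso = mu * (l3 - 1.0 / l3)
    r = np.where(l3 > 1.0, g * iso, iso)
    vol = chi * (J - 1.0) * s1 * s2
    return r + np.where(J > 1.0, g * vol, vol)


def _ps_residual_ogden(l3, s1, s2, mat: OgdenMaterial):
    J = s1 * s2 * l3
    Jm13 = J ** (-1.0 / 3.0)
    lb = (
        (s1 * Jm13) ** mat.alpha
        + (s2 * Jm13) ** mat.alpha
        + (l3 * Jm13) ** mat.alpha
    )
    dev = (2.0 * mat.mu_og / mat.alpha) / l3 * ((l3 * Jm13) ** mat.alpha - lb / 3.0)
    return dev + mat.k_og * (J - 1.0) * s1 * s2


def _bisect_lambda3(residual, lo=_L3_LO, hi=_L3_HI, iters=_BISECT_ITERS):
    """Vectorized bisection for the monotone plane-stress residual."""
    r_lo = residual(np.asarray(lo, dtype=np.float64))
    r_hi = residual(np.asarray(hi, dtype=np.float64))
    if np.any(r_lo > 0) or np.any(r_hi < 0):
        raise RootBracketError(
            "plane-stress residual has no sign change on "
            f"[{_L3_LO}, {_L3_HI}]"
        )
    a = np.broadcast_to(np.float64(lo), np.shape(r_lo)).copy()
    b = np.broadcast_to(np.float64(hi), np.shape(r_hi)).copy()
    for _ in range(iters):
        mid = 0.5 * (a + b)
        neg = residual(mid) < 0.0
        a = np.where(neg, mid, a)
        b = np.where(neg, b, mid)
    return 0.5 * (a + b)


def plane_stress_lambda3(
    lambda1: float,
    lambda2: float,
    p: float,
    mat: HydrogelMaterial,
    xtol: float = 1e-12,
) -> float:
    """Thickness stretch minimizing the degraded energy at fixed (l1, l2, p).

    The through-thickness Cauchy stress vanishes at the returned value.
    """
    if lambda1 <= 0 or lambda2 <= 0:
        raise ValueError("in-plane stretches must be positive")
    g = float(degradation(p, mat.k_res))

    def res(l3):
        return float(
            _ps_residual_hydrogel(
                np.float64(l3), lambda1, lambda2, g, mat.mu, mat.chi
            )
        )

    r_lo, r_hi = res(_L3_LO), res(_L3_HI)
    if r_lo > 0 or r_hi < 0:
        raise RootBracketError(
            f"no bracket for lambda3 at (l1={lambda1}, l2={lambda2}, p={p})"
        )
    return float(brentq(res, _L3_LO, _L3_HI, xtol=xtol))


# ---------------------------------------------------------------------------
# per-element state (spec-facing scalar helpers)
# ---------------------------------------------------------------------------


def element_deformation_gradient(
    frames: ElementFrames, e: int, positions, triangles, lambda3: float
) -> np.ndarray:
    """Full 3x3 deformation gradient of element e with thickness stretch."""
    if lambda3 <= 0:
        raise ValueError("lambda3 must be positive")
    tri = triangles[e]
    c1 = positions[tri[1]] - positions[tri[0]]
    c2 = positions[tri[2]] - positions[tri[0]]
    n = np.cross(c1, c2)
    n_norm = np.linalg.norm(n)
    if n_norm < 1e-14:
        raise GeometryError(f"current triangle {e} is degenerate")
    n_cur = n / n_norm
    M = np.stack([c1, c2], axis=1) @ frames.Dinv[e]
    return M @ frames.tangent[e].T + lambda3 * np.outer(n_cur, frames.normal[e])


# ---------------------------------------------------------------------------
# region materials and the membrane model
# ---------------------------------------------------------------------------


@dataclass
class RegionMaterial:
    """Material assigned to an element_region label."""

    material: object  # HydrogelMaterial | OgdenMaterial
    phase_field: bool | None = None  # default: hydrogel yes, ogden no

    def __post_init__(self):
        if self.phase_field is None:
            self.phase_field = isinstance(self.material, HydrogelMaterial)


@dataclass
class MembraneResult:
    energy: float
    forces: np.ndarray | None
    e_plus: float  # degraded tensile energy
    e_minus: float
    e_bend: float
    elem_w_plus: np.ndarray  # per-element thickness-averaged W+ (undegraded)
    lambda3: np.ndarray
    svals: np.ndarray  # (m, 2) in-plane principal stretches
    p_elem: np.ndarray


@dataclass
class BendingConfig:
    enabled: bool = False
    stiffness: float = 0.0


class MembraneModel:
    """Assembles energy, nodal forces and diagnostics over the whole mesh."""

    def __init__(
        self,
        mesh: TriMesh,
        materials: dict,
        rule: ThicknessRule = ThicknessRule(3),
        bending: BendingConfig | None = None,
    ):
        self.mesh = mesh
        self.rule = rule
        self.frames = build_frames(mesh)
        self.materials = {
            k: (v if isinstance(v, RegionMaterial) else RegionMaterial(v))
            for k, v in materials.items()
        }
        regions = set(np.unique(mesh.element_region))
        missing = regions - set(self.materials)
        if missing:
            raise ValueError(f"no material for region(s) {sorted(missing)}")
        self.groups = {
            r: np.flatnonzero(mesh.element_region == r)
            for r in sorted(regions)
        }
        self.phase_mask = np.zeros(mesh.n_triangles, dtype=bool)
        for r, idx in self.groups.items():
            if self.materials[r].phase_field:
                self.phase_mask[idx] = True
        self.bending = (
            _HingeBending(mesh, bending.stiffness)
            if bending is not None and bending.enabled and mesh.n_triangles > 1
            else None
        )
        self._warned = False

    # -- core evaluation ----------------------------------------------

    def evaluate(
        self, positions, p_vertex, compute_forces: bool = True
    ) -> MembraneResult:
        mesh = self.mesh
        tris = mesh.triangles
        m = mesh.n_triangles
        p_elem = p_vertex[tris].mean(axis=1)
        M = membrane_matrix(self.frames, positions, tris)
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        s = np.maximum(s, 1e-9)  # guard collapsed current triangles
        s1, s2 = s[:, 0], s[:, 1]

        lam3 = np.ones(m)
        w_plus = np.zeros(m)
        w_minus = np.zeros(m)
        g1 = np.zeros(m)  # dW/ds1 (degraded where applicable)
        g2 = np.zeros(m)
        e_plus = 0.0
        e_minus = 0.0
        scale = self.frames.area * mesh.thickness

        for r, idx in self.groups.items():
            rm = self.materials[r]
            mat = rm.material
            if isinstance(mat, HydrogelMaterial):
                g = degradation(p_elem[idx], mat.k_res)

                def res(l3, _s1=s1[idx], _s2=s2[idx], _g=g, _m=mat):
                    return _ps_residual_hydrogel(l3, _s1, _s2, _g, _m.mu, _m.chi)

                l3 = _bisect_lambda3(res)
                lams = np.stack([s1[idx], s2[idx], l3], axis=1)
                J = s1[idx] * s2[idx] * l3
                wp, wm = split_energy_principal(lams, J, mat.mu, mat.chi)
                dp, dm = dsplit_dlambda(lams, J, mat.mu, mat.chi)
                gcol = g
                lam3[idx] = l3
                w_plus[idx] = wp
                w_minus[idx] = wm
                g1[idx] = gcol * dp[:, 0] + dm[:, 0]
                g2[idx] = gcol * dp[:, 1] + dm[:, 1]
                e_plus += float((scale[idx] * gcol * wp).sum())
                e_minus += float((scale[idx] * wm).sum())
            elif isinstance(mat, OgdenMaterial):

                def res(l3, _s1=s1[idx], _s2=s2[idx], _m=mat):
                    return _ps_residual_ogden(l3, _s1, _s2, _m)

                l3 = _bisect_lambda3(res)
                lams = np.stack([s1[idx], s2[idx], l3], axis=1)
                J = s1[idx] * s2[idx] * l3
                w = ogden_energy_principal(lams, J, mat)
                dW = dogden_dlambda(lams, J, mat)
                lam3[idx] = l3
                w_minus[idx] = w  # undamageable: bookkept as compressive
                g1[idx] = dW[:, 0]
                g2[idx] = dW[:, 1]
                e_minus += float((scale[idx] * w).sum())
            else:  # pragma: no cover
                raise TypeError(f"unsupported material {type(mat)!r}")

        energy = e_plus + e_minus
        forces = None
        if compute_forces:
            # dW/dM = U diag(g1, g2) V^T ; dE/dC = area t dW/dM Dinv^T
            dWdM = np.einsum("eik,ek,ekj->eij", U, np.stack([g1, g2], 1), Vt)
            dEdC = scale[:, None, None] * (dWdM @ np.transpose(self.frames.Dinv, (0, 2, 1)))
            forces = np.zeros_like(positions)
            np.add.at(forces, tris[:, 1], dEdC[:, :, 0])
            np.add.at(forces, tris[:, 2], dEdC[:, :, 1])
            np.add.at(forces, tris[:, 0], -dEdC[:, :, 0] - dEdC[:, :, 1])

        e_bend = 0.0
        if self.bending is not None:
            k_res = self._any_k_res()
            eb, fb = self.bending.energy_forces(
                positions, p_elem, k_res, compute_forces
            )
            e_bend = eb
            energy += eb
            if compute_forces and fb is not None:
                forces += fb

        return MembraneResult(
            energy=energy,
            forces=forces,
            e_plus=e_plus,
            e_minus=e_minus,
            e_bend=e_bend,
            elem_w_plus=w_plus,
            lambda3=lam3,
            svals=s,
            p_elem=p_elem,
        )

    def _any_k_res(self) -> float:
        for rm in self.materials.values():
            if isinstance(rm.material, HydrogelMaterial):
                return rm.material.k_res
        return 1e-4

    # -- diagnostics ---------------------------------------------------

    def effective_stress(self, positions, p_vertex) -> np.ndarray:
        """Per-element von Mises equivalent Cauchy stress."""
        res = self.evaluate(positions, p_vertex, compute_forces=False)
        tris = self.mesh.triangles
        M = membrane_matrix(self.frames, positions, tris)
        U, s, Vt = np.linalg.svd(M, full_matrices=False)
        s = np.maximum(s, 1e-9)
        p_elem = res.p_elem
        m = self.mesh.n_triangles
        g = np.zeros((m, 2))
        for r, idx in self.groups.items():
            mat = self.materials[r].material
            lams = np.stack([s[idx, 0], s[idx, 1], res.lambda3[idx]], axis=1)
            J = lams.prod(axis=1)
            if isinstance(mat, HydrogelMaterial):
                dp, dm = dsplit_dlambda(lams, J, mat.mu, mat.chi)
                gg = degradation(p_elem[idx], mat.k_res)
                g[idx] = (gg[:, None] * dp + dm)[:, :2]
            else:
                g[idx] = dogden_dlambda(lams, J, mat)[:, :2]
        # P = U diag(g) V^T mapped back to 3D right-hand frame; the normal
        # principal stress is zero at the plane-stress optimum.
        dWdM = np.einsum("eik,ek,ekj->eij", U, g, Vt)
        P3 = dWdM @ np.transpose(self.frames.tangent, (0, 2, 1))
        # full F for the push-forward
        c1 = positions[tris[:, 1]] - positions[tris[:, 0]]
        c2 = positions[tris[:, 2]] - positions[tris[:, 0]]
        n = np.cross(c1, c2)
        n_cur = n / np.maximum(np.linalg.norm(n, axis=1), 1e-300)[:, None]
        F = M @ np.transpose(self.frames.tangent, (0, 2, 1))
        F += res.lambda3[:, None, None] * np.einsum(
            "ei,ej->eij", n_cur, self.frames.normal
        )
        J = s[:, 0] * s[:, 1] * res.lambda3
        sigma = np.einsum("eij,ekj->eik", P3, F) / J[:, None, None]
        tr = np.trace(sigma, axis1=1, axis2=2) / 3.0
        dev = sigma - tr[:, None, None] * np.eye(3)[None]
        return np.sqrt(1.5 * np.einsum("eij,eij->e", dev, dev))


# ---------------------------------------------------------------------------
# spec-facing wrappers
# ---------------------------------------------------------------------------


def element_avg_energy(model: MembraneModel, e: int, positions, p_vertex):
    """Thickness-averaged (W+, W-) of element e via the Gauss rule.

    In pure-membrane mode every Gauss point sees the same deformation
    gradient, so the average equals the single-point value; the quadrature
    loop is kept to honor the averaging contract.
    """
    res = model.evaluate(positions, p_vertex, compute_forces=False)
    mat = model.materials[str(model.mesh.element_region[e])].material
    lams = np.array([res.svals[e, 0], res.svals[e, 1], res.lambda3[e]])
    J = np.float64(lams.prod())
    if isinstance(mat, HydrogelMaterial):
        wp_pt, wm_pt = split_energy_principal(lams, J, mat.mu, mat.chi)
    else:
        wp_pt, wm_pt = np.float64(0.0), ogden_energy_principal(lams, J, mat)
    t = float(model.mesh.thickness[e])
    _, w = model.rule.points_weights(t)
    wp = float(sum(wi * wp_pt for wi in w) / w.sum())
    wm = float(sum(wi * wm_pt for wi in w) / w.sum())
    return wp, wm


def internal_forces(
    mesh: TriMesh,
    positions,
    p_vertex,
    materials: dict,
    rule: ThicknessRule = ThicknessRule(3),
    bending: BendingConfig | None = None,
):
    """(nodal force vector, total energy) for the given state."""
    model = MembraneModel(mesh, materials, rule, bending)
    res = model.evaluate(positions, p_vertex, compute_forces=True)
    return res.forces, res.energy


# ---------------------------------------------------------------------------
# discrete-hinge bending
# ---------------------------------------------------------------------------


class _HingeBending:
    """Quadratic dihedral-angle bending on interior edges.

    E = sum_e g(p_e) * k * 3 |e|^2 / (A1 + A2) * (theta - theta_ref)^2
    with reference quantities frozen from the undeformed mesh and p_e the
    mean of the two adjacent element phase values.
    """

    def __init__(self, mesh: TriMesh, stiffness: float):
        self.stiffness = float(stiffness)
        edge_info: dict = {}
        t = mesh.triangles
        for e in range(len(t)):
            a, b, c = (int(x) for x in t[e])
            for (i, j, k) in ((a, b, c), (b, c, a), (c, a, b)):
                key = (min(i, j), max(i, j))
                edge_info.setdefault(key, []).append((e, i, j, k))
        quads = []
        for key, lst in edge_info.items():
            if len(lst) == 2:
                (eA, i0, i1, i2), (eB, _, _, i3) = lst
                quads.append((i0, i1, i2, i3, eA, eB))
        if not quads:
            self.n = 0
            return
        q = np.array(quads, dtype=np.int64)
        self.i0, self.i1, self.i2, self.i3 = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
        self.eA, self.eB = q[:, 4], q[:, 5]
        self.n = len(q)
        v = mesh.vertices
        elen2 = np.sum((v[self.i1] - v[self.i0]) ** 2, axis=1)
        areas = mesh.areas()
        self.coef = 3.0 * elen2 / (areas[self.eA] + areas[self.eB])
        self.theta_ref = self._angles(v)[0]

    def _angles(self, positions):
        x0 = positions[self.i0]
        e0 = positions[self.i1] - x0
        e1 = positions[self.i2] - x0
        e2 = positions[self.i3] - x0
        nA = np.cross(e0, e1)
        nB = np.cross(e2, e0)
        elen = np.linalg.norm(e0, axis=1)
        sin_t = np.einsum("ij,ij->i", np.cross(nA, nB), e0) / np.maximum(
            elen, 1e-300
        )
        cos_t = np.einsum("ij,ij->i", nA, nB)
        return np.arctan2(sin_t, cos_t), (e0, e1, e2, nA, nB, elen)

    def energy_forces(self, positions, p_elem, k_res, compute_forces=True):
        if self.n == 0 or self.stiffness == 0.0:
            return 0.0, None
        theta, (e0, e1, e2, nA, nB, elen) = self._angles(positions)
        p_edge = 0.5 * (p_elem[self.eA] + p_elem[self.eB])
        g = degradation(p_edge, k_res)
        dtheta = theta - self.theta_ref
        k = self.stiffness * self.coef * g
        energy = float(np.sum(k * dtheta**2))
        if not compute_forces:
            return energy, None
        # gradient of the dihedral angle w.r.t. the four stencil vertices
        nA2 = np.einsum("ij,ij->i", nA, nA)
        nB2 = np.einsum("ij,ij->i", nB, nB)
        gA = nA / np.maximum(nA2, 1e-300)[:, None]
        gB = nB / np.maximum(nB2, 1e-300)[:, None]
        d01 = np.einsum("ij,ij->i", e0, e1) / elen
        d02 = np.einsum("ij,ij->i", e0, e2) / elen
        grad2 = -elen[:, None] * gA
        grad3 = -elen[:, None] * gB
        grad1 = d01[:, None] * gA + d02[:, None] * gB
        grad0 = -(grad1 + grad2 + grad3)
        w = (2.0 * k * dtheta)[:, None]
        forces = np.zeros_like(positions)
        np.add.at(forces, self.i0, w * grad0)
        np.add.at(forces, self.i1, w * grad1)
        np.add.at(forces, self.i2, w * grad2)
        np.add.at(forces, self.i3, w * grad3)
        return energy, forces
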