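import numpy as np
import pytest

from gelshell import (
    HydrogelMaterial,
    MembraneModel,
    OgdenMaterial,
    ThicknessRule,
    internal_forces,
    plane_stress_lambda3,
)
from gelshell.constitutive import degradation, split_energy_principal
from gelshell.generators import gen_notched_plate
from gelshell.shell import (
    BendingConfig,
    build_frames,
    element_avg_energy,
    element_deformation_gradient,
)

from conftest import random_rotation


@pytest.fixture
def small_mesh():
    return gen_notched_plate(1.0, 1.0, 0.3, 0.12)


@pytest.fixture
def model(small_mesh, hydrogel):
    return MembraneModel(small_mesh, {"default": hydrogel})


def _deformed_state(mesh, rng, amp=0.02):
    pos = mesh.vertices.copy()
    pos[:, 0] *= 1.15
    pos[:, 1] *= 0.95
    pos += amp * rng.standard_normal(pos.shape)
    p = np.clip(rng.uniform(0.3, 1.0, mesh.n_vertices), 0, 1)
    return pos, p


class TestThicknessRule:
    def test_weights_sum_to_thickness(self):
        for ng in (1, 3, 5):
            z, w = ThicknessRule(ng).points_weights(0.1)
            assert w.sum() == pytest.approx(0.1, abs=1e-14)
            assert np.abs(z).max() <= 0.05 + 1e-14

    def test_invalid_ng(self):
        with pytest.raises(ValueError):
            ThicknessRule(0)


class TestFrames:
    def test_orthonormal(self, small_mesh):
        fr = build_frames(small_mesh)
        T = fr.tangent
        g11 = np.einsum("eij,eij->ej", T, T)
        np.testing.assert_allclose(g11, 1.0, atol=1e-12)
        cross = np.einsum("ei,ei->e", T[:, :, 0], T[:, :, 1])
        np.testing.assert_allclose(cross, 0.0, atol=1e-12)
        np.testing.assert_allclose(
            np.einsum("ei,eij->ej", fr.normal, T), 0.0, atol=1e-12
        )


class TestElementDeformationGradient:
    def test_reference_is_identity(self, small_mesh):
        fr = build_frames(small_mesh)
        F = element_deformation_gradient(
            fr, 0, small_mesh.vertices, small_mesh.triangles, 1.0
        )
        s = np.linalg.svd(F, compute_uv=False)
        np.testing.assert_allclose(s, 1.0, atol=1e-12)

    def test_uniform_stretch(self, small_mesh):
        fr = build_frames(small_mesh)
        pos = small_mesh.vertices * 1.3
        F = element_deformation_gradient(
            fr, 5, pos, small_mesh.triangles, 0.7
        )
        s = np.linalg.svd(F, compute_uv=False)
        np.testing.assert_allclose(sorted(s), [0.7, 1.3, 1.3], atol=1e-12)

    def test_rigid_rotation(self, small_mesh, hydrogel, rng):
        fr = build_frames(small_mesh)
        R = random_rotation(rng)
        pos = small_mesh.vertices @ R.T
        F = element_deformation_gradient(
            fr, 3, pos, small_mesh.triangles, 1.0
        )
        s = np.linalg.svd(F, compute_uv=False)
        np.testing.assert_allclose(s, 1.0, atol=1e-12)
        lams = np.sort(s)[::-1]
        wp, wm = split_energy_principal(
            lams, np.prod(lams), hydrogel.mu, hydrogel.chi
        )
        assert wp == pytest.approx(0.0, abs=1e-12)
        assert wm == pytest.approx(0.0, abs=1e-12)


class TestPlaneStress:
    def test_stress_free(self, hydrogel):
        for p in (0.0, 0.4, 1.0):
            assert plane_stress_lambda3(1.0, 1.0, p, hydrogel) == pytest.approx(
                1.0, abs=1e-10
            )

    def test_incompressible_limit(self):
        mat = HydrogelMaterial(mu=1.0, chi=1e4, k_res=1e-4)
        l3 = plane_stress_lambda3(1.2, 1.0, 1.0, mat)
        assert abs(l3 - 1.0 / 1.2) / (1.0 / 1.2) < 0.01

    def test_scan_oracle(self, hydrogel, rng):
        for _ in range(10):
            l1, l2 = rng.uniform(0.7, 1.5, 2)
            p = float(rng.uniform(0, 1))
            l3 = plane_stress_lambda3(l1, l2, p, hydrogel)
            grid = np.linspace(max(0.05, l3 - 0.5), l3 + 0.5, 2000)
            lams = np.stack(
                [np.full_like(grid, l1), np.full_like(grid, l2), grid], axis=1
            )
            wp, wm = split_energy_principal(
                lams, l1 * l2 * grid, hydrogel.mu, hydrogel.chi
            )
            W = degradation(p, hydrogel.k_res) * wp + wm
            l3_scan = grid[np.argmin(W)]
            assert abs(l3 - l3_scan) <= abs(grid[1] - grid[0]) + 1e-6

    def test_envelope_second_order(self, hydrogel):
        # perturbing lambda3 around the optimum changes W at second order
        l1, l2, p = 1.25, 1.1, 0.8
        l3 = plane_stress_lambda3(l1, l2, p, hydrogel)

        def W(l3v):
            lams = np.array([l1, l2, l3v])
            wp, wm = split_energy_principal(
                lams, l1 * l2 * l3v, hydrogel.mu, hydrogel.chi
            )
            return float(degradation(p, hydrogel.k_res) * wp + wm)

        w0 = W(l3)
        d1 = abs(W(l3 + 1e-3) - w0)
        d2 = abs(W(l3 + 1e-4) - w0)
        assert d2 < 0.02 * d1  # quadratic scaling: factor ~1e-2


class TestElementAvgEnergy:
    def test_ng_invariance_membrane_mode(self, small_mesh, hydrogel):
        pos = small_mesh.vertices * 1.1
        p = np.ones(small_mesh.n_vertices)
        vals = []
        for ng in (1, 5):
            model = MembraneModel(
                small_mesh, {"default": hydrogel}, ThicknessRule(ng)
            )
            vals.append(element_avg_energy(model, 3, pos, p))
        assert vals[0] == pytest.approx(vals[1], abs=1e-14)
        assert vals[0][0] > 0

    def test_undeformed_zero(self, model, small_mesh):
        wp, wm = element_avg_energy(
            model, 0, small_mesh.vertices, np.ones(small_mesh.n_vertices)
        )
        assert wp == pytest.approx(0.0, abs=1e-14)
        assert wm == pytest.approx(0.0, abs=1e-14)


class TestInternalForces:
    def test_undeformed_zero(self, small_mesh, hydrogel):
        f, e = internal_forces(
            small_mesh,
            small_mesh.vertices,
            np.ones(small_mesh.n_vertices),
            {"default": hydrogel},
        )
        assert abs(e) < 1e-14
        assert np.abs(f).max() < 1e-12

    def test_fd_consistency(self, small_mesh, model, rng):
        pos, p = _deformed_state(small_mesh, rng)
        res = model.evaluate(pos, p)
        h = 1e-6
        for _ in range(15):
            i = int(rng.integers(small_mesh.n_vertices))
            c = int(rng.integers(3))
            pp, pm = pos.copy(), pos.copy()
            pp[i, c] += h
            pm[i, c] -= h
            fd = (
                model.evaluate(pp, p, compute_forces=False).energy
                - model.evaluate(pm, p, compute_forces=False).energy
            ) / (2 * h)
            assert abs(fd - res.forces[i, c]) <= 1e-4 * max(abs(fd), 1e-8)

    def test_translation_and_rotation_force_free(self, small_mesh, model, rng):
        pos = small_mesh.vertices + np.array([0.3, -0.2, 0.5])
        res = model.evaluate(pos, np.ones(small_mesh.n_vertices))
        assert np.abs(res.forces).max() < 1e-9
        R = random_rotation(rng)
        res2 = model.evaluate(
            small_mesh.vertices @ R.T, np.ones(small_mesh.n_vertices)
        )
        assert np.abs(res2.forces).max() < 1e-9

    def test_net_force_zero(self, small_mesh, model):
        pos = small_mesh.vertices * np.array([1.2, 0.9, 1.0])
        res = model.evaluate(pos, np.ones(small_mesh.n_vertices))
        assert np.abs(res.forces.sum(axis=0)).max() < 1e-10

    def test_energy_additivity(self, small_mesh, model, rng):
        pos, p = _deformed_state(small_mesh, rng)
        res = model.evaluate(pos, p)
        scale = model.frames.area * small_mesh.thickness
        g = degradation(res.p_elem, 1e-4)
        manual = float(np.sum(scale * g * res.elem_w_plus))
        # recompute W- per element
        lams = np.concatenate([res.svals, res.lambda3[:, None]], axis=1)
        _, wm = split_energy_principal(lams, lams.prod(axis=1), 1.0, 2.17)
        manual += float(np.sum(scale * wm))
        assert res.energy == pytest.approx(manual, rel=1e-12)


class TestMixedRegions:
    def test_ogden_region_not_damageable(self, hydrogel, ogden):
        mesh = gen_notched_plate(1.0, 1.0, 0.3, 0.15)
        region = mesh.element_region.copy()
        region[: mesh.n_triangles // 2] = "tissue"
        mesh.element_region = region
        model = MembraneModel(
            mesh, {"default": hydrogel, "tissue": ogden}
        )
        assert model.phase_mask.sum() == mesh.n_triangles - mesh.n_triangles // 2
        pos = mesh.vertices * 1.1
        res = model.evaluate(pos, np.ones(mesh.n_vertices))
        # Ogden elements contribute no tensile driving energy
        assert np.all(res.elem_w_plus[: mesh.n_triangles // 2] == 0.0)
        assert res.energy > 0

    def test_missing_region_material(self, hydrogel):
        mesh = gen_notched_plate(1.0, 1.0, 0.3, 0.15)
        with pytest.raises(ValueError, match="no material"):
            MembraneModel(mesh, {"other": hydrogel})


class TestBending:
    def test_fd_consistency(self, small_mesh, hydrogel, rng):
        model = MembraneModel(
            small_mesh,
            {"default": hydrogel},
            bending=BendingConfig(True, 1e-3),
        )
        pos, p = _deformed_state(small_mesh, rng)
        pos[:, 2] += 0.1 * np.sin(3 * pos[:, 0]) * np.cos(2 * pos[:, 1])
        res = model.evaluate(pos, p)
        assert res.e_bend > 0
        h = 1e-6
        for _ in range(10):
            i = int(rng.integers(small_mesh.n_vertices))
            c = int(rng.integers(3))
            pp, pm = pos.copy(), pos.copy()
            pp[i, c] += h
            pm[i, c] -= h
            fd = (
                model.evaluate(pp, p, compute_forces=False).energy
                - model.evaluate(pm, p, compute_forces=False).energy
            ) / (2 * h)
            assert abs(fd - res.forces[i, c]) <= 1e-4 * max(abs(fd), 1e-6)

    def test_flat_reference_no_bending_energy(self, small_mesh, hydrogel):
        model = MembraneModel(
            small_mesh,
            {"default": hydrogel},
            bending=BendingConfig(True, 1e-3),
        )
        res = model.evaluate(
            small_mesh.vertices * 1.2, np.ones(small_mesh.n_vertices)
        )
        # in-plane stretch of a flat mesh bends nothing
        assert res.e_bend == pytest.approx(0.0, abs=1e-18)
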