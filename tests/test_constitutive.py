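import numpy as np
import pytest

from gelshell import (
    HydrogelMaterial,
    OgdenMaterial,
    cauchy_effective,
    degraded_energy,
    ogden_energy,
    ogden_pk1,
    pk1_hydrogel,
    split_energy,
    stretch_state,
)
from gelshell.errors import InvertedElementError

from conftest import random_F, random_rotation


def _fd_gradient(fun, F, h=1e-6):
    G = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Fp, Fm = F.copy(), F.copy()
            Fp[i, j] += h
            Fm[i, j] -= h
            G[i, j] = (fun(Fp) - fun(Fm)) / (2 * h)
    return G


class TestStretchState:
    def test_identity(self):
        s = stretch_state(np.eye(3))
        np.testing.assert_allclose(s.lambdas, 1.0)
        assert s.J == pytest.approx(1.0)
        assert s.I1 == pytest.approx(3.0)

    def test_diagonal(self):
        s = stretch_state(np.diag([1.2, 1.0, 0.8]))
        np.testing.assert_allclose(s.lambdas, [1.2, 1.0, 0.8])
        assert s.J == pytest.approx(0.96)

    def test_rotation_invariance(self, rng):
        F = np.diag([1.2, 1.0, 0.8])
        R = random_rotation(rng)
        s = stretch_state(R @ F)
        np.testing.assert_allclose(s.lambdas, [1.2, 1.0, 0.8], atol=1e-12)
        assert s.J == pytest.approx(0.96, abs=1e-12)
        assert abs(np.prod(s.lambdas) - s.J) <= 1e-10 * abs(s.J)

    def test_inverted_rejected(self):
        with pytest.raises(InvertedElementError):
            stretch_state(np.diag([1.0, 1.0, -1.0]))


class TestSplitEnergy:
    def test_reference_state_zero(self, hydrogel):
        wp, wm = split_energy(stretch_state(np.eye(3)), hydrogel)
        assert wp == 0.0 and wm == 0.0

    def test_pure_tension(self, hydrogel):
        # lambda = (1.2, 1, 1), J = 1.2; independent scalar evaluation:
        # W+ = 0.5(1.2^2 - 1 - 2 ln 1.2) + 0.5*2.17*(0.2)^2 = 0.0810783
        wp, wm = split_energy(stretch_state(np.diag([1.2, 1, 1])), hydrogel)
        assert wp == pytest.approx(0.0810783, abs=1e-6)
        assert wm == 0.0

    def test_pure_compression(self, hydrogel):
        wp, wm = split_energy(stretch_state(np.diag([0.8, 1, 1])), hydrogel)
        assert wp == 0.0
        assert wm == pytest.approx(0.0865436, abs=1e-6)

    def test_mixed_state(self, hydrogel):
        # lambda = (1.2, 0.8, 1), J = 0.96: tension from lambda_1 only
        wp, wm = split_energy(
            stretch_state(np.diag([1.2, 0.8, 1])), hydrogel
        )
        assert wp == pytest.approx(0.0376783, abs=1e-6)
        wm_expect = 0.5 * (0.8**2 - 1 - 2 * np.log(0.8)) + 0.5 * 2.17 * 0.04**2
        assert wm == pytest.approx(wm_expect, abs=1e-10)

    def test_nonnegative_and_continuous_across_kinks(self, hydrogel, rng):
        for t in np.linspace(-0.2, 0.2, 81):
            F = np.diag([1.0 + t, 1.0, 1.0 / (1.0 + 0.5 * t)])
            wp, wm = split_energy(stretch_state(F), hydrogel)
            assert wp >= 0 and wm >= 0
        # continuity of W+ + W- across lambda = 1 (compare to unsplit G)
        from gelshell.constitutive import neo_hookean_G

        for _ in range(20):
            F = random_F(rng)
            s = stretch_state(F)
            wp, wm = split_energy(s, hydrogel)
            # sum differs from G only through the J-split cross terms;
            # check continuity by a tiny perturbation across the kink
            eps = 1e-8
            Fp = F * (1 + eps)
            sp = stretch_state(Fp)
            wp2, wm2 = split_energy(sp, hydrogel)
            assert abs((wp2 + wm2) - (wp + wm)) < 1e-5


class TestDegradedEnergy:
    def test_full_integrity(self, hydrogel):
        assert degraded_energy(2.0, 1.0, 1.0, hydrogel) == pytest.approx(3.0)

    def test_fully_damaged_residual(self, hydrogel):
        assert degraded_energy(2.0, 1.0, 0.0, hydrogel) == pytest.approx(
            hydrogel.k_res * 2.0 + 1.0
        )

    def test_half_damage_arithmetic(self):
        mat = HydrogelMaterial(1.0, 2.17, 1e-4)
        # (0.9999*0.25 + 1e-4)*2 + 1 = 1.50015
        assert degraded_energy(2.0, 1.0, 0.5, mat) == pytest.approx(
            1.50015, abs=1e-12
        )

    def test_p_out_of_range(self, hydrogel):
        with pytest.raises(ValueError):
            degraded_energy(1.0, 0.0, 1.5, hydrogel)

    def test_monotone_in_p(self, hydrogel, rng):
        F = np.diag([1.3, 1.1, 1.0])
        s = stretch_state(F)
        wp, wm = split_energy(s, hydrogel)
        assert wp > 0
        ps = np.linspace(0, 1, 11)
        vals = [degraded_energy(wp, wm, p, hydrogel) for p in ps]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestPk1Hydrogel:
    def test_reference_stress_free(self, hydrogel):
        np.testing.assert_allclose(
            pk1_hydrogel(np.eye(3), 0.3, hydrogel), 0.0, atol=1e-14
        )

    def test_all_tension_closed_form(self, hydrogel, rng):
        # all stretches > 1 and J > 1, p = 1: the degraded stress equals the
        # plain neo-Hookean PK1 = mu (F - F^-T) + chi J (J-1) F^-T
        for _ in range(5):
            R = random_rotation(rng)
            F = R @ np.diag(rng.uniform(1.05, 1.4, 3))
            P = pk1_hydrogel(F, 1.0, hydrogel)
            FinvT = np.linalg.inv(F).T
            J = np.linalg.det(F)
            P_exact = hydrogel.mu * (F - FinvT) + hydrogel.chi * J * (J - 1) * FinvT
            np.testing.assert_allclose(P, P_exact, atol=1e-10)

    def test_fd_consistency(self, hydrogel, rng):
        for _ in range(20):
            F = random_F(rng)
            p = float(rng.uniform(0, 1))

            def energy(Fx):
                s = stretch_state(Fx)
                wp, wm = split_energy(s, hydrogel)
                return float(degraded_energy(wp, wm, p, hydrogel))

            P = pk1_hydrogel(F, p, hydrogel)
            G = _fd_gradient(energy, F)
            scale = max(np.abs(P).max(), 1e-10)
            assert np.abs(P - G).max() <= 1e-5 * scale

    def test_frame_indifference(self, hydrogel, rng):
        F = random_F(rng)
        R = random_rotation(rng)
        s1 = stretch_state(F)
        s2 = stretch_state(R @ F)
        w1 = split_energy(s1, hydrogel)
        w2 = split_energy(s2, hydrogel)
        assert w1[0] == pytest.approx(w2[0], abs=1e-10)
        assert w1[1] == pytest.approx(w2[1], abs=1e-10)
        P1 = pk1_hydrogel(F, 0.7, hydrogel)
        P2 = pk1_hydrogel(R @ F, 0.7, hydrogel)
        assert np.linalg.norm(P1) == pytest.approx(
            np.linalg.norm(P2), abs=1e-10
        )

    def test_repeated_stretches(self, hydrogel):
        # equal principal stretches must not blow up the principal-frame
        # assembly
        F = 1.2 * np.eye(3)
        P = pk1_hydrogel(F, 1.0, hydrogel)
        FinvT = np.linalg.inv(F).T
        J = np.linalg.det(F)
        P_exact = hydrogel.mu * (F - FinvT) + hydrogel.chi * J * (J - 1) * FinvT
        np.testing.assert_allclose(P, P_exact, atol=1e-10)


class TestOgden:
    def test_reference_zero(self, ogden):
        assert ogden_energy(np.eye(3), ogden) == pytest.approx(0.0, abs=1e-14)
        np.testing.assert_allclose(ogden_pk1(np.eye(3), ogden), 0.0, atol=1e-12)

    def test_isochoric_value(self, ogden):
        # F = diag(1.1, 1.1^-1/2, 1.1^-1/2), J = 1:
        # W = 0.0005 (1.1^-20 + 2*1.1^10 - 3) = 1.1681e-3
        F = np.diag([1.1, 1.1**-0.5, 1.1**-0.5])
        assert ogden_energy(F, ogden) == pytest.approx(1.1681e-3, abs=1e-7)

    def test_alpha2_reduction(self, rng):
        # alpha = 2: W = mu/2 (Ibar1 - 3) + K/2 (J-1)^2
        mat = OgdenMaterial(mu_og=0.37, k_og=1.4, alpha=2.0)
        for _ in range(10):
            F = random_F(rng)
            J = np.linalg.det(F)
            lam = np.linalg.svd(F, compute_uv=False)
            Ibar1 = J ** (-2.0 / 3.0) * np.sum(lam**2)
            expect = 0.5 * mat.mu_og * (Ibar1 - 3) + 0.5 * mat.k_og * (J - 1) ** 2
            assert ogden_energy(F, mat) == pytest.approx(expect, abs=1e-10)

    def test_fd_consistency(self, ogden, rng):
        for _ in range(20):
            F = random_F(rng)
            P = ogden_pk1(F, ogden)
            G = _fd_gradient(lambda Fx: ogden_energy(Fx, ogden), F)
            scale = max(np.abs(P).max(), 1e-10)
            assert np.abs(P - G).max() <= 1e-5 * scale

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            OgdenMaterial(-1.0, 1.0, 2.0)
        with pytest.raises(ValueError):
            OgdenMaterial(1.0, 1.0, 0.0)


class TestCauchyEffective:
    def test_zero_stress(self):
        assert cauchy_effective(np.zeros((3, 3)), np.eye(3)) == 0.0

    def test_hydrostatic(self):
        # sigma = -p I has zero deviator
        P = -2.5 * np.eye(3)
        assert cauchy_effective(P, np.eye(3)) == pytest.approx(0.0, abs=1e-14)

    def test_uniaxial(self):
        P = np.diag([3.2, 0.0, 0.0])
        assert cauchy_effective(P, np.eye(3)) == pytest.approx(3.2)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    _entry = st.floats(-0.45, 0.45, allow_nan=False)

    @given(st.lists(_entry, min_size=9, max_size=9), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_split_invariants_property(entries, p):
        F = np.eye(3) + np.array(entries).reshape(3, 3)
        if np.linalg.det(F) <= 0.05:
            return
        mat = HydrogelMaterial(1.0, 2.17, 1e-4)
        s = stretch_state(F)
        wp, wm = split_energy(s, mat)
        assert wp >= 0.0 and wm >= 0.0
        w = degraded_energy(wp, wm, p, mat)
        assert wm <= w <= wp + wm + 1e-12
        # degradation never increases the energy
        assert w <= degraded_energy(wp, wm, 1.0, mat) + 1e-12

except ImportError:  # pragma: no cover - hypothesis is present in CI env
    pass


def test_material_validation():
    with pytest.raises(ValueError):
        HydrogelMaterial(mu=-1.0, chi=1.0)
    with pytest.raises(ValueError):
        HydrogelMaterial(mu=1.0, chi=1.0, k_res=0.0)
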