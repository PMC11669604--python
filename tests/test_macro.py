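import numpy as np
import pytest

from gliosim.fields import Grid3D, TissueState, ball_indicator, extract_boundary
from gliosim import numerics
from gliosim.macro import (
    MacroParams, adhesion_vector, adhesion_offsets, proliferation, death,
    ecm_decay_step, macro_rhs, advance_stage, build_diffusion_tensor,
)
from gliosim.nutrients import NutrientParams, psi_p, psi_d

MP = MacroParams()


class TestTensorDiffusion:
    def test_constant_field_constant_tensor_vanishes(self):
        c = np.full((10, 10, 10), 0.7)
        out = numerics.tensor_diffusion(c, np.eye(3), (1, 1, 1))
        assert np.abs(out).max() < 1e-13

    def test_isotropic_reduces_to_seven_point_laplacian(self, rng):
        c = rng.random((10, 10, 10))
        d = 1.7
        out = numerics.tensor_diffusion(c, d * np.eye(3), (1, 1, 1))
        cp = np.pad(c, 1, mode="symmetric")
        lap = (cp[2:, 1:-1, 1:-1] + cp[:-2, 1:-1, 1:-1]
               + cp[1:-1, 2:, 1:-1] + cp[1:-1, :-2, 1:-1]
               + cp[1:-1, 1:-1, 2:] + cp[1:-1, 1:-1, :-2] - 6 * c)
        assert np.abs(out - d * lap)[1:-1, 1:-1, 1:-1].max() < 1e-13

    def test_quadratic_exactness(self):
        g = Grid3D((12, 12, 12))
        X, _, _ = g.coords()
        c = np.broadcast_to(X**2, g.shape).copy()
        out = numerics.tensor_diffusion(c, np.diag([2.0, 3.0, 4.0]), g.spacing)
        interior = out[2:-2, 2:-2, 2:-2]
        assert np.allclose(interior, 2 * 2.0, atol=1e-11)

    def test_asymmetric_tensor_rejected(self):
        t = np.eye(3)
        t[0, 1] = 0.3  # not mirrored
        with pytest.raises(ValueError):
            numerics.tensor_diffusion(np.zeros((6, 6, 6)), t, (1, 1, 1))


class TestWENO:
    def test_fifth_order_on_smooth_data(self):
        errs = []
        for N in (32, 64, 128):
            h = 2 * np.pi / N
            x = (np.arange(N) + 0.5) * h
            c = np.cos(x)[:, None, None] * np.ones((1, 6, 6))
            A = [np.ones_like(c), np.zeros_like(c), np.zeros_like(c)]
            div = numerics.advection_divergence(c, A, (h, 1.0, 1.0))
            exact = -np.sin(x)[:, None, None]
            errs.append(np.abs(div - exact)[4:-4].max())
        orders = [np.log2(errs[i] / errs[i + 1]) for i in range(2)]
        assert min(orders) >= 4.0

    def test_transport_conserves_mass(self, rng):
        c = rng.random((12, 12, 12))
        A = [rng.standard_normal((12, 12, 12)) for _ in range(3)]
        div = numerics.advection_divergence(c, A, (1, 1, 1))
        assert abs(div.sum()) < 1e-10
        diff = numerics.tensor_diffusion(c, np.eye(3), (1, 1, 1))
        assert abs(diff.sum()) < 1e-10


class TestAdhesion:
    def test_zero_densities_zero_vector(self, grid16):
        st = TissueState.zeros(grid16)
        A = adhesion_vector(st, np.zeros(grid16.shape + (3,)), MP)
        assert np.abs(A).max() == 0.0

    def test_spherical_symmetry_cancels(self):
        g = Grid3D((17, 17, 17))
        st = TissueState.zeros(g)
        X, Y, Z = g.coords()
        r2 = (X - 8.5) ** 2 + (Y - 8.5) ** 2 + (Z - 8.5) ** 2
        st.c = 0.3 * np.exp(-r2 / 8.0)
        A = adhesion_vector(st, np.zeros(g.shape + (3,)), MP)
        centre = A[8, 8, 8]
        assert np.linalg.norm(centre) < 1e-12

    def test_single_occupied_voxel_matches_brute_force(self, grid16):
        st = TissueState.zeros(grid16)
        st.c[9, 8, 8] = 0.4  # offset +x1 inside the sensing ball
        params = MacroParams(S_cc=1.0, S_cl=0.0, S_cF=0.0)
        A = adhesion_vector(st, np.zeros(grid16.shape + (3,)), params)
        # Direct quadrature at the probe point x = (8, 8, 8).
        offs, yhat, w = adhesion_offsets(grid16, params.R_s)
        expected = np.zeros(3)
        for off, yh, wq in zip(offs, yhat, w):
            tgt = np.array([8, 8, 8]) + off
            cval = st.c[tuple(tgt)]
            expected += wq * yh * cval * (1.0 - cval)
        assert np.allclose(A[8, 8, 8], expected, atol=1e-14)
        assert expected[0] > 0 and abs(expected[1]) < 1e-14

    def test_sensing_radius_below_voxel_rejected(self, grid16):
        st = TissueState.zeros(grid16)
        with pytest.raises(ValueError):
            adhesion_vector(st, np.zeros(grid16.shape + (3,)),
                            MacroParams(R_s=0.5))


class TestKinetics:
    def test_proliferation_values(self, grid16):
        st = TissueState.zeros(grid16)
        st.c += 0.2
        st.l += 0.3
        # rho = 0.5, psi_p = 1: P = mu * 0.2 * 0.5
        params = MacroParams(mu=0.5)
        P = proliferation(st, np.ones(grid16.shape), params)
        assert np.allclose(P, 0.5 * 0.2 * 0.5)

    def test_overcrowding_truncation(self, grid16):
        st = TissueState.zeros(grid16)
        st.c += 0.6
        st.l += 0.7  # rho = 1.3 > 1
        P = proliferation(st, np.ones(grid16.shape), MP)
        assert np.abs(P).max() == 0.0

    def test_death_arithmetic_and_zero_c(self, grid16):
        st = TissueState.zeros(grid16)
        st.c += 0.3
        Q = death(st, np.ones(grid16.shape), MacroParams(death=0.1))
        assert np.allclose(Q, 0.03)
        st.c *= 0.0
        assert np.abs(death(st, np.ones(grid16.shape), MP)).max() == 0.0


class TestEcmDecay:
    def test_no_cancer_no_decay(self, grid16):
        st = TissueState.zeros(grid16)
        st.F += 0.4
        st.l += 0.3
        F, l = ecm_decay_step(st, MP, dt=1.0)
        assert np.allclose(F, 0.4) and np.allclose(l, 0.3)

    def test_matches_closed_form_exponential(self, grid16):
        st = TissueState.zeros(grid16)
        st.c += 0.5
        st.F += 1.0
        st.l += 1.0
        t = 2.0
        F, l = ecm_decay_step(st, MP, dt=t)
        assert np.allclose(F, np.exp(-0.5 * MP.beta_F * t), atol=1e-12)
        assert np.allclose(l, np.exp(-0.5 * MP.beta_l * t), atol=1e-12)

    def test_therapy_accelerates_decay(self, grid16):
        st = TissueState.zeros(grid16)
        st.c += 0.5
        st.F += 1.0
        st.l += 1.0
        F_off, _ = ecm_decay_step(st, MP, 1.0)
        F_on, _ = ecm_decay_step(st, MP, 1.0, chemo_active=True, radio_active=True)
        assert np.all(F_on < F_off)


class TestRHSAndStepping:
    def test_zero_state_zero_rhs(self, grid16):
        st = TissueState.zeros(grid16)
        rhs = macro_rhs(st, np.broadcast_to(np.eye(3), grid16.shape + (3, 3)),
                        np.zeros(grid16.shape + (3,)), MP,
                        np.ones(grid16.shape), np.ones(grid16.shape))
        assert np.abs(rhs).max() == 0.0

    def test_uniform_state_reduces_to_kinetics(self, grid16):
        # No adhesion, no treatment, uniform c: transport of a uniform
        # field vanishes and the RHS is exactly P - Q.
        st = TissueState.zeros(grid16)
        st.c += 0.2
        st.l += 0.3
        params = MacroParams(S_cc=0.0, S_cl=0.0, S_cF=0.0)
        pp = np.full(grid16.shape, 0.8)
        pd = np.full(grid16.shape, 0.6)
        rhs = macro_rhs(st, np.broadcast_to(np.eye(3), grid16.shape + (3, 3)),
                        np.zeros(grid16.shape + (3,)), params, pp, pd)
        expected = params.mu * 0.8 * 0.2 * 0.5 - params.death * 0.6 * 0.2
        assert np.allclose(rhs[2:-2, 2:-2, 2:-2], expected, atol=1e-12)

    def test_logistic_ode_regime_second_order(self, grid16):
        # Pure logistic growth (no transport): dc/dt = mu c (1 - c).
        params = MacroParams(mu=1.0, death=0.0, S_cc=0, S_cl=0, S_cF=0, D_c=0.0)
        DT = np.zeros(grid16.shape + (3, 3))
        ones = np.ones(grid16.shape)

        def one_step(c0, dt):
            st = TissueState.zeros(grid16)
            st.c += c0
            return advance_stage(st, DT, np.zeros(grid16.shape + (3,)), params,
                                 ones, np.zeros(grid16.shape), dt)[0, 0, 0]

        c0 = 0.2
        exact = lambda t: c0 * np.exp(t) / (1 - c0 + c0 * np.exp(t))
        e1 = abs(one_step(c0, 0.2) - exact(0.2))
        e2 = abs(one_step(c0, 0.1) - exact(0.1))
        # one-step (local) error of a 2nd-order scheme scales ~ dt^3
        assert e1 / e2 > 6.0
        assert e1 < 1e-3

    def test_rhs_zero_keeps_state(self, grid16):
        st = TissueState.zeros(grid16)
        st.c += 0.3
        params = MacroParams(mu=0.0, death=0.0, S_cc=0, S_cl=0, S_cF=0, D_c=0.0)
        c1 = advance_stage(st, np.zeros(grid16.shape + (3, 3)),
                           np.zeros(grid16.shape + (3,)), params,
                           np.ones(grid16.shape), np.ones(grid16.shape), 0.5)
        assert np.allclose(c1, 0.3)

    def test_transport_only_conserves_mass(self, grid16, rng):
        ind = ball_indicator(grid16, (8, 8, 8), 6.0)
        st = TissueState.zeros(grid16)
        st.c = np.where(ind, 0.2 + 0.1 * rng.random(grid16.shape), 0.0)
        st.l = np.full(grid16.shape, 0.2)
        params = MacroParams(mu=0.0, death=0.0)
        DT = np.broadcast_to(0.2 * np.eye(3), grid16.shape + (3, 3))
        face_open = numerics.interface_face_open(ind)
        theta = np.zeros(grid16.shape + (3,))
        zeros = np.zeros(grid16.shape)
        m0 = st.c.sum()
        for _ in range(100):
            st.c = advance_stage(st, DT, theta, params, zeros, zeros, 0.2,
                                 face_open=face_open)
        assert abs(st.c.sum() - m0) / m0 < 1e-3

    def test_density_stays_in_unit_range(self, grid16):
        st = TissueState.zeros(grid16)
        st.c += 0.9
        params = MacroParams(S_cc=0, S_cl=0, S_cF=0, D_c=0.0)
        ones = np.ones(grid16.shape)
        for _ in range(50):
            st.c = advance_stage(st, np.zeros(grid16.shape + (3, 3)),
                                 np.zeros(grid16.shape + (3,)), params,
                                 ones, np.zeros(grid16.shape), 0.2)
        assert st.c.max() <= 1.0 + 1e-6
        assert st.c.min() >= 0.0


class TestDiffusionTensorMixture:
    def test_grey_matter_is_isotropic(self, rng):
        tensors = np.broadcast_to(np.diag([3.0, 0.0, 0.0]), (4, 4, 4, 3, 3))
        wm = np.zeros((4, 4, 4))
        gm = np.ones((4, 4, 4))
        DT = build_diffusion_tensor(tensors, wm, gm, D_c=0.5)
        assert np.allclose(DT, 0.5 * np.eye(3))

    def test_white_matter_keeps_anisotropy_scaled(self):
        t = np.diag([2.5, 0.25, 0.25])  # trace 3 already
        tensors = np.broadcast_to(t, (4, 4, 4, 3, 3))
        wm = np.ones((4, 4, 4))
        gm = np.zeros((4, 4, 4))
        DT = build_diffusion_tensor(tensors, wm, gm, D_c=0.2)
        assert np.allclose(DT[0, 0, 0], 0.2 * t)
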