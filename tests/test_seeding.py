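import numpy as np
import pytest
from scipy.integrate import quad

from gliosim.fields import Grid3D, GeometryError, ball_indicator, extract_boundary
from gliosim.seeding import (
    SeedingSpec, mollifier_psi1, mollifier_profile, gaussian_profile,
    controller_length, normal_ray_distance, seed_oedema_field, eq20_h,
    init_noncancer_fields,
)


class TestSpec:
    def test_controller_must_exceed_one(self):
        with pytest.raises(ValueError):
            SeedingSpec(xi=1.0)

    def test_case_restricted(self):
        with pytest.raises(ValueError):
            SeedingSpec(case=3)


class TestMollifier:
    def test_unit_integral(self):
        val = quad(mollifier_psi1, -1, 1)[0]
        assert val == pytest.approx(1.0, rel=1e-8)

    def test_compact_support(self):
        q, kR = 10.0, 5.0
        R = q / kR
        assert mollifier_profile(R, q, kR) == 0.0
        assert mollifier_profile(R + 0.1, q, kR) == 0.0
        assert mollifier_profile(0.5 * R, q, kR) > 0.0

    def test_half_mass_on_positive_axis(self):
        q, kR = 10.0, 5.0
        R = q / kR
        mass = quad(lambda u: mollifier_profile(u, q, kR), 0, q)[0]
        assert mass == pytest.approx(0.5, rel=1e-6)

    def test_doubling_controller_halves_support(self):
        assert controller_length(10.0, 8.0, 1) == 0.8
        assert controller_length(20.0, 8.0, 1) == 0.4

    def test_negative_coordinate_rejected(self):
        with pytest.raises(ValueError):
            mollifier_profile(-0.1, 10.0, 5.0)


class TestGaussian:
    def test_mode_at_cavity_edge(self):
        u = np.linspace(0, 10, 200)
        prof = gaussian_profile(u, 10.0, 5.0)
        assert prof[0] == prof.max()

    def test_one_sigma_ratio(self):
        q, k = 10.0, 5.0
        sig = q / k
        assert gaussian_profile(sig, q, k) / gaussian_profile(0.0, q, k) == \
            pytest.approx(np.exp(-0.5))

    def test_strictly_positive_at_oedema_boundary(self):
        assert gaussian_profile(10.0, 10.0, 10.0) > 0.0


class TestControllerMap:
    def test_shared_formula(self):
        assert controller_length(2.0, 10.0, 1) == 5.0
        assert controller_length(2.0, 10.0, 2) == 5.0

    def test_limit_concentrates_at_gamma(self):
        assert controller_length(1e9, 10.0, 1) == pytest.approx(0.0, abs=1e-7)


class TestNormalRay:
    def test_concentric_spheres_radial_distance(self):
        g = Grid3D((32, 32, 32))
        centre = np.array([16.0, 16.0, 16.0])
        oedema = ball_indicator(g, centre, 12.0)
        cavity = extract_boundary(ball_indicator(g, centre, 5.0), g)
        for p, n in zip(cavity.boundary_coords()[::17], cavity.normals[::17]):
            q, hit = normal_ray_distance(p, n, oedema, g)
            assert hit
            r0 = np.linalg.norm(p - centre)
            assert q == pytest.approx(12.0 - r0, abs=0.75)

    def test_point_on_outer_boundary_returns_zero(self):
        g = Grid3D((32, 32, 32))
        oedema = ball_indicator(g, (16, 16, 16), 8.0)
        p = np.array([16.0 + 8.4, 16.0, 16.0])  # just outside the ball
        q, hit = normal_ray_distance(p, np.array([1.0, 0, 0]), oedema, g)
        assert q <= 0.5

    def test_ellipsoidal_oedema_matches_analytic_intersection(self):
        g = Grid3D((40, 40, 40))
        X, Y, Z = g.coords()
        a, b, c = 15.0, 10.0, 8.0
        centre = 20.0
        oedema = (((X - centre) / a) ** 2 + ((Y - centre) / b) ** 2
                  + ((Z - centre) / c) ** 2) <= 1.0
        # Ray from the centre along +x: exits at distance a.
        q, hit = normal_ray_distance(np.array([centre, centre, centre]),
                                     np.array([1.0, 0, 0]), oedema, g)
        assert hit and q == pytest.approx(a, abs=0.5)
        # Ray along +y: exits at distance b.
        q, _ = normal_ray_distance(np.array([centre, centre, centre]),
                                   np.array([0.0, 1.0, 0]), oedema, g)
        assert q == pytest.approx(b, abs=0.5)

    def test_ray_leaving_grid_flags_miss(self):
        g = Grid3D((16, 16, 16))
        oedema = np.ones(g.shape, bool)
        q, hit = normal_ray_distance(np.array([8.0, 8.0, 8.0]),
                                     np.array([1.0, 0, 0]), oedema, g)
        assert not hit


class TestSeedField:
    def _geometry(self):
        g = Grid3D((32, 32, 32))
        centre = (16, 16, 16)
        cavity = ball_indicator(g, centre, 4.0)
        oedema = ball_indicator(g, centre, 12.0)
        return g, cavity, oedema

    def test_peak_density_is_c_max(self):
        g, cavity, oedema = self._geometry()
        for case in (1, 2):
            c0 = seed_oedema_field(SeedingSpec(case=case, xi=5.0),
                                   oedema, cavity, g)
            assert c0.max() == pytest.approx(0.1)

    def test_zero_outside_oedema(self):
        g, cavity, oedema = self._geometry()
        c0 = seed_oedema_field(SeedingSpec(case=2, xi=5.0), oedema, cavity, g)
        assert np.abs(c0[~oedema]).max() == 0.0

    def test_zero_when_multipliers_vanish_and_masks_cover(self):
        g, cavity, oedema = self._geometry()
        spec = SeedingSpec(xi=5.0, alpha_it=0.0, alpha_sc=0.0)
        c0 = seed_oedema_field(spec, cavity, cavity, g,
                               initial_tumour_mask=cavity)
        assert np.abs(c0).max() == 0.0

    def test_larger_controller_concentrates_mass_at_cavity(self):
        g, cavity, oedema = self._geometry()
        from scipy import ndimage

        ups = ndimage.distance_transform_edt(~cavity)
        shell = oedema & ~cavity
        means = []
        # controllers kept small enough that the support spans several voxels
        for xi in (1.5, 2.5, 4.0):
            c0 = seed_oedema_field(SeedingSpec(case=1, xi=xi), oedema, cavity, g)
            means.append((c0[shell] * ups[shell]).sum() / c0[shell].sum())
        assert means[0] > means[1] > means[2]

    def test_mass_fraction_near_gamma_increases_with_controller(self):
        g, cavity, oedema = self._geometry()
        from scipy import ndimage

        ups = ndimage.distance_transform_edt(~cavity)
        near = oedema & ~cavity & (ups <= 0.25 * 8.0)
        fracs = []
        for xi in (1.5, 4.0):
            c0 = seed_oedema_field(SeedingSpec(case=1, xi=xi), oedema, cavity, g)
            shell_tot = c0[oedema & ~cavity].sum()
            fracs.append(c0[near & ~cavity].sum() / shell_tot)
        assert fracs[1] > fracs[0]

    def test_empty_cavity_rejected(self):
        g, cavity, oedema = self._geometry()
        with pytest.raises(GeometryError):
            seed_oedema_field(SeedingSpec(), oedema,
                              np.zeros(g.shape, bool), g)

    def test_deterministic(self):
        g, cavity, oedema = self._geometry()
        a = seed_oedema_field(SeedingSpec(case=2, xi=7.0), oedema, cavity, g)
        b = seed_oedema_field(SeedingSpec(case=2, xi=7.0), oedema, cavity, g)
        assert np.array_equal(a, b)


class TestNonCancerInit:
    def _centre_grid(self):
        # 15 cells of width 0.2 spanning [-1.5, 1.5]: cell 7 centred at 0.
        return Grid3D((15, 15, 15), spacing=(0.2, 0.2, 0.2),
                      origin=(-1.5, -1.5, -1.5))

    def test_centre_value_half(self):
        g = self._centre_grid()
        l0, sigma = init_noncancer_fields(np.zeros(g.shape), g)
        assert l0[7, 7, 7] == pytest.approx(0.5)
        assert eq20_h(0.0, 0.0, 0.0) == pytest.approx(0.5)

    def test_saturated_cancer_leaves_no_room(self):
        g = self._centre_grid()
        c0 = np.ones(g.shape)
        l0, _ = init_noncancer_fields(c0, g)
        assert np.abs(l0).max() == 0.0

    def test_nutrients_start_at_point_four(self):
        g = self._centre_grid()
        _, sigma = init_noncancer_fields(np.zeros(g.shape), g)
        assert np.all(sigma == 0.4)
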