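import numpy as np
import pytest

from gliosim.fields import Grid3D, ball_indicator, extract_boundary
from gliosim.boundary import (
    BoundaryMicroParams, BundleError, build_bundle, mde_source_field,
    solve_mde, relocation_vector, evolve_domain, boundary_micro_stage,
    BoundaryMicroDomain, DomainEvolver,
)

BP = BoundaryMicroParams()


@pytest.fixture(scope="module")
def sphere_domain():
    g = Grid3D((24, 24, 24))
    return g, extract_boundary(ball_indicator(g, (12, 12, 12), 6.0), g)


class TestBundle:
    def test_single_point_single_cube(self, grid16):
        ind = np.zeros(grid16.shape, bool)
        ind[8, 8, 8] = True
        dom = extract_boundary(ind, grid16)
        cubes = build_bundle(dom, BP)
        assert len(cubes) == 1
        assert np.allclose(cubes[0].centre, (8.5, 8.5, 8.5))

    def test_sphere_cover_within_half_eps(self, sphere_domain):
        g, dom = sphere_domain
        cubes = build_bundle(dom, BP)
        centres = np.array([c.centre for c in cubes])
        bcoords = dom.boundary_coords()
        for p in bcoords:
            d = np.max(np.abs(centres - p), axis=1).min()
            assert d <= BP.eps / 2

    def test_empty_boundary_rejected(self, grid16):
        dom = extract_boundary(ball_indicator(grid16, (8, 8, 8), 4.0), grid16)
        dom.boundary_points = np.empty((0, 3), dtype=int)
        with pytest.raises(BundleError):
            build_bundle(dom, BP)

    def test_tiny_cube_rejected(self):
        with pytest.raises(ValueError):
            BoundaryMicroParams(micro_n=1)


class TestSource:
    def test_no_cancer_zero_source(self, sphere_domain):
        g, dom = sphere_domain
        cube = build_bundle(dom, BP)[0]
        src = mde_source_field(cube, np.zeros(g.shape), dom.indicator, g, BP)
        assert np.abs(src).max() == 0.0

    def test_uniform_density_gives_its_mean(self, sphere_domain):
        g, dom = sphere_domain
        c0 = 0.42
        c = np.where(dom.indicator, c0, 0.0)
        cube = build_bundle(dom, BP)[0]
        src = mde_source_field(cube, c, dom.indicator, g, BP)
        X, Y, Z = cube.micro_coords(g.spacing)
        idx = tuple(np.clip(np.floor(A).astype(int), 0, s - 1)
                    for A, s in zip((X, Y, Z), g.shape))
        well_inside = dom.indicator[idx] & (src > 0)
        assert src.max() <= c0 + 1e-12
        assert np.allclose(src[well_inside], c0)

    def test_zero_beyond_mollification_band(self, sphere_domain):
        g, dom = sphere_domain
        c = np.where(dom.indicator, 0.5, 0.0)
        cube = build_bundle(dom, BP)[0]
        src = mde_source_field(cube, c, dom.indicator, g, BP)
        X, Y, Z = cube.micro_coords(g.spacing)
        r = np.sqrt((X - 12) ** 2 + (Y - 12) ** 2 + (Z - 12) ** 2)
        far_outside = r > 6.0 + BP.rho + 1.0
        assert np.abs(src[far_outside]).max() == 0.0


class TestMdeSolve:
    def test_null_source_null_solution(self):
        m = solve_mde(np.zeros((8, 8, 8)), 4.0, 1.0, 0.2)
        assert np.abs(m).max() == 0.0

    def test_uniform_source_integrates_in_time(self):
        h0 = 0.3
        m = solve_mde(np.full((8, 8, 8), h0), 4.0, 1.0, 0.2)
        assert np.allclose(m, h0 * 0.2, atol=1e-12)

    def test_mass_balance_against_time_integrated_source(self, rng):
        src = rng.random((8, 8, 8))
        dt = 0.2
        m = solve_mde(src, 4.0, 3.0, dt)
        assert abs(m.sum() - src.sum() * dt) / (src.sum() * dt) < 1e-10

    def test_point_source_matches_refined_reference(self):
        src = np.zeros((8, 8, 8))
        src[4, 4, 4] = 1.0
        m = solve_mde(src, 4.0, 0.5, 0.2, nsub_min=400)
        ref = solve_mde(src, 4.0, 0.5, 0.2, nsub_min=6400)
        rel = np.linalg.norm(m - ref) / np.linalg.norm(ref)
        assert rel <= 1e-3


class TestRelocation:
    def _cube(self, g):
        return BoundaryMicroDomain(np.array([12.5, 12.5, 12.5]),
                                   np.array([12, 12, 12]), BP.eps, BP.micro_n)

    def test_zero_mde_no_movement(self, sphere_domain):
        g, dom = sphere_domain
        cube = self._cube(g)
        inside = np.ones((BP.micro_n,) * 3, bool)
        inside[:, :, BP.micro_n // 2:] = False
        assert relocation_vector(cube, np.zeros((BP.micro_n,) * 3), inside,
                                 g, BP) is None

    def test_concentrated_outside_mass_sets_direction(self, sphere_domain):
        g, dom = sphere_domain
        cube = self._cube(g)
        n = BP.micro_n
        inside = np.zeros((n, n, n), bool)
        inside[: n // 2] = True  # inside half along -x
        m = np.full((n, n, n), 1e-4)
        # significant mass in a +x face block symmetric about the x axis
        m[n - 1, n // 2 - 1: n // 2 + 1, n // 2 - 1: n // 2 + 1] = 5.0
        res = relocation_vector(cube, m, inside, g, BP)
        assert res is not None
        direction, magnitude = res
        assert direction[0] > 0.99
        assert magnitude > 0

    def test_symmetric_outside_mass_moves_along_normal(self, sphere_domain):
        g, dom = sphere_domain
        cube = self._cube(g)
        n = BP.micro_n
        inside = np.zeros((n, n, n), bool)
        inside[: n // 2] = True
        m = np.zeros((n, n, n))
        m[n - 2, :, :] = 1.0  # a slab symmetric about the +x axis
        res = relocation_vector(cube, m, inside, g, BP)
        direction, _ = res
        assert abs(direction[1]) < 1e-9 and abs(direction[2]) < 1e-9
        assert direction[0] == pytest.approx(1.0)


class TestEvolveDomain:
    def test_no_relocations_no_change(self, sphere_domain):
        g, dom = sphere_domain
        assert evolve_domain(dom, []) is dom

    def test_uniform_outward_growth_of_ball(self, sphere_domain):
        g, dom = sphere_domain
        relocs = [(p, n, 1.2) for p, n in
                  zip(dom.boundary_points, dom.normals)]
        d2 = evolve_domain(dom, relocs)
        centre = np.array([12.0, 12.0, 12.0])
        dists = np.linalg.norm(d2.boundary_coords() - centre, axis=1)
        assert 6.0 < dists.mean() < 8.5  # grew by about one voxel
        assert d2.volume_voxels > dom.volume_voxels

    def test_monotone_growth_contract(self, sphere_domain, rng):
        g, dom = sphere_domain
        sel = rng.integers(0, len(dom.boundary_points), 20)
        relocs = [(dom.boundary_points[i], dom.normals[i], 1.0) for i in sel]
        d2 = evolve_domain(dom, relocs)
        assert not (dom.indicator & ~d2.indicator).any()

    def test_evolver_accumulates_subvoxel_advances(self, sphere_domain):
        g, dom = sphere_domain
        ev = DomainEvolver(g)
        relocs = [(p, n, 0.4) for p, n in
                  zip(dom.boundary_points, dom.normals)]
        d1 = ev.apply(dom, relocs)
        assert d1.volume_voxels == dom.volume_voxels  # banked, not applied
        d2 = ev.apply(d1, relocs)
        d3 = ev.apply(d2, relocs)
        assert d3.volume_voxels > dom.volume_voxels  # 1.2 voxels banked


class TestStage:
    def test_advance_scales_with_boundary_density(self, sphere_domain):
        # More cancer at the rim must produce larger relocation magnitudes.
        g, dom = sphere_domain
        c_hi = np.where(dom.indicator, 0.5, 0.0)
        c_lo = np.where(dom.indicator, 0.1, 0.0)
        rel_hi = boundary_micro_stage(c_hi, dom, BP, dt=0.2)
        rel_lo = boundary_micro_stage(c_lo, dom, BP, dt=0.2)
        assert rel_hi and rel_lo
        mag_hi = np.mean([m for _, _, m in rel_hi])
        mag_lo = np.mean([m for _, _, m in rel_lo])
        assert mag_hi > mag_lo
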