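"""Boundary proteolysis micro-process and moving-boundary domain update.

Matrix-degrading enzymes (MDEs) are secreted by cancer cells near the
tumour interface.  On a bundle of overlapping cubic micro-domains of edge
``eps`` centred on boundary points, the MDE density obeys a diffusion
equation with a source given by the mean cancer density within a
sup-norm ball of radius ``gamma_h`` around each micro node (mollified to
zero a distance ``rho`` outside the tumour), null initial condition and
zero-flux walls.  The degradation pattern that the final MDE
distribution leaves outside the current tumour determines, per boundary
point, a relocation direction (first moment of the significant outside
mass) and magnitude (proportional to that mass), provided the outside
mass exceeds a threshold fraction of the cube total.  Applying the
relocations grows the tumour domain monotonically (invasion only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fields import Grid3D, TumourDomain, extract_boundary


class BundleError(ValueError):
    pass


@dataclass(frozen=True)
class BoundaryMicroParams:
    eps: float = 4.0  # cube edge length [macro voxels]
    micro_n: int = 8  # micro cells per cube edge
    gamma_h: float = 1.5  # source sensing radius [macro voxels]
    rho: float = 0.5  # mollification range (< gamma_h)
    D_m: float = 3.0  # MDE diffusion coefficient [len^2/day]
    omega_threshold: float = 0.02  # outside-mass fraction triggering movement
    xi_mag: float = 2.0  # displacement per unit outside mass [len]
    max_cubes: int = 512  # bundle subsampling cap
    max_displacement: float = 1.0  # per-stage cap [macro voxels]

    def __post_init__(self) -> None:
        if not 0 < self.rho < self.gamma_h:
            raise ValueError("need 0 < rho < gamma_h")
        if self.eps <= 0 or self.micro_n < 2:
            raise ValueError("cube edge must span at least 2 micro cells")
        if self.D_m <= 0:
            raise ValueError("D_m must be positive")


@dataclass
class BoundaryMicroDomain:
    """One cubic micro-domain of the boundary bundle."""

    centre: np.ndarray  # physical coordinates of the boundary point
    centre_index: np.ndarray  # macro voxel index
    eps: float
    micro_n: int

    def micro_coords(self, spacing) -> tuple[np.ndarray, ...]:
        """Physical coordinates of micro-cell centres (each (n,n,n))."""
        half = 0.5 * self.eps * np.asarray(spacing)
        axes = []
        for d in range(3):
            h = self.eps * spacing[d] / self.micro_n
            axes.append(
                self.centre[d] - half[d] + (np.arange(self.micro_n) + 0.5) * h
            )
        return np.meshgrid(*axes, indexing="ij", sparse=False)


def build_bundle(domain: TumourDomain,
                 params: BoundaryMicroParams) -> list[BoundaryMicroDomain]:
    """Bundle of cubic micro-domains covering the eps/2-envelope of the
    boundary, one cube per (stride-subsampled) boundary point."""
    pts = domain.boundary_points
    if len(pts) == 0:
        raise BundleError("empty tumour boundary")
    stride = max(1, int(np.ceil(len(pts) / params.max_cubes)))
    sel = np.arange(0, len(pts), stride)
    coords = domain.boundary_coords()
    return [
        BoundaryMicroDomain(coords[i], pts[i], params.eps, params.micro_n)
        for i in sel
    ]


def mde_source_field(cube: BoundaryMicroDomain, c_macro: np.ndarray,
                     inside: np.ndarray, grid: Grid3D,
                     params: BoundaryMicroParams) -> np.ndarray:
    """Micro-scale MDE source: mean cancer density near each micro node.

    ``h(y) = mean of c over B_inf(y, gamma_h) ∩ Omega`` for nodes inside
    the tumour, ramping smoothly to zero across the band of width ``rho``
    outside the interface, and exactly zero beyond it.
    """
    inside = inside.astype(bool)
    if not inside.any():
        raise BundleError("source evaluation requires a nonempty tumour")
    h_vox = np.asarray(grid.spacing)
    # Box-filtered mean of c over the inside part of the gamma_h ball,
    # computed at macro resolution then sampled at the micro nodes.
    size = max(1, 2 * int(np.floor(params.gamma_h)) + 1)
    csum = ndimage.uniform_filter(c_macro * inside, size=size, mode="constant")
    isum = ndimage.uniform_filter(inside.astype(np.float64), size=size,
                                  mode="constant")
    mean_c = np.divide(csum, isum, out=np.zeros_like(csum), where=isum > 1e-12)

    # Signed distance outside the tumour (0 inside) for the rho ramp.
    dist_out = ndimage.distance_transform_edt(~inside, sampling=grid.spacing)

    X, Y, Z = cube.micro_coords(grid.spacing)
    o = np.asarray(grid.origin)
    idx = []
    for d, A in enumerate((X, Y, Z)):
        i = np.floor((A - o[d]) / h_vox[d]).astype(int)
        idx.append(np.clip(i, 0, grid.shape[d] - 1))
    idx = tuple(idx)
    src = mean_c[idx]
    dist = dist_out[idx]
    ramp = np.clip(1.0 - dist / params.rho, 0.0, 1.0)
    # Smoothstep for a C1 ramp across the mollification band.
    ramp = ramp * ramp * (3.0 - 2.0 * ramp)
    return src * ramp


def solve_mde(source: np.ndarray, cube_edge: float, D_m: float, dt: float,
              nsub_min: int = 1) -> np.ndarray:
    """Explicit zero-flux heat solve ``dm/dtau = D_m lap(m) + h`` on the cube.

    Null initial condition; the explicit step auto-substeps to satisfy
    stability.  The discretisation is in flux form so the total mass of
    the result equals the time-integrated source exactly (up to float
    roundoff).  ``source`` may be (n,n,n) or a batch (k,n,n,n).
    """
    src = np.asarray(source, dtype=np.float64)
    batched = src.ndim == 4
    if not batched:
        src = src[None]
    n = src.shape[-1]
    h = cube_edge / n
    dt_stable = h * h / (6.0 * D_m)
    nsub = max(nsub_min, int(np.ceil(dt / (0.8 * dt_stable))))
    tau = dt / nsub
    m = np.zeros_like(src)
    for _ in range(nsub):
        lap = np.zeros_like(m)
        for ax in range(1, 4):
            a = np.moveaxis(m, ax, 1)
            flux = (a[:, 1:] - a[:, :-1]) / h  # interior faces
            div = np.zeros_like(a)
            div[:, :-1] += flux / h
            div[:, 1:] -= flux / h
            lap += np.moveaxis(div, 1, ax)
        m = m + tau * (D_m * lap + src)
    np.clip(m, 0.0, None, out=m)
    return m if batched else m[0]


def relocation_vector(cube: BoundaryMicroDomain, m_final: np.ndarray,
                      inside_micro: np.ndarray, grid: Grid3D,
                      params: BoundaryMicroParams):
    """Direction and magnitude of boundary-point relocation, or ``None``.

    Outside micro cells carrying more MDE than the cube mean mark the
    significant degradation pattern; if their summed mass exceeds
    ``omega_threshold`` of the cube total, the point moves along the
    mass-weighted first moment of those cells, by ``xi_mag`` times the
    significant outside mass (micro cell volumes included).
    """
    total = float(m_final.sum())
    if total <= 0:
        return None
    mean = m_final.mean()
    outside = ~inside_micro.astype(bool)
    sig = outside & (m_final > mean)
    cell_vol = float(np.prod(np.asarray(grid.spacing) * cube.eps / cube.micro_n))
    q_tot = float(m_final[sig].sum()) * cell_vol
    if q_tot <= params.omega_threshold * total * cell_vol:
        return None
    X, Y, Z = cube.micro_coords(grid.spacing)
    offs = np.stack([X - cube.centre[0], Y - cube.centre[1], Z - cube.centre[2]],
                    axis=-1)
    moment = (m_final[sig][:, None] * offs[sig]).sum(axis=0)
    nrm = np.linalg.norm(moment)
    if nrm < 1e-14:
        return None
    direction = moment / nrm
    magnitude = params.xi_mag * q_tot
    return direction, magnitude


def boundary_micro_stage(c_macro: np.ndarray, domain: TumourDomain,
                         params: BoundaryMicroParams, dt: float):
    """Run the MDE micro-process on the whole bundle for one stage.

    Returns a list of ``(point_index, direction, magnitude)`` relocations
    (macro length units, capped at ``max_displacement`` voxels).
    """
    grid = domain.grid
    inside = domain.indicator.astype(bool)
    cubes = build_bundle(domain, params)

    sources = []
    inmasks = []
    o = np.asarray(grid.origin)
    h_vox = np.asarray(grid.spacing)
    # Shared macro-scale precomputations.
    size = max(1, 2 * int(np.floor(params.gamma_h)) + 1)
    csum = ndimage.uniform_filter(c_macro * inside, size=size, mode="constant")
    isum = ndimage.uniform_filter(inside.astype(np.float64), size=size,
                                  mode="constant")
    mean_c = np.divide(csum, isum, out=np.zeros_like(csum), where=isum > 1e-12)
    dist_out = ndimage.distance_transform_edt(~inside, sampling=grid.spacing)

    for cube in cubes:
        X, Y, Z = cube.micro_coords(grid.spacing)
        idx = []
        for d, A in enumerate((X, Y, Z)):
            i = np.floor((A - o[d]) / h_vox[d]).astype(int)
            idx.append(np.clip(i, 0, grid.shape[d] - 1))
        idx = tuple(idx)
        dist = dist_out[idx]
        ramp = np.clip(1.0 - dist / params.rho, 0.0, 1.0)
        ramp = ramp * ramp * (3.0 - 2.0 * ramp)
        sources.append(mean_c[idx] * ramp)
        inmasks.append(inside[idx])

    src = np.stack(sources)
    m_fin = solve_mde(src, params.eps * float(np.mean(h_vox)), params.D_m, dt)

    relocations = []
    cap = params.max_displacement * float(np.mean(h_vox))
    for i, cube in enumerate(cubes):
        res = relocation_vector(cube, m_fin[i], inmasks[i], grid, params)
        if res is None:
            continue
        direction, magnitude = res
        relocations.append((cube.centre_index, direction, min(magnitude, cap)))
    return relocations


def evolve_domain(domain: TumourDomain, relocations) -> TumourDomain:
    """Grow Omega by rasterising the displaced boundary points.

    Each relocated boundary point sweeps the voxels along its
    displacement segment into the tumour; interior holes created by the
    rasterisation are filled.  The domain is monotone non-decreasing
    (invasion only; treatment reduces density, not the footprint).
    """
    grid = domain.grid
    if not relocations:
        return domain
    indicator = domain.indicator.copy()
    h = np.asarray(grid.spacing)
    o = np.asarray(grid.origin)
    nmax = np.asarray(grid.shape) - 2  # stay off the frame
    for idx, direction, magnitude in relocations:
        start = o + (np.asarray(idx) + 0.5) * h
        steps = max(2, int(np.ceil(magnitude / min(h) * 4)))
        for t in np.linspace(0.0, magnitude, steps):
            p = start + t * direction
            cell = np.floor((p - o) / h).astype(int)
            cell = np.clip(cell, 1, nmax)
            indicator[tuple(cell)] = True
    indicator = ndimage.binary_fill_holes(indicator)
    indicator |= domain.indicator.astype(bool)
    return extract_boundary(indicator, grid)


class DomainEvolver:
    """Accumulates sub-voxel boundary advances between lattice updates.

    A single stage typically relocates boundary points by a fraction of a
    voxel, which a binary lattice cannot represent.  The evolver banks
    each boundary voxel's relocation magnitude; once the accumulated
    advance reaches one voxel the displaced segment is rasterised into
    the indicator and the bank is reset for the voxels that moved.
    Advances are inherited nowhere: freshly exposed boundary voxels start
    from zero.  The domain remains monotone non-decreasing.
    """

    def __init__(self, grid: Grid3D):
        self.grid = grid
        self.advance = np.zeros(grid.shape)
        self.direction = np.zeros(grid.shape + (3,))

    def apply(self, domain: TumourDomain, relocations) -> TumourDomain:
        if not relocations:
            return domain
        h_min = float(min(self.grid.spacing))
        due = []
        for idx, direction, magnitude in relocations:
            key = tuple(idx)
            self.advance[key] += magnitude
            self.direction[key] = direction
            if self.advance[key] >= h_min:
                due.append((idx, self.direction[key], self.advance[key]))
        if not due:
            return domain
        new_domain = evolve_domain(domain, due)
        for idx, _, _ in due:
            self.advance[tuple(idx)] = 0.0
        return new_domain
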