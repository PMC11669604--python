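"""Cell-scale ECM fibre representation and cancer-driven rearrangement.

Every macro voxel owns a cubic micro-domain (default 5^3 micro cells)
holding a nonnegative fibre mass distribution laid down as straight
narrow stripes: randomly oriented in grey matter, aligned with the local
tract tangent in white matter, filled until the occupied volume reaches
35% of the micro-domain.  The macroscopic fibre field is induced bottom-up:
``theta_f`` points along the mass-weighted mean stripe direction
(directions are axial, so they are disambiguated into a common
hemisphere) and its magnitude is the mean micro mass, so
``F = ||theta_f||_2``.

Moving cancer cells rearrange the micro fibres top-down: the macroscopic
cell flux, mediated against the existing fibre orientation by the weight
``w = c/(c+F)``, displaces each micro-domain's mass towards the flux
direction; mass crossing a micro-domain face lands in the neighbouring
micro-domain.  Rearrangement conserves fibre mass exactly; degradation
happens only through the macroscopic ECM decay law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fields import Grid3D, weight_w

DEFAULT_MICRO_N = 5
DEFAULT_FILL = 0.35


@dataclass
class MicroFibreDomain:
    """Micro fibre state of a single macro voxel."""

    mass: np.ndarray  # (n, n, n) nonnegative
    dirvec: np.ndarray  # (n, n, n, 3) mass-weighted stripe directions
    fill_fraction: float
    n_stripes: int
    last_stripe_cells: int

    @property
    def n(self) -> int:
        return self.mass.shape[0]


def _stripe_cells(n: int, direction: np.ndarray, point: np.ndarray) -> np.ndarray:
    """Micro cells covered by a straight unit-cross-section stripe."""
    u = direction / np.linalg.norm(direction)
    L = np.sqrt(3.0) * n
    t = np.arange(-L, L, 0.25)
    pts = point[None, :] + t[:, None] * u[None, :]
    cells = np.floor(pts).astype(int)
    ok = np.all((cells >= 0) & (cells < n), axis=1)
    cells = cells[ok]
    if len(cells) == 0:
        return cells
    return np.unique(cells, axis=0)


def init_micro_fibre_domain(rng: np.random.Generator, n: int = DEFAULT_MICRO_N,
                            fill: float = DEFAULT_FILL,
                            direction: np.ndarray | None = None
                            ) -> MicroFibreDomain:
    """Fill one micro-domain with stripes until the target volume fraction.

    ``direction=None`` draws an independent uniform orientation per stripe
    (grey matter); a fixed ``direction`` lays down parallel stripes at
    random offsets (white matter).  Stripes are laid until the cumulative
    occupied volume first reaches ``fill`` (the crossing stripe is kept,
    so the overshoot is bounded by one stripe's volume).
    """
    mass = np.zeros((n, n, n))
    dirvec = np.zeros((n, n, n, 3))
    vsum = np.zeros(3)
    total = n**3
    occupied = 0
    n_stripes = 0
    last_added = 0
    for _ in range(10_000):
        if occupied / total >= fill:
            break
        if direction is None:
            u = rng.standard_normal(3)
            while np.linalg.norm(u) < 1e-8:
                u = rng.standard_normal(3)
            u = u / np.linalg.norm(u)
        else:
            u = np.asarray(direction, dtype=np.float64)
            u = u / np.linalg.norm(u)
        if np.dot(u, vsum) < 0:
            u = -u  # axial fibres: keep directions in one hemisphere
        point = rng.uniform(0, n, size=3)
        cells = _stripe_cells(n, u, point)
        if len(cells) == 0:
            continue
        idx = tuple(cells.T)
        new = mass[idx] == 0
        added = int(new.sum())
        if added == 0:
            continue
        sel = tuple(c[new] for c in idx)
        mass[sel] = 1.0
        dirvec[sel] = u
        vsum += added * u
        occupied += added
        n_stripes += 1
        last_added = added
    return MicroFibreDomain(mass, dirvec, occupied / total, n_stripes, last_added)


def theta_f_single(domain: MicroFibreDomain) -> np.ndarray:
    """Macroscopic fibre vector of one micro-domain.

    Magnitude is the mean micro mass (so ``F = ||theta_f||``); direction
    is the normalised mass-weighted mean of stripe directions.  An empty
    domain yields the zero vector.
    """
    F = domain.mass.mean()
    if F <= 0:
        return np.zeros(3)
    v = domain.dirvec.reshape(-1, 3).sum(axis=0)
    nv = np.linalg.norm(v)
    if nv < 1e-14:
        return np.array([F, 0.0, 0.0])  # isotropic cancellation: fixed axis
    return F * v / nv


class MicroFibreField:
    """Collection of micro-domains on a shared global micro lattice.

    Macro voxel ``(i, j, k)`` owns the micro block
    ``[i*n:(i+1)*n, j*n:(j+1)*n, k*n:(k+1)*n]`` of the global ``mass``
    and ``dirvec`` arrays.
    """

    def __init__(self, grid: Grid3D, n: int = DEFAULT_MICRO_N,
                 mass: np.ndarray | None = None,
                 dirvec: np.ndarray | None = None):
        self.grid = grid
        self.n = int(n)
        shape = tuple(s * self.n for s in grid.shape)
        self.mass = np.zeros(shape) if mass is None else mass
        self.dirvec = np.zeros(shape + (3,)) if dirvec is None else dirvec
        if self.mass.shape != shape or self.dirvec.shape != shape + (3,):
            raise ValueError("micro arrays do not match grid * micro resolution")

    def _blocks(self, a: np.ndarray) -> np.ndarray:
        nx, ny, nz = self.grid.shape
        n = self.n
        extra = a.shape[3:]
        return a.reshape(nx, n, ny, n, nz, n, *extra).transpose(
            0, 2, 4, 1, 3, 5, *range(6, 6 + len(extra))
        )

    def set_block(self, index, domain: MicroFibreDomain) -> None:
        i, j, k = index
        n = self.n
        sl = (slice(i * n, (i + 1) * n), slice(j * n, (j + 1) * n),
              slice(k * n, (k + 1) * n))
        self.mass[sl] = domain.mass
        self.dirvec[sl] = domain.dirvec

    def theta_f(self) -> np.ndarray:
        """Macro fibre vector field (shape + (3,)); ``F = ||theta_f||``."""
        mb = self._blocks(self.mass)
        F = mb.mean(axis=(3, 4, 5))
        v = self._blocks(self.dirvec).sum(axis=(3, 4, 5))
        nv = np.linalg.norm(v, axis=-1)
        deg = (F > 0) & (nv < 1e-14)
        dirs = v / np.maximum(nv, 1e-300)[..., None]
        dirs[deg] = np.array([1.0, 0.0, 0.0])
        return F[..., None] * dirs

    def F(self) -> np.ndarray:
        return self._blocks(self.mass).mean(axis=(3, 4, 5))

    def total_mass(self) -> float:
        return float(self.mass.sum())

    def scale_mass(self, factor: np.ndarray) -> None:
        """Scale each macro voxel's micro mass (macroscopic ECM decay)."""
        changed = np.abs(np.asarray(factor) - 1.0) > 1e-15
        if not changed.any():
            return
        pts = np.argwhere(changed)
        lo, hi = pts.min(axis=0), pts.max(axis=0) + 1
        n = self.n
        sub = factor[tuple(slice(a, b) for a, b in zip(lo, hi))]
        up = np.repeat(np.repeat(np.repeat(sub, n, 0), n, 1), n, 2)
        crop = tuple(slice(a * n, b * n) for a, b in zip(lo, hi))
        self.mass[crop] *= up
        self.dirvec[crop] *= up[..., None]

    def copy(self) -> "MicroFibreField":
        return MicroFibreField(self.grid, self.n, self.mass.copy(), self.dirvec.copy())


def _direction_key(u: np.ndarray, bins: int = 24) -> tuple[int, int]:
    theta = np.arccos(np.clip(abs(u[2]), 0, 1))  # axial: fold hemisphere
    phi = np.arctan2(u[1], u[0]) % np.pi
    return (int(theta / np.pi * bins), int(phi / np.pi * bins))


def init_micro_fibres(wm_fraction: np.ndarray, gm_fraction: np.ndarray,
                      grid: Grid3D, seed: int = 0,
                      tract_directions: np.ndarray | None = None,
                      n: int = DEFAULT_MICRO_N, fill: float = DEFAULT_FILL,
                      library_size: int = 64) -> MicroFibreField:
    """Initialise every macro voxel's micro fibre domain.

    White-matter voxels (``wm > gm``) use stripes aligned with the local
    tract tangent; grey-matter voxels use random orientations.  For
    speed, realisations are drawn from a seeded library of fill-until
    configurations (random-orientation library for grey matter, one
    aligned realisation per quantised tract direction for white matter);
    each library member is a faithful fill-until realisation.
    """
    rng = np.random.default_rng(seed)
    field = MicroFibreField(grid, n)
    brain = (wm_fraction + gm_fraction) > 0.05
    wm_vox = brain & (wm_fraction > gm_fraction)
    gm_vox = brain & ~wm_vox

    gm_library = [init_micro_fibre_domain(rng, n, fill) for _ in range(library_size)]
    wm_cache: dict[tuple[int, int], MicroFibreDomain] = {}

    for idx in np.argwhere(gm_vox):
        field.set_block(idx, gm_library[rng.integers(len(gm_library))])
    for idx in np.argwhere(wm_vox):
        u = (tract_directions[tuple(idx)]
             if tract_directions is not None else np.array([1.0, 0.0, 0.0]))
        key = _direction_key(u)
        if key not in wm_cache:
            wm_cache[key] = init_micro_fibre_domain(rng, n, fill, direction=u)
        field.set_block(idx, wm_cache[key])
    return field


def rearrangement_flux(cell_flux: np.ndarray, c: np.ndarray, F: np.ndarray,
                       theta_f: np.ndarray) -> np.ndarray:
    """Rearrangement vector ``r = w * flux + (1 - w) * theta_f`` with
    ``w = c / (c + F)`` (per macro voxel)."""
    w = weight_w(c, F)
    return w[..., None] * cell_flux + (1.0 - w)[..., None] * theta_f


def reallocate_micro_fibres(field: MicroFibreField, r: np.ndarray, dt: float,
                            gain: float = 0.1, active: np.ndarray | None = None,
                            deposition: str = "trilinear") -> float:
    """Shift micro fibre mass along the rearrangement vector ``r``.

    Every parcel in macro voxel ``x`` is displaced by
    ``gain * r(x) * dt`` (macro length units), capped at one macro voxel
    per call; mass crossing micro-domain faces is deposited in the
    neighbouring domain (trilinear or nearest-voxel deposition on the
    global micro lattice).  ``active`` restricts the update to a macro
    mask (outside it fibres stay untouched).  Total fibre mass is
    conserved to machine precision.  Returns the largest displacement
    magnitude (macro-voxel units) before capping.
    """
    grid = field.grid
    n = field.n
    h = np.asarray(grid.spacing)
    disp = gain * dt * np.asarray(r)  # macro length units
    disp_vox = disp / h  # macro-voxel units
    mag = np.linalg.norm(disp_vox, axis=-1)
    max_mag = float(mag.max()) if mag.size else 0.0
    over = mag > 1.0
    if over.any():
        warnings.warn(
            f"fibre displacement cap exceeded in {int(over.sum())} voxels; clamped",
            stacklevel=2,
        )
        disp_vox = np.where(over[..., None], disp_vox / np.maximum(mag, 1e-300)[..., None], disp_vox)
    if active is None:
        active = mag > 0
    else:
        active = np.asarray(active, dtype=bool) & (mag > 0)
    if not active.any():
        return max_mag

    disp_micro = disp_vox * n  # micro-cell units

    # Crop to the bounding box of active macro voxels (plus one halo voxel).
    pts = np.argwhere(active)
    lo = np.maximum(pts.min(axis=0) - 1, 0)
    hi = np.minimum(pts.max(axis=0) + 2, np.asarray(grid.shape))
    mlo, mhi = lo * n, hi * n
    crop = tuple(slice(a, b) for a, b in zip(mlo, mhi))
    Mc = np.ascontiguousarray(field.mass[crop])
    Vc = np.ascontiguousarray(field.dirvec[crop])
    act_c = active[tuple(slice(a, b) for a, b in zip(lo, hi))]
    disp_c = disp_micro[tuple(slice(a, b) for a, b in zip(lo, hi))]

    # Micro cells belonging to active macro voxels, with their (uniform
    # per macro voxel) displacement.
    act_micro = np.repeat(np.repeat(np.repeat(act_c, n, 0), n, 1), n, 2)
    dmicro = np.repeat(np.repeat(np.repeat(disp_c, n, 0), n, 1), n, 2)
    src = np.argwhere(act_micro & (Mc > 0))
    if len(src) == 0:
        return max_mag
    sidx = tuple(src.T)
    m = Mc[sidx]
    v = Vc[sidx]
    d = dmicro[sidx]

    shape = Mc.shape
    newpos = src + d
    for ax in range(3):
        np.clip(newpos[:, ax], 0.0, shape[ax] - 1.0 - 1e-9, out=newpos[:, ax])

    Mc[sidx] = 0.0
    Vc[sidx] = 0.0

    def _deposit(flat_idx, weights_m, weights_v):
        size = int(np.prod(shape))
        Mc[...] += np.bincount(flat_idx, weights=weights_m, minlength=size
                               ).reshape(shape)
        flatV = Vc.reshape(-1, 3)
        for dcomp in range(3):
            flatV[:, dcomp] += np.bincount(
                flat_idx, weights=weights_v[:, dcomp], minlength=size
            )

    if deposition == "nearest":
        cells = np.rint(newpos).astype(np.int64)
        flat = np.ravel_multi_index(tuple(cells.T), shape)
        _deposit(flat, m, v)
    else:
        base = np.floor(newpos).astype(np.int64)
        frac = newpos - base
        for corner in range(8):
            off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
            w = np.ones(len(src))
            for ax in range(3):
                w *= frac[:, ax] if off[ax] else (1.0 - frac[:, ax])
            cells = np.minimum(base + off, np.asarray(shape) - 1)
            flat = np.ravel_multi_index(tuple(cells.T), shape)
            _deposit(flat, m * w, v * w[:, None])

    field.mass[crop] = Mc
    field.dirvec[crop] = Vc
    return max_mag
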