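"""Nutrient steady state and nutrient-dependent kinetic rate functions.

Avascular tumours absorb nutrients through the outer interface, so the
nutrient level sigma obeys a stationary diffusion-uptake balance

    0 = div( Dsig grad sigma ) - d_sigma * c * sigma    on Omega(t),
    sigma = sigma_nor                                   on the outer interface,

with spatially varying transport coefficient
``Dsig = D_sigma / (c + F + p0)`` (crowded tissue transports less).  The
discrete elliptic system (7-point stencil, harmonic-mean face
coefficients) is solved by red-black successive over-relaxation.

Proliferation and death rates are smooth cosine ramps between a necrotic
threshold ``sigma_n`` and an optimal-proliferation level ``sigma_p``:
no proliferation below ``sigma_n`` and maximal above ``sigma_p``; death
is the mirror image (maximal in necrotic regions, zero above
``sigma_p``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import Grid3D, TissueState, TumourDomain


class SolverError(RuntimeError):
    """Iterative solver failed to converge."""


@dataclass(frozen=True)
class NutrientParams:
    D_sigma: float = 1.0  # maximal diffusive transport
    d_sigma: float = 2.0  # cellular uptake rate
    p0: float = 0.5  # baseline permeability
    sigma_nor: float = 1.0  # normal tissue nutrient level (Dirichlet value)
    sigma_p: float = 0.6  # optimal proliferation level
    sigma_n: float = 0.2  # necrotic threshold
    psi_p_max: float = 1.0
    psi_d_max: float = 1.0
    sor_omega: float = 1.8
    sor_tol: float = 1e-8
    sor_max_sweeps: int = 10_000

    def __post_init__(self) -> None:
        if not (self.sigma_nor > self.sigma_p > self.sigma_n > 0):
            raise ValueError(
                "nutrient levels must satisfy sigma_nor > sigma_p > sigma_n > 0"
            )
        for name in ("D_sigma", "d_sigma", "p0", "psi_p_max", "psi_d_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0 < self.sor_omega < 2:
            raise ValueError("SOR relaxation factor must lie in (0, 2)")


def transition_phi(sigma, phi_max, phi_min, phi_L, sigma_n, sigma_p):
    """Cosine transition between two rate extrema.

    ``phi_L`` shifts the phase of the cosine so the same family serves
    both the proliferation ramp (rising) and the death ramp (falling).
    """
    if sigma_p <= sigma_n:
        raise ValueError("transition requires sigma_p > sigma_n")
    sigma = np.asarray(sigma, dtype=np.float64)
    arg = np.pi * (sigma - sigma_n - phi_L) / (sigma_p - sigma_n)
    out = 0.5 * (phi_max - phi_min) * (np.cos(arg) + 1.0) + phi_min
    return out if out.ndim else float(out)


def psi_p(sigma, params: NutrientParams):
    """Nutrient-modulated proliferation factor: 0 below ``sigma_n``,
    ``psi_p_max`` above ``sigma_p``, smooth cosine ramp in between."""
    sigma = np.asarray(sigma, dtype=np.float64)
    ramp = transition_phi(
        sigma, params.psi_p_max, 0.0, params.sigma_p - params.sigma_n,
        params.sigma_n, params.sigma_p,
    )
    out = np.where(
        sigma <= params.sigma_n, 0.0,
        np.where(sigma >= params.sigma_p, params.psi_p_max, ramp),
    )
    return out if out.ndim else float(out)


def psi_d(sigma, params: NutrientParams):
    """Nutrient-modulated death factor: maximal below ``sigma_n``, zero
    above ``sigma_p``, smooth cosine ramp in between."""
    sigma = np.asarray(sigma, dtype=np.float64)
    ramp = transition_phi(
        sigma, params.psi_d_max, 0.0, 0.0, params.sigma_n, params.sigma_p
    )
    out = np.where(
        sigma <= params.sigma_n, params.psi_d_max,
        np.where(sigma >= params.sigma_p, 0.0, ramp),
    )
    return out if out.ndim else float(out)


def _face_coefficients(dcoef: np.ndarray, grid: Grid3D):
    """Harmonic-mean transmissibilities on the three face families."""
    faces = []
    for axis, h in enumerate(grid.spacing):
        a = np.swapaxes(dcoef, 0, axis)
        num = 2.0 * a[:-1] * a[1:]
        den = a[:-1] + a[1:]
        f = np.divide(num, den, out=np.zeros_like(num), where=den > 0) / h**2
        faces.append(np.swapaxes(f, 0, axis))
    return faces


def assemble_nutrient_system(state: TissueState, domain: TumourDomain,
                             params: NutrientParams):
    """Discrete operator pieces shared by SOR and the direct-solve oracle.

    Returns ``(inside, faces, uptake)`` where ``faces`` are the harmonic
    transmissibilities and ``uptake = d_sigma * c``.  Dirichlet value
    ``sigma_nor`` applies at every outside neighbour.
    """
    grid = state.grid
    inside = domain.indicator.astype(bool)
    dcoef = params.D_sigma / (state.c + state.F + params.p0)
    faces = _face_coefficients(dcoef, grid)
    uptake = params.d_sigma * state.c
    return inside, faces, uptake


def _neighbour_terms(sigma_ext, faces, inside_ext):
    """Sum of face-coeff * neighbour-value and sum of face-coeffs, with
    Dirichlet neighbours already substituted in sigma_ext."""
    nx, ny, nz = np.asarray(sigma_ext.shape) - 2
    acc = np.zeros((nx, ny, nz))
    diag = np.zeros((nx, ny, nz))
    core = (slice(1, -1), slice(1, -1), slice(1, -1))
    for axis, f in enumerate(faces):
        lo = [slice(1, -1)] * 3
        hi = [slice(1, -1)] * 3
        lo[axis] = slice(0, -2)
        hi[axis] = slice(2, None)
        fpad_shape = list(acc.shape)
        fpad_shape[axis] += 1
        fpad = np.zeros(fpad_shape)
        sl_in = [slice(None)] * 3
        sl_in[axis] = slice(1, -1)
        fpad[tuple(sl_in)] = f
        sl_lo = [slice(None)] * 3
        sl_lo[axis] = slice(0, -1)
        sl_hi = [slice(None)] * 3
        sl_hi[axis] = slice(1, None)
        f_lo = fpad[tuple(sl_lo)]
        f_hi = fpad[tuple(sl_hi)]
        acc += f_lo * sigma_ext[tuple(lo)] + f_hi * sigma_ext[tuple(hi)]
        diag += f_lo + f_hi
    return acc, diag


def solve_nutrients(state: TissueState, domain: TumourDomain,
                    params: NutrientParams, *, sigma0: np.ndarray | None = None,
                    tol: float | None = None) -> np.ndarray:
    """Steady-state nutrient field on Omega(t) by red-black SOR.

    Outside Omega the returned field is set to ``sigma_nor`` for output
    convenience (the PDE is only posed on Omega).  ``sigma0`` warm-starts
    the iteration.  Raises :class:`SolverError` if the residual sup-norm
    does not fall below tolerance within the sweep budget.
    """
    grid = state.grid
    inside, faces, uptake = assemble_nutrient_system(state, domain, params)
    tol = params.sor_tol if tol is None else tol

    sigma = np.full(grid.shape, params.sigma_nor, dtype=np.float64)
    if sigma0 is not None:
        sigma = np.where(inside, np.clip(sigma0, 0.0, params.sigma_nor), sigma)

    # Extended array with a one-voxel Dirichlet rim; outside voxels stay at
    # sigma_nor, providing the boundary value seen by inside stencils.
    ext = np.full(tuple(np.asarray(grid.shape) + 2), params.sigma_nor)
    core = (slice(1, -1),) * 3
    ext[core] = sigma

    ii, jj, kk = np.indices(grid.shape)
    red = ((ii + jj + kk) % 2 == 0) & inside
    black = ((ii + jj + kk) % 2 == 1) & inside
    omega = params.sor_omega

    for sweep in range(params.sor_max_sweeps):
        for mask in (red, black):
            acc, diag = _neighbour_terms(ext, faces, inside)
            denom = diag + uptake
            gs = np.divide(acc, denom, out=np.full_like(acc, params.sigma_nor),
                           where=denom > 0)
            cur = ext[core]
            upd = (1 - omega) * cur + omega * gs
            ext[core] = np.where(mask, upd, cur)
        acc, diag = _neighbour_terms(ext, faces, inside)
        resid = acc - (diag + uptake) * ext[core]
        res = np.abs(np.where(inside, resid, 0.0)).max()
        if res < tol:
            break
    else:
        raise SolverError(
            f"SOR did not converge in {params.sor_max_sweeps} sweeps "
            f"(residual sup-norm {res:.3e}, tol {tol:.1e})"
        )

    out = np.where(inside, ext[core], params.sigma_nor)
    return np.clip(out, 0.0, params.sigma_nor)


def direct_solve_nutrients(state: TissueState, domain: TumourDomain,
                           params: NutrientParams) -> np.ndarray:
    """Sparse direct solve of the identical discretisation (test oracle)."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.linalg import spsolve

    grid = state.grid
    inside, faces, uptake = assemble_nutrient_system(state, domain, params)
    idx = -np.ones(grid.shape, dtype=np.int64)
    pts = np.argwhere(inside)
    idx[tuple(pts.T)] = np.arange(len(pts))
    n = len(pts)
    rows, cols, vals = [], [], []
    rhs = np.zeros(n)
    diag = uptake[tuple(pts.T)].copy()

    for axis, f in enumerate(faces):
        for sgn in (-1, 1):
            nb = pts.copy()
            nb[:, axis] += sgn
            valid = (nb[:, axis] >= 0) & (nb[:, axis] < grid.shape[axis])
            fidx = pts.copy()
            if sgn == -1:
                fidx[:, axis] -= 1
            fv = np.zeros(n)
            ok = (fidx[:, axis] >= 0) & (fidx[:, axis] < f.shape[axis])
            fv[ok] = f[tuple(fidx[ok].T)]
            diag += fv
            nb_in = np.zeros(n, dtype=bool)
            nb_in[valid] = inside[tuple(nb[valid].T)]
            conn = valid & nb_in
            rows.extend(np.nonzero(conn)[0])
            cols.extend(idx[tuple(nb[conn].T)])
            vals.extend(-fv[conn])
            dirich = ~conn
            rhs[dirich] += fv[dirich] * params.sigma_nor

    rows.extend(range(n))
    cols.extend(range(n))
    vals.extend(diag)
    A = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    sol = spsolve(A, rhs)
    out = np.full(grid.shape, params.sigma_nor)
    out[tuple(pts.T)] = sol
    return out
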