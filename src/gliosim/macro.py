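"""Macro-scale cancer dynamics: transport, adhesion, kinetics, time stepping.

The cancer density obeys

    dc/dt = div(div(D_T c)) - div(c * A) + P(u) - Q(u)
            - Radiotherapy(c, t) - Chemotherapy(c, t),

with anisotropic diffusion tensor ``D_T`` built from the tissue tensor
field, a non-local adhesion velocity ``A`` integrating cell-cell,
cell-matrix and fibre-directed adhesion over a sensing ball, logistic
volume-filling proliferation ``P``, nutrient-regulated death ``Q`` and the
two treatment sinks.  The two ECM phases decay where cancer is present,
faster while therapy is being delivered:

    dF/dt = -F c (beta_F + beta_FChemo + beta_FRadio),
    dl/dt = -l c (beta_l + beta_lChemo + beta_lRadio).

Time marching is a Heun predictor-corrector; the ECM decay is advanced
with an exact exponential integrator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import Grid3D, TissueState, total_density
from . import numerics


class StepError(RuntimeError):
    """Time step went unstable."""


@dataclass(frozen=True)
class MacroParams:
    mu: float = 0.4  # proliferation rate [1/day]
    death: float = 0.15  # death rate [1/day]
    S_cc: float = 0.3  # cell-cell adhesion strength
    S_cl: float = 0.1  # cell / non-fibre-ECM adhesion strength
    S_cF: float = 0.3  # cell / fibre-ECM adhesion strength
    R_s: float = 2.0  # sensing radius [length]
    kernel: str = "cone"  # radial kernel K(r) = 1 - r/R_s
    beta_F: float = 0.5  # baseline fibre ECM decay [1/day]
    beta_l: float = 0.3  # baseline non-fibre ECM decay [1/day]
    beta_F_chemo: float = 0.1
    beta_F_radio: float = 0.1
    beta_l_chemo: float = 0.1
    beta_l_radio: float = 0.1
    dt: float = 0.2  # macro step = one stage [day]
    D_c: float = 0.2  # diffusion scaling of the tissue tensor [len^2/day]

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("mu", "death", "beta_F", "beta_l", "beta_F_chemo",
                     "beta_F_radio", "beta_l_chemo", "beta_l_radio", "D_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


def build_diffusion_tensor(tensor_field: np.ndarray, wm_fraction: np.ndarray,
                           gm_fraction: np.ndarray, D_c: float) -> np.ndarray:
    """Tumour diffusion tensor from the imaging-derived tissue tensors.

    Mixture rule: ``D_T = D_c * (gm * I + wm * Dhat)`` with ``Dhat`` the
    trace-normalised tissue tensor (trace 3), so grey matter diffuses
    isotropically and white matter inherits the tract anisotropy.
    """
    tr = np.trace(tensor_field, axis1=-2, axis2=-1)
    dhat = tensor_field * (3.0 / np.maximum(tr, 1e-300))[..., None, None]
    eye = np.eye(3)
    out = D_c * (
        gm_fraction[..., None, None] * eye + wm_fraction[..., None, None] * dhat
    )
    # Keep a small isotropic floor outside brain tissue so the operator
    # stays elliptic everywhere.
    bg = np.clip(1.0 - wm_fraction - gm_fraction, 0.0, 1.0)
    return out + 0.05 * D_c * bg[..., None, None] * eye


def adhesion_offsets(grid: Grid3D, R_s: float):
    """Quadrature offsets within the sensing ball (cached per grid/R_s).

    Returns integer voxel offsets (m, 3), unit directions (m, 3) and
    quadrature weights ``K(|y|) * dV / R_s``.
    """
    h = np.asarray(grid.spacing)
    if R_s < min(h):
        raise ValueError("sensing radius must be at least one voxel")
    ranges = [np.arange(-int(np.floor(R_s / hh)), int(np.floor(R_s / hh)) + 1)
              for hh in h]
    I, J, K = np.meshgrid(*ranges, indexing="ij")
    offs = np.stack([I.ravel(), J.ravel(), K.ravel()], axis=1)
    y = offs * h
    r = np.linalg.norm(y, axis=1)
    keep = (r > 0) & (r <= R_s)
    offs, y, r = offs[keep], y[keep], r[keep]
    yhat = y / r[:, None]
    kern = 1.0 - r / R_s
    w = kern * np.prod(h) / R_s
    return offs, yhat, w


def _shift(a: np.ndarray, off) -> np.ndarray:
    """Sample ``a`` at x + off, zero beyond the grid frame."""
    out = np.zeros_like(a)
    src = []
    dst = []
    for d, o in enumerate(off):
        n = a.shape[d]
        o = int(o)
        if abs(o) >= n:
            return out
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = a[tuple(src)]
    return out


def adhesion_vector(state: TissueState, theta_f: np.ndarray,
                    params: MacroParams) -> np.ndarray:
    """Non-local adhesion velocity ``A(x)`` (shape + (3,)).

    Discrete quadrature of

        A(x) = 1/R_s * int_{B(0,R_s)} K(|y|) [ yhat (S_cc c + S_cl l)
               + yhat_f S_cF F ] (1 - rho(u))^+ dy,

    where ``yhat_f`` is the unit fibre direction at x+y flipped into the
    hemisphere containing ``yhat`` (fibres are axial, adhesion along them
    pulls towards the sampled point).
    """
    grid = state.grid
    offs, yhat, w = adhesion_offsets(grid, params.R_s)
    free = np.clip(1.0 - total_density(state), 0.0, None)
    gcl = (params.S_cc * state.c + params.S_cl * state.l) * free
    Ffree = params.S_cF * state.F * free

    fnorm = np.linalg.norm(theta_f, axis=-1)
    fdir = theta_f / np.maximum(fnorm, 1e-300)[..., None]
    has_f = fnorm > 1e-14

    A = np.zeros(grid.shape + (3,))
    for off, yh, wq in zip(offs, yhat, w):
        g = _shift(gcl, off)
        for d in range(3):
            A[..., d] += wq * yh[d] * g
        if params.S_cF > 0:
            Fs = _shift(Ffree, off)
            if not Fs.any():
                continue
            fd = np.stack([_shift(fdir[..., d], off) for d in range(3)], axis=-1)
            hf = _shift(has_f.astype(np.float64), off)
            dot = fd @ yh
            sgn = np.where(dot >= 0, 1.0, -1.0)
            A += (wq * Fs * hf * sgn)[..., None] * fd
    return A


def proliferation(state: TissueState, psi_p_field: np.ndarray,
                  params: MacroParams) -> np.ndarray:
    """Logistic volume-filling growth ``P(u) = mu * Psi_p(sigma) * c * (1-rho)^+``."""
    free = np.clip(1.0 - total_density(state), 0.0, None)
    return params.mu * psi_p_field * state.c * free


def death(state: TissueState, psi_d_field: np.ndarray,
          params: MacroParams) -> np.ndarray:
    """Nutrient-regulated death ``Q(u) = d * Psi_d(sigma) * c``."""
    return params.death * psi_d_field * state.c


def ecm_decay_step(state: TissueState, params: MacroParams, dt: float,
                   chemo_active: bool = False, radio_active: bool = False
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Exact exponential update of the two ECM phases over ``dt``.

    Therapy-induced decay rates are only included while the corresponding
    delivery bump is nonzero (``chemo_active`` / ``radio_active``).
    Returns the updated ``(F, l)``.
    """
    bF = params.beta_F + chemo_active * params.beta_F_chemo \
        + radio_active * params.beta_F_radio
    bl = params.beta_l + chemo_active * params.beta_l_chemo \
        + radio_active * params.beta_l_radio
    F = state.F * np.exp(-state.c * bF * dt)
    l = state.l * np.exp(-state.c * bl * dt)
    return F, l


def macro_rhs(state: TissueState, D_T: np.ndarray, theta_f: np.ndarray,
              params: MacroParams, psi_p_field: np.ndarray,
              psi_d_field: np.ndarray, treatment_rate: np.ndarray | float = 0.0,
              face_open: list[np.ndarray] | None = None,
              adhesion: np.ndarray | None = None) -> np.ndarray:
    """Right-hand side ``dc/dt`` of the cancer equation.

    ``treatment_rate`` is the combined radiotherapy + chemotherapy kill
    rate per unit density (multiplies c).  ``face_open`` masks transport
    fluxes (zero flux at the tumour interface and grid frame).
    ``adhesion`` may pass a precomputed velocity to avoid recomputation
    inside a multi-stage time step.
    """
    grid = state.grid
    diff = numerics.tensor_diffusion(state.c, D_T, grid.spacing, face_open)
    if adhesion is None:
        adhesion = adhesion_vector(state, theta_f, params)
    adv = numerics.advection_divergence(
        state.c, [adhesion[..., 0], adhesion[..., 1], adhesion[..., 2]],
        grid.spacing, face_open,
    )
    rhs = (
        diff - adv
        + proliferation(state, psi_p_field, params)
        - death(state, psi_d_field, params)
        - treatment_rate * state.c
    )
    if not np.all(np.isfinite(rhs)):
        raise StepError("non-finite values in macro RHS")
    return rhs


def cancer_flux(state: TissueState, D_T: np.ndarray, theta_f: np.ndarray,
                params: MacroParams,
                adhesion: np.ndarray | None = None) -> np.ndarray:
    """Cell-centred spatial flux ``F = D_T grad(c) + c div(D_T) - c A``.

    This is the flux expression driving micro-fibre rearrangement (it is
    not reused for transport, which is discretised conservatively).
    """
    grid = state.grid
    grad_c = numerics.gradient(state.c, grid.spacing)
    div_D = numerics.divergence_of_tensor(D_T, grid.spacing)
    if adhesion is None:
        adhesion = adhesion_vector(state, theta_f, params)
    flux = np.einsum("...ij,...j->...i", D_T, grad_c)
    flux += state.c[..., None] * div_D
    flux -= state.c[..., None] * adhesion
    return flux


@dataclass
class StepDiagnostics:
    clipped_mass: float = 0.0


def advance_stage(state: TissueState, D_T: np.ndarray, theta_f: np.ndarray,
                  params: MacroParams, psi_p_field: np.ndarray,
                  psi_d_field: np.ndarray, dt: float,
                  treatment_rate_t0: np.ndarray | float = 0.0,
                  treatment_rate_t1: np.ndarray | float = 0.0,
                  face_open: list[np.ndarray] | None = None,
                  diagnostics: StepDiagnostics | None = None,
                  adhesion: np.ndarray | None = None) -> np.ndarray:
    """Heun predictor-corrector advance of the cancer field over ``dt``.

    Predictor: forward Euler with the RHS at t; corrector: trapezoidal
    average of the RHS at t and at the predicted state.  Negative
    densities are clipped to zero with the clipped mass recorded.  The
    nutrient rate fields and the adhesion velocity are frozen over the
    step (they vary on the slower stage timescale).
    """
    adh = adhesion_vector(state, theta_f, params) if adhesion is None else adhesion
    k1 = macro_rhs(state, D_T, theta_f, params, psi_p_field, psi_d_field,
                   treatment_rate_t0, face_open, adhesion=adh)
    pred = state.copy()
    pred.c = np.clip(state.c + dt * k1, 0.0, None)
    k2 = macro_rhs(pred, D_T, theta_f, params, psi_p_field, psi_d_field,
                   treatment_rate_t1, face_open, adhesion=adh)
    c_new = state.c + 0.5 * dt * (k1 + k2)

    sup0 = np.abs(state.c).max()
    sup1 = np.abs(c_new).max()
    if sup0 > 1e-14 and sup1 > 10.0 * max(sup0, 1.0):
        raise StepError(
            f"instability detected: sup-norm grew {sup0:.3e} -> {sup1:.3e}"
        )
    clipped = -float(np.minimum(c_new, 0.0).sum()) * state.grid.voxel_volume
    if diagnostics is not None:
        diagnostics.clipped_mass += clipped
    return np.clip(c_new, 0.0, None)
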