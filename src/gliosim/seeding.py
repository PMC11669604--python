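"""Post-surgical initial cancer distribution inside the peritumoural oedema.

After resection, residual cancer cells sit inside the oedema along the
outward normal rays from the surgical-cavity edge Gamma.  Along each ray
the density follows one of two one-dimensional profiles parameterised by
the ray length ``q`` (distance from Gamma to the outer oedema boundary)
and a concentration controller ``xi > 1``:

* case 1 — a compactly supported mollifier of support radius
  ``R = q / xi`` (density vanishes before the oedema boundary);
* case 2 — a half-Gaussian of standard deviation ``sigma~ = q / xi``
  (strictly positive up to the boundary).

Larger ``xi`` concentrates the cells at the cavity edge.  The voxel
field is realised through distance transforms (equivalent to per-voxel
normal rays for smooth geometry): the normal coordinate of a voxel is
its distance to the cavity, and ``q`` is that distance plus the distance
to the oedema exterior.  Presence multipliers ``alpha_it`` (initial
tumour mask) and ``alpha_sc`` (surgical-cavity mask) modulate the three-
mask composition; the field is rescaled so its peak equals ``c_max``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.integrate import quad

from .fields import Grid3D, GeometryError

#: Normalisation constant of the 1D standard mollifier exp(-1/(1-x^2)).
_MOLLIFIER_NORM = 1.0 / quad(lambda x: np.exp(-1.0 / (1.0 - x * x)), -1, 1)[0]


@dataclass(frozen=True)
class SeedingSpec:
    """Oedema seeding description.

    ``case`` selects the ray profile (1 mollifier, 2 Gaussian); ``xi``
    is the concentration controller (the field constants k_R and
    k_sigma~ for the two cases); ``alpha_it`` and ``alpha_sc`` scale the
    density on the initial-tumour and surgical-cavity masks; ``c_max``
    is the peak density of the final field.
    """

    case: int = 1
    xi: float = 5.0
    alpha_it: float = 1.0
    alpha_sc: float = 1.0
    c_max: float = 0.1

    def __post_init__(self) -> None:
        if self.case not in (1, 2):
            raise ValueError("case must be 1 (mollifier) or 2 (Gaussian)")
        if self.xi <= 1:
            raise ValueError("the controller xi must exceed 1")
        if not (0 <= self.alpha_it <= 1 and 0 <= self.alpha_sc <= 1):
            raise ValueError("presence multipliers must lie in [0, 1]")
        if not 0 < self.c_max <= 1:
            raise ValueError("c_max must lie in (0, 1]")


def mollifier_psi1(x) -> np.ndarray:
    """1D standard symmetric mollifier: ``C exp(-1/(1-x^2))`` on (-1, 1),
    zero outside, with unit integral."""
    x = np.asarray(x, dtype=np.float64)
    inside = np.abs(x) < 1.0
    x2 = np.where(inside, x * x, 0.0)
    out = np.where(inside, _MOLLIFIER_NORM * np.exp(-1.0 / (1.0 - x2)), 0.0)
    return out if out.ndim else float(out)


def mollifier_profile(upsilon, q, k_R: float):
    """Case-1 ray profile ``R^-1 psi1(upsilon / R)`` with ``R = q / k_R``."""
    if k_R <= 1:
        raise ValueError("k_R must exceed 1")
    upsilon = np.asarray(upsilon, dtype=np.float64)
    if np.any(upsilon < 0):
        raise ValueError("the normal coordinate upsilon must be nonnegative")
    R = np.asarray(q, dtype=np.float64) / k_R
    out = np.divide(
        mollifier_psi1(np.divide(upsilon, R, out=np.full_like(upsilon + 0.0, 2.0),
                                 where=R > 0)),
        R, out=np.zeros(np.broadcast_shapes(upsilon.shape, R.shape)), where=R > 0,
    )
    return out if out.ndim else float(out)


def gaussian_profile(upsilon, q, k_sigma: float):
    """Case-2 ray profile: half-Gaussian ``exp(-upsilon^2 / (2 sigma~^2))``
    with ``sigma~ = q / k_sigma``; strictly positive on [0, q]."""
    upsilon = np.asarray(upsilon, dtype=np.float64)
    sig = np.asarray(q, dtype=np.float64) / k_sigma
    out = np.exp(
        -0.5 * np.divide(upsilon, sig, out=np.full_like(upsilon + 0.0, np.inf),
                         where=sig > 0) ** 2
    )
    out = np.where(sig > 0, out, 0.0)
    return out if out.ndim else float(out)


def controller_length(xi: float, q, case: int):
    """Length scale of either profile: ``q / xi`` (support radius in case
    1, standard deviation in case 2)."""
    if xi <= 1:
        raise ValueError("xi must exceed 1")
    if case not in (1, 2):
        raise ValueError("case must be 1 or 2")
    q = np.asarray(q, dtype=np.float64)
    out = q / xi
    return out if out.ndim else float(out)


def normal_ray_distance(x: np.ndarray, normal: np.ndarray,
                        oedema_mask: np.ndarray, grid: Grid3D,
                        step: float = 0.25, refine_iters: int = 30
                        ) -> tuple[float, bool]:
    """Distance along the outward normal ray from ``x`` to the outer
    oedema boundary, by marching with sub-voxel bisection refinement.

    Returns ``(q, hit)``; ``hit`` is False when the ray leaves the grid
    before exiting the oedema (then ``q`` is the distance to the frame).
    """
    o = np.asarray(grid.origin)
    h = np.asarray(grid.spacing)
    n_arr = np.asarray(grid.shape)
    normal = np.asarray(normal, dtype=np.float64)
    normal = normal / np.linalg.norm(normal)

    def inside_oedema(p):
        cell = np.floor((p - o) / h).astype(int)
        if np.any(cell < 0) or np.any(cell >= n_arr):
            return None
        return bool(oedema_mask[tuple(cell)])

    t = 0.0
    tmax = float(np.linalg.norm(n_arr * h)) * 2
    prev = t
    while t < tmax:
        t += step * float(min(h))
        state = inside_oedema(np.asarray(x) + t * normal)
        if state is None:
            return prev, False
        if not state:
            break
        prev = t
    else:
        return prev, False
    lo, hi = prev, t
    for _ in range(refine_iters):
        mid = 0.5 * (lo + hi)
        if inside_oedema(np.asarray(x) + mid * normal):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), True


def seed_oedema_field(spec: SeedingSpec, oedema_mask: np.ndarray,
                      cavity_mask: np.ndarray, grid: Grid3D,
                      initial_tumour_mask: np.ndarray | None = None
                      ) -> np.ndarray:
    """Voxel-wise residual-cancer field inside the oedema.

    The normal coordinate of a voxel is its Euclidean distance to the
    cavity; the ray length ``q`` is that distance plus the distance to
    the oedema exterior.  The profile value is multiplied by
    ``alpha_sc`` on the cavity mask, else ``alpha_it`` on the
    initial-tumour mask (the cavity, being the more recent observation,
    takes precedence where the masks overlap); it is zero outside the
    oedema.  The final field is rescaled to peak ``c_max``.
    """
    oedema = np.asarray(oedema_mask, dtype=bool)
    cavity = np.asarray(cavity_mask, dtype=bool)
    if not cavity.any():
        raise GeometryError("empty surgical cavity: no seeding surface Gamma")
    if oedema.shape != grid.shape or cavity.shape != grid.shape:
        raise ValueError("masks must live on the seeding grid")

    ups = ndimage.distance_transform_edt(~cavity, sampling=grid.spacing)
    d_out = ndimage.distance_transform_edt(oedema, sampling=grid.spacing)
    q = ups + d_out

    if spec.case == 1:
        profile = mollifier_profile(ups, q, spec.xi)
    else:
        profile = gaussian_profile(ups, q, spec.xi)

    c0 = np.where(oedema, profile, 0.0)
    mult = np.ones(grid.shape)
    if initial_tumour_mask is not None:
        mult = np.where(np.asarray(initial_tumour_mask, dtype=bool),
                        spec.alpha_it, mult)
    mult = np.where(cavity, spec.alpha_sc, mult)
    c0 = c0 * mult

    peak = c0.max()
    if peak > 0:
        c0 = c0 * (spec.c_max / peak)
    return c0


def eq20_h(x1, x2, x3):
    """Spatially heterogeneous non-fibre ECM profile on the reference cube.

    ``h = 1/2 + (1/4) sin^3(7 pi y1 y2 y3) sin(7 pi y1/y2/y3)`` with
    ``y_i = (x_i + 1.5) / 3`` mapping the cube [-1.5, 1.5]^3 to the unit
    cube; at the cube centre the second factor is sin(14 pi) = 0 so
    h = 1/2.
    """
    y1 = (np.asarray(x1, dtype=np.float64) + 1.5) / 3.0
    y2 = (np.asarray(x2, dtype=np.float64) + 1.5) / 3.0
    y3 = (np.asarray(x3, dtype=np.float64) + 1.5) / 3.0
    ratio = y1 / y2 / y3
    return 0.5 + 0.25 * np.sin(7 * np.pi * y1 * y2 * y3) ** 3 * np.sin(7 * np.pi * ratio)


def init_noncancer_fields(c0: np.ndarray, grid: Grid3D,
                          sigma0: float = 0.4) -> tuple[np.ndarray, np.ndarray]:
    """Initial non-fibre ECM and nutrient fields.

    Physical coordinates are affinely mapped onto the reference cube
    [-1.5, 1.5]^3; ``l(x,0) = min(h(x), 1 - c(x,0))`` and the nutrient
    level starts at the uniform value ``sigma0`` (default 0.4).
    """
    X, Y, Z = grid.coords()
    ref = []
    for A, n, h, o in zip((X, Y, Z), grid.shape, grid.spacing, grid.origin):
        lo, hi = o, o + n * h
        ref.append(-1.5 + 3.0 * (A - lo) / (hi - lo))
    hfield = np.broadcast_to(eq20_h(*ref), grid.shape)
    l0 = np.minimum(hfield, 1.0 - c0)
    l0 = np.clip(l0, 0.0, None)
    sigma = np.full(grid.shape, float(sigma0))
    return l0, sigma
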